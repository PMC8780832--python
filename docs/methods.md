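# Methods

This note documents the models, conventions, numerical choices and
limitations behind actisphere: a pipeline for analysing multi-day,
waist-worn (L5/S1) IMU recordings by projecting acceleration samples onto
the unit acceleration sphere (UAS), selecting information-rich 3-s
windows from the resulting orientation statistics, computing stroke-
relevant movement metrics, and classifying windows with a deep LSTM.

## Coordinate conventions and the unit acceleration sphere

A sample `a = [a_x, a_y, a_z]` (in g) is written in spherical coordinates

    rho   = sqrt(a_x^2 + a_y^2 + a_z^2)
    theta = atan2(a_y, sqrt(a_x^2 + a_z^2))        # elevation from equator
    phi   = atan2(a_x, -a_z)                       # azimuth

with `theta in [-pi/2, pi/2]` and `phi in [-pi, pi]`.  The sensor is worn
so that upright standing gives `a = [0, -1, 0]`, i.e. theta = -pi/2 (the
south pole).  Positive x points to the wearer's left, so `phi >= 0`
captures left-directed and `phi < 0` right-directed accelerations; the
azimuth convention is configurable (`atan2(a_x, a_z)` as an alternative)
because sensors are sometimes mounted mirrored.  Both `theta` and `phi`
are computed with the four-quadrant arctangent so they are defined
everywhere except the zero vector, which is rejected; at the poles
(`a_x = a_z = 0`) the azimuth is undefined and set to 0 by convention.

Projection onto the UAS sets `rho = 1` and keeps both angles.  The sphere
is discretized into 360 x 180 one-degree bins; bins are half-open
`[lo, hi)` with the top edge closed, so the 64,800 bins partition the
closed angle ranges exactly and every sample lands in exactly one bin.
Per bin we accumulate the occupancy count, its probability (count /
total), and the mean and SD of `|a|`.  The SD is the population SD
(`ddof = 0`, configurable): bins are descriptive summaries, not samples
from a superpopulation.  The one-pass variance is accumulated on
`|a| - 1` (resting magnitudes sit near 1 g), which keeps it conditioned;
bins with a single sample have SD 0, and empty bins carry NaN — never 0 —
so they can never masquerade as "low-variability" bins downstream.

Hemisphere views render one hemisphere as a polar raster (angle = phi,
radius = pi/2 - |theta|, pole at the center), i.e. the sphere viewed
along the y-axis.  The probability view supports a log10 colour scale;
zero-probability bins are masked rather than mapped to -inf.  The
per-bin probability is plotted as-is (not normalized by bin solid angle).

## Information-rich window selection

Multi-day recordings are dominated by rest and sleep.  A sample is kept
when all three of the following hold:

1. **Elevation.** `theta in [-pi/2, theta_max]` with `theta_max = -pi/3`:
   the south polar cap, the neighbourhood of upright posture where
   daytime movement happens.
2. **Daytime.** Wall-clock time in `[07:00, 20:00)` (configurable).
3. **Bin statistics.** The sample's 1-degree bin shows movement:
   `SD(|a|) >= 0.02 g` **or** `|mean(|a|) - 1 g| > 0.02 g`.

The third criterion's combination rule deserves a note.  The screening
idea is to *exclude* bins that are simultaneously low-variability and
near-gravity — those are rest, breathing artifacts and static postures.
Excluding (low-SD AND near-g) is accepting (high-SD OR far-from-g), so
the default `combine_rule` is `"OR"`.  The conjunctive reading ("a bin
must show high SD AND a shifted mean") is stricter in a way that breaks
contiguity: during any rhythmic movement some visited bins have a mean
`|a|` crossing 1 g while their SD is large, and requiring both conditions
punches per-cycle holes in the selection mask so that no contiguous 3-s
run survives.  `combine_rule="AND"` remains available.

Selected samples are cut into contiguous, non-overlapping windows of
`window_s * sample_rate` timesteps (300 at the 3-s / 100 Hz defaults)
within each maximal contiguous masked run; runs also end at timestamp
gaps larger than 1.5 sample intervals, so windows never span sensor-off
periods.  A run of L samples yields floor(L / 300) windows.  Each window
carries 12 channels: `a_x, a_y, a_z`, the three angular velocities,
`|a|`, the three UAS-projected (unit-vector) components, theta and phi.
The 80/20 train/validation split is a seeded random shuffle of windows
(not subjects); an optional subject-level split can be built by filtering
on subject metadata, but no claims are made for it.

## Movement metrics

All thresholds below are in g and configurable; the defaults are recorded
in every serialized report.

**Higher-acceleration fraction (HAF).**  Over daytime samples in the
south polar cap (criteria 1-2 above; the bin filter is *not* applied),

    HAF = log10( #{|a| > 2 g} / #selected )

HAF <= 0 by construction, and 0 exactly when every selected sample
exceeds 2 g.  When no sample exceeds the threshold the function returns
NaN as an explicit "none above threshold" sentinel rather than -inf.
The log base (10) and the 2 g cut are configurable.

**Acceleration asymmetry index (AAI).**  Among the same selection's
high-acceleration samples (`|a| > 2 g`), `n_R` counts samples with
`phi < 0` (right side) and `n_L` those with `phi >= 0` (left side):

    alpha = | log10( n_R / n_L ) |

The absolute value is reported as the index (a symmetric mover gives
~0 regardless of which side dominates); the signed log-ratio and the raw
counts are returned alongside.  If either side has no samples the index
is NaN with the counts still reported.  Mirroring a recording
(`a_x -> -a_x`) leaves `alpha` unchanged and flips the sign of the signed
value — a tested invariant.

**Sleep detection.**  The x-z-plane resultant `R_xz = sqrt(a_x^2 +
a_z^2)` is ~1 g when supine and ~0 when upright.  The recording is split
into consecutive 1-s blocks; a block is sleep when `[mean - var, mean +
var]` of `R_xz` lies within `[0.97, 1.02] g` (variance, not SD, per the
rule's definition).  Non-overlapping blocks are used rather than a
1-sample-stride sliding window: at the +-1% recovery tolerance the
distinction only moves epoch edges by under a second, at 100x the cost.

**Activity amplitude.**  The detrended resultant acceleration is
`DRA = | |a| - 1 |`.  With noisy data DRA is strictly positive almost
everywhere, so "active epochs" are defined as contiguous runs with
`DRA > 0.05 g` (the epoch threshold, configurable).  Each epoch's
amplitude is the Riemann integral `dt * sum(DRA)` — chosen over the
trapezoid so that an idealized rectangular epoch (0.2 g held for 10 s)
integrates to exactly 2.0 g s; the two rules differ by O(dt) on real
epochs.  Epochs are banded by their peak DRA against cut points
(0.1, 0.3) g — values in the spirit of low/medium/high activity
intensities, fully configurable — and credited to one of four six-hour
time zones (00-06, 06-12, 12-18, 18-24) by the epoch's *start* time.
Raising a band's lower cut never increases that band's total (tested).

**Movement transitions.**  Peaks of `|a|` with prominence >= 0.2 g and
>= 1 s separation are candidate transitions.  Each peak's segment runs
from the nearest *held* baseline on the left to the nearest on the right,
where "held" means `|a|` within 0.02 g of 1 g continuously for at least
0.3 s — rhythmic gait grazes 1 g twice per cycle but never holds it, so
bouts are not counted.  A peak qualifies when this trough-to-trough span
is <= 3 s (the time scale of postural transitions).  Max, min, RMS,
range and duration are computed on the segment.  This detector is a
documented approximation: the original transition definition lives in
prior work that the source analysis does not reproduce.

**Wavelet spectrogram.**  The mean-removed `|a|` is convolved with
complex Morlet kernels — a complex exponential at frequency f under a
Gaussian envelope with SD `cycles / (2 pi f)` seconds, truncated at 4 SD
and L2-normalized — and the squared magnitude is returned per frequency.
`cycles` (default 7) trades time against frequency resolution.

**Cohen's d** uses the (n-1)-weighted pooled SD and returns NaN when the
pooled SD is zero with unequal means.

## The LSTM classifier

The reference architecture for (300, 12) windows is

    LSTM(200, sequence output) -> BatchNorm(200, channel axis)
    -> LSTM(50) -> Dropout(0.2) -> Dense(50, ReLU) -> Dropout(0.2)
    -> Dense(15, ReLU) -> Dense(1, sigmoid)

`count_parameters` computes the per-layer counts analytically: an LSTM
with u units and input dimension d holds `4(u(u+d) + u)` parameters
(170,400 and 50,200 for the two recurrent layers); batch normalization
tracks 4 values per channel (scale, shift and the two running statistics
= 800); a dense layer d -> u holds `(d+1)u` (2,550; 765; 16); dropout
holds none.

The network is implemented directly in NumPy: forward pass, full
backpropagation through time, inverted dropout, and Adam (lr 1e-3,
betas 0.9/0.999) with global gradient-norm clipping at 5.0.  Gate order
is (input, forget, candidate, output); input weights are Glorot-uniform,
recurrent weights orthogonal per gate, and the forget-gate bias starts
at 1.  The binary cross-entropy loss is fused with the output sigmoid for
numerical stability.  All computation is float32 by default (float64 for
gradient checking, which verifies backpropagation against central finite
differences to ~1e-6 relative error).  Inputs are z-scored per channel
with statistics from the training set only; the theta and phi channels
are standardized like the rest.  Given a seed, initialization, shuffling
and dropout are all drawn from one generator, so single-threaded training
is reproducible bit for bit.

Dropout probability (0.2), batch size, epochs and learning rate are
configuration, not architecture; the dropout layers contribute no
parameters, matching the analytic counts.

ROC evaluation sweeps thresholds over predicted probabilities
(scikit-learn's `roc_curve`), reports the trapezoidal area, and provides
the highest threshold that still attains a requested sensitivity — the
operating-point tuner for high-sensitivity screening.

## The synthetic generator

The generator emulates the study conditions: 1-3 day recordings at
100 Hz from a waist sensor, deterministic given a seed.

* **Upright rest** is `[0, -1, 0]` g plus white noise (0.01 g SD, the
  scale of a consumer MEMS accelerometer at 100 Hz).
* **Sleep** inside wall-clock windows (default 23:00-07:00) is supine,
  `[0, 0, -1]` g plus noise — which pins `R_xz` inside the sleep
  detector's band by construction.
* **Gait bouts** arrive as a per-hour Poisson process at time-zone-
  dependent rates (default ~5/h in the daytime zones), last 30-90 s, and
  superpose on gravity a stride-frequency fundamental (1.8 +- 0.3 Hz)
  plus a weaker second harmonic, shaped by a raised-sine envelope and
  ~12% stride-to-stride amplitude jitter.  Bout peak amplitudes are
  drawn from low/medium/high ranges mixed 50/35/15 and scaled by
  `amp_scale`.  Each bout carries a constant postural tilt of 3-7
  degrees (torso lean), which — as in real torso recordings — moves the
  bout's orientations off the upright-rest bins; lateral sway and
  fore-aft components are bounded so the elevation stays inside the
  south polar cap throughout a bout.
* **High-acceleration events** (defaults: 24 per awake-daytime hour,
  0.25 s, peak 2.2-3.0 g) point into the south polar cap with an
  azimuth directed right (`phi < 0`) with probability
  `asymmetry_factor / (1 + asymmetry_factor)`.  The default rate is a
  design-time power calculation: the AAI estimator's noise is
  ~`2 / sqrt(n_events) / ln 10` in log10 units, so ~300 events per
  analysed recording are needed for the symmetric generator's mean
  |alpha| to sit below 0.05; at 24/h a full analysed day (13 daytime
  hours) supplies them.
* **Stroke-like profiles** (used by `generate_cohort`) combine:
  `amp_scale` 0.5-0.75 (reduced activity amplitudes), `asymmetry_factor`
  1.8-3.2 applied both to event lateralization and to alternate-stride
  attenuation of the gait waveform (step-to-step asymmetry — the limp's
  subharmonic), cadence scaled by 0.75 (hemiparetic gait is slower), a
  6 Hz spasticity/clonus-like oscillation of 0.08-0.14 g during
  movement, and a halved high-acceleration event rate.  Healthy profiles
  use asymmetry 1.0-1.25, `amp_scale` 0.9-1.1 and no tremor component.
  BMI is drawn per group (healthy 26.1 +- 3.0, stroke 30.8 +- 5.6
  kg/m^2) and couples negatively and log-linearly to the event rate.
* **Gyro channels** are smoothed noise plus bout-locked oscillation:
  plumbing sufficient to exercise the 12-channel feature path, with no
  claim of rotational realism.

What the generator does *not* emulate: biomechanically valid gait
waveforms, off-body/non-wear periods, posture diversity beyond
upright/supine, sensor drift and temperature effects, or the
heterogeneity of real stroke presentations.  Passing tests therefore
demonstrate that the pipeline recovers structure it is designed to
detect under controlled conditions — not clinical validity on real
cohorts, whose headline numbers require the original recordings.

## Problem sizes and reproducibility checks

The test suite and the acceptance script run the whole pipeline at desk
scale; sizes are the package's own choices:

* binning oracle: 1e5 random samples against naive per-sample
  accumulation;
* AAI recovery: 0.55-day all-daytime recordings (07:00 start), 10 seeds
  per asymmetry factor over {1, 1.5, 2, 3};
* sleep recovery: one 24-h recording with the nocturnal 8-h window;
* transitions: pulse trains of k = 1..10 planted rectangular pulses;
* classifier: a 4+4-subject cohort of 6-h daytime recordings yielding a
  1,200-window subsample (1,000 train / 200 validation), trained 12
  epochs at batch 32 — with a 3-epoch permuted-label control that must
  stay at chance.

Known limitations: the classifier's window-level split shares subjects
between training and validation (as in the source protocol), so its
accuracy partly reflects subject idiosyncrasy; the transition detector
is an approximation (above); the azimuth convention must be set to match
how the sensor was actually worn; and the AAI's absolute value makes it
a biased (upward) estimator of |log ratio| at small event counts — the
power consideration above keeps that bias below the reported tolerance.
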