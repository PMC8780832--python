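# actisphere

Analysis of multi-day, waist-worn IMU recordings for movement health:
unit-acceleration-sphere visualization, information-rich time-series
extraction, stroke-relevant movement metrics, and a deep LSTM window
classifier — with a seeded synthetic generator so the whole pipeline can
be exercised end to end without clinical data.

## The problem

Wearable sensors worn passively at the low back record days of triaxial
acceleration and angular velocity at 100 Hz — over 8.6 million samples
per channel per day.  Most of that volume is rest and sleep; the
movement signatures that distinguish, say, a stroke survivor's
activities of daily living from a healthy peer's occupy a small
fraction of the stream.  actisphere implements a visualization-driven
way to find and use that fraction:

1. **Unit acceleration sphere (UAS).**  Each sample
   `a = [a_x, a_y, a_z]` (in g) is written in spherical coordinates —
   magnitude ρ, elevation θ = atan2(a_y, √(a_x²+a_z²)) ∈ [−π/2, π/2],
   azimuth φ = atan2(a_x, −a_z) ∈ [−π, π] — and projected onto the unit
   sphere (ρ = 1).  Upright standing maps to the south pole
   (θ = −π/2); the sign of φ separates left- from right-directed
   accelerations.  The sphere is discretized into 360×180 one-degree
   bins holding per-bin occupancy probability, mean |a| and SD of |a|,
   rendered as polar hemisphere maps.
2. **Window extraction.**  Samples are kept when they sit in the south
   polar cap (θ ≤ −π/3), during daytime (07:00–20:00), and in a bin
   whose statistics show movement (SD ≥ 0.02 g or |mean − 1 g| >
   0.02 g).  Contiguous selected runs are cut into 3-s, 300-timestep,
   12-channel windows.
3. **Metrics.**  Higher-acceleration fraction
   `HAF = log10(n_{|a|>2g} / n_selected)`, acceleration asymmetry index
   `α = |log10(n_R / n_L)|` over high-acceleration samples on the right
   (φ < 0) versus left (φ ≥ 0), sleep hours from 1-s blocks of
   `R_xz = √(a_x² + a_z²)` held within [0.97, 1.02] g, activity
   amplitudes (time integrals of `||a| − 1|`) by intensity band and
   six-hour time zone, movement-transition detection, complex-Morlet
   spectrograms, and Cohen's d.
4. **Classifier.**  A deep LSTM — LSTM(200, sequences) → BatchNorm →
   LSTM(50) → Dropout → Dense(50) → Dropout → Dense(15) → Dense(1,
   sigmoid) — over the 300×12 windows, implemented in NumPy with full
   backpropagation through time, seeded and reproducible, with analytic
   per-layer parameter counts (170,400 / 800 / 50,200 / 2,550 / 765 /
   16) and ROC evaluation.
5. **Synthetic cohorts.**  A seeded generator of healthy- and
   stroke-like recordings (sleep windows, gait bouts, rare >2 g events
   with configurable lateral asymmetry, reduced amplitudes, slowed
   cadence and tremor for stroke profiles) defines reproducible study
   conditions for every test.

It is intended for researchers in digital health and rehabilitation who
need an inspectable, scriptable reference pipeline for actigraphy-style
movement analysis.

## Worked example

```python
import datetime
from actisphere.synth import ProfileConfig, generate_recording
from actisphere.metrics import compute_report

cfg = ProfileConfig(days=0.55, seed=7,
                    start_clock=datetime.datetime(2022, 1, 10, 7, 0))
rec = generate_recording(cfg)           # 13 h of daytime activity
rep = compute_report(rec)
print(f"samples          : {rec.n_samples}")
print(f"HAF              : {rep.haf:.3f}")
print(f"AAI |log10 nR/nL|: {rep.aai:.4f}  (n_R={rep.n_right}, n_L={rep.n_left})")
print(f"sleep hours      : {rep.sleep_hours:.2f}")
print("activity amp g*s :", {k: round(v, 1) for k, v in rep.activity_amplitude.items()})
print("per time zone    :", {k: round(v, 1) for k, v in rep.aa_by_timezone.items()})
print(f"transitions      : {rep.n_transitions}")
```

prints:

```
samples          : 4752000
HAF              : -3.060
AAI |log10 nR/nL|: 0.0674  (n_R=1882, n_L=2198)
sleep hours      : 0.00
activity amp g*s : {'low': 17.1, 'medium': 72.0, 'high': 129.2}
per time zone    : {1: 0.0, 2: 107.4, 3: 92.5, 4: 18.3}
transitions      : 284
```

Reading: about 1 in 10^3.06 ≈ 1/1150 of the daytime south-polar-cap
samples exceeded 2 g; the left/right high-acceleration counts are nearly
balanced (α ≈ 0.07 — this profile is a symmetric mover, so the index
sits near 0); no sleep was detected in a daytime-only recording; and
activity amplitude concentrates in the morning/afternoon zones.  A
stroke-like profile (`amp_scale=0.6, asymmetry_factor=2.5`) shifts α
toward `log10(2.5) ≈ 0.4` and shrinks every amplitude band.

The same pipeline from the shell:

```bash
actisphere synth --seed 7 --days 0.25 --out rec.csv
actisphere visualize rec.csv --out-dir viz --statistic prob --log-scale
actisphere extract rec.csv --out windows.h5
actisphere metrics rec.csv --out report.json
actisphere train windows.h5 --epochs 10 --out model.npz
actisphere eval windows.h5 model.npz --out roc.csv
```

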