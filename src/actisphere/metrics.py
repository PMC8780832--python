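"""Scalar and banded movement metrics for multi-day recordings.

The metrics quantify stroke-relevant aspects of everyday movement:

* higher-acceleration fraction (HAF): log of the fraction of daytime,
  south-polar-cap samples whose magnitude exceeds 2 g — a sedentary /
  vigour measure (always <= 0);
* acceleration asymmetry index (AAI): |log(n_R / n_L)| of high-acceleration
  sample counts on the right (phi < 0) versus left (phi >= 0) side — near 0
  for symmetric movers, growing with lateralized impairment;
* sleep detection from the x-z-plane resultant R_a,xz = sqrt(ax^2 + az^2),
  which is ~1 g when supine and ~0 when upright: 1-s blocks whose
  mean +/- variance lies within [0.97, 1.02] g are flagged as sleep;
* activity amplitudes: time integrals of the detrended resultant
  acceleration DRA = ||a| - 1| over activity epochs, banded by peak DRA
  (low/medium/high) and credited to six-hour time zones;
* movement transitions: short (<= 3 s trough-to-trough) prominent peaks of
  |a|, with per-transition max/min/rms/range/duration statistics;
* a complex-Morlet-wavelet spectrogram of |a| for time-frequency structure.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .extraction import SelectionCriteria, daytime_mask
from .imu_io import IMURecording
from .uas import to_spherical

HIGH_ACCEL_THRESHOLD_G = 2.0


def selection_mask(rec: IMURecording, crit: SelectionCriteria | None = None) -> np.ndarray:
    """Daytime + elevation mask used by HAF and AAI (no bin filter)."""
    crit = crit or SelectionCriteria()
    theta = np.asarray(to_spherical(rec.accel).theta)
    return (theta <= crit.theta_max) & daytime_mask(rec, crit)


def higher_acceleration_fraction(
    rec: IMURecording,
    crit: SelectionCriteria | None = None,
    threshold_g: float = HIGH_ACCEL_THRESHOLD_G,
    log_base: float = 10.0,
) -> float:
    """HAF = log(count(|a| > threshold) / count(selected)).

    Computed over daytime samples in the south polar cap.  Returns NaN (the
    "none above threshold" sentinel, rather than -inf) when no selected
    sample exceeds the threshold; raises if the selection itself is empty.
    """
    mask = selection_mask(rec, crit)
    total = int(mask.sum())
    if total == 0:
        raise ValueError("no samples pass the daytime + elevation selection")
    above = int((rec.magnitude()[mask] > threshold_g).sum())
    if above == 0:
        return math.nan
    return math.log(above / total, log_base)


@dataclass
class AAIResult:
    """Asymmetry index with its side counts.

    ``aai`` is |log(n_R / n_L)|; ``signed`` keeps the sign (positive when
    the right side dominates).  Both are NaN when either side has no
    high-acceleration samples.
    """

    aai: float
    signed: float
    n_left: int
    n_right: int


def acceleration_asymmetry_index(
    rec: IMURecording,
    crit: SelectionCriteria | None = None,
    threshold_g: float = HIGH_ACCEL_THRESHOLD_G,
    log_base: float = 10.0,
) -> AAIResult:
    """Acceleration asymmetry index from high-acceleration sample counts.

    Among daytime south-polar-cap samples with |a| > threshold, n_R counts
    those directed to the wearer's right (phi < 0) and n_L to the left
    (phi >= 0).
    """
    mask = selection_mask(rec, crit)
    sp = to_spherical(rec.accel)
    high = mask & (np.asarray(sp.rho) > threshold_g)
    phi = np.asarray(sp.phi)[high]
    n_right = int((phi < 0).sum())
    n_left = int((phi >= 0).sum())
    if n_right == 0 or n_left == 0:
        return AAIResult(math.nan, math.nan, n_left, n_right)
    signed = math.log(n_right / n_left, log_base)
    return AAIResult(abs(signed), signed, n_left, n_right)


def detect_sleep(
    rec: IMURecording,
    lo_g: float = 0.97,
    hi_g: float = 1.02,
    window_s: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Sleep mask and total sleep hours from the x-z-plane resultant.

    The recording is split into consecutive ``window_s`` blocks; a block is
    flagged as sleep when mean(R_a,xz) - var(R_a,xz) >= ``lo_g`` and
    mean + var <= ``hi_g`` (supine stillness keeps R_a,xz pinned near 1 g).
    Returns the per-sample mask and the flagged duration in hours.
    """
    w = int(round(window_s * rec.sample_rate_hz))
    if rec.n_samples < w:
        return np.zeros(rec.n_samples, dtype=bool), 0.0
    r_xz = np.hypot(rec.accel[:, 0], rec.accel[:, 2])
    n_blocks = rec.n_samples // w
    blocks = r_xz[: n_blocks * w].reshape(n_blocks, w)
    mean = blocks.mean(axis=1)
    var = blocks.var(axis=1)
    flagged = (mean - var >= lo_g) & (mean + var <= hi_g)
    mask = np.zeros(rec.n_samples, dtype=bool)
    mask[: n_blocks * w] = np.repeat(flagged, w)
    sleep_hours = float(flagged.sum()) * window_s / 3600.0
    return mask, sleep_hours


TIME_ZONE_BOUNDS_H = (0, 6, 12, 18, 24)  # zones 1..4


def time_zone_of(second_of_day: float) -> int:
    """Six-hour time zone (1..4) of a wall-clock second-of-day."""
    hour = (second_of_day % 86400.0) / 3600.0
    for zone, (lo, hi) in enumerate(
        zip(TIME_ZONE_BOUNDS_H[:-1], TIME_ZONE_BOUNDS_H[1:]), start=1
    ):
        if lo <= hour < hi:
            return zone
    return 4


@dataclass
class AmplitudeReport:
    """Activity-amplitude totals (g*s) by band and by six-hour time zone."""

    by_band: dict[str, float]
    by_zone: dict[int, float]
    n_epochs: int


def activity_amplitude(
    rec: IMURecording,
    band_thresholds: tuple[float, float] = (0.1, 0.3),
    epoch_threshold_g: float = 0.05,
) -> AmplitudeReport:
    """Integrate the detrended resultant acceleration over activity epochs.

    DRA = ||a| - 1 g|.  An epoch is a contiguous run with DRA above
    ``epoch_threshold_g`` (a noise floor; accelerometer noise keeps DRA
    strictly positive almost everywhere, so literal supra-zero runs would
    merge the whole recording).  Each epoch's amplitude is the Riemann
    integral dt * sum(DRA); it is banded low/medium/high by its peak DRA
    against ``band_thresholds`` and credited to the time zone of its start.
    """
    t_low, t_high = band_thresholds
    if not (epoch_threshold_g < t_low < t_high):
        raise ValueError("band thresholds must satisfy epoch < low < high cut")
    dra = np.abs(rec.magnitude() - 1.0)
    active = dra > epoch_threshold_g
    by_band = {"low": 0.0, "medium": 0.0, "high": 0.0}
    by_zone = {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}
    sod = rec.seconds_of_day()
    dt_s = 1.0 / rec.sample_rate_hz
    n_epochs = 0
    padded = np.diff(np.concatenate(([0], active.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    for s, e in zip(starts, stops):
        seg = dra[s:e]
        amp = float(seg.sum()) * dt_s
        peak = float(seg.max())
        band = "low" if peak < t_low else ("medium" if peak < t_high else "high")
        by_band[band] += amp
        by_zone[time_zone_of(float(sod[s]))] += amp
        n_epochs += 1
    return AmplitudeReport(by_band, by_zone, n_epochs)


@dataclass
class Transition:
    """One short movement transition and its |a| segment statistics."""

    peak_index: int
    start_index: int
    stop_index: int
    max: float
    min: float
    rms: float
    range: float
    duration_s: float


def detect_transitions(
    rec: IMURecording,
    prominence_g: float = 0.2,
    min_separation_s: float = 1.0,
    max_span_s: float = 3.0,
    edge_tol_g: float = 0.02,
    edge_dwell_s: float = 0.3,
) -> list[Transition]:
    """Detect short postural transitions as prominent, brief |a| peaks.

    Peaks of |a| with at least ``prominence_g`` prominence and
    ``min_separation_s`` separation are found; each peak's segment extends
    to the nearest *held* baseline (|a| within ``edge_tol_g`` of 1 g for at
    least ``edge_dwell_s`` continuously) on either side.  A peak qualifies
    as a transition when that trough-to-trough span is at most
    ``max_span_s`` — sustained rhythmic activity such as a gait bout only
    grazes 1 g momentarily and never holds it, so it is excluded.
    Statistics (max, min, rms, range, duration) are computed on the
    segment.
    """
    mag = rec.magnitude()
    distance = max(1, int(round(min_separation_s * rec.sample_rate_hz)))
    peaks, _ = signal.find_peaks(mag, prominence=prominence_g, distance=distance)
    near = np.abs(mag - 1.0) <= edge_tol_g
    # keep only near-baseline samples belonging to runs held >= edge_dwell_s
    dwell = max(1, int(round(edge_dwell_s * rec.sample_rate_hz)))
    edges = np.diff(np.concatenate(([0], near.astype(np.int8), [0])))
    near_base = np.zeros_like(near)
    for s, e in zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)):
        if e - s >= dwell:
            near_base[s:e] = True
    out: list[Transition] = []
    max_span = max_span_s * rec.sample_rate_hz
    for p in peaks:
        left_candidates = np.flatnonzero(near_base[: p + 1])
        right_candidates = np.flatnonzero(near_base[p:])
        if left_candidates.size == 0 or right_candidates.size == 0:
            continue
        left = int(left_candidates[-1])
        right = int(p + right_candidates[0])
        if right - left > max_span:
            continue
        seg = mag[left : right + 1]
        out.append(
            Transition(
                peak_index=int(p),
                start_index=left,
                stop_index=right,
                max=float(seg.max()),
                min=float(seg.min()),
                rms=float(np.sqrt(np.mean(seg**2))),
                range=float(seg.max() - seg.min()),
                duration_s=(right - left) / rec.sample_rate_hz,
            )
        )
    return out


def cmw_spectrogram(
    rec: IMURecording,
    freqs: Sequence[float],
    cycles: float = 7.0,
) -> np.ndarray:
    """Complex-Morlet-wavelet power of the mean-removed |a| signal.

    Each kernel is a complex sine at frequency f multiplied by a Gaussian
    whose SD is ``cycles / (2 pi f)`` seconds, truncated at +/- 4 SD and
    normalized to unit energy.  Returns power (squared magnitude) shaped
    (len(freqs), n_samples).  Raises when a kernel would be longer than the
    signal.
    """
    freqs = np.asarray(freqs, dtype=float)
    nyquist = rec.sample_rate_hz / 2.0
    if np.any(freqs <= 0) or np.any(freqs >= nyquist):
        raise ValueError("frequencies must lie strictly within (0, Nyquist)")
    x = rec.magnitude()
    x = x - x.mean()
    fs = rec.sample_rate_hz
    rows = []
    for f in freqs:
        sd = cycles / (2 * np.pi * f)
        half = int(np.ceil(4 * sd * fs))
        if 2 * half + 1 > x.size:
            raise ValueError(
                f"kernel for {f} Hz ({2 * half + 1} samples) exceeds signal length"
            )
        t = np.arange(-half, half + 1) / fs
        kernel = np.exp(2j * np.pi * f * t) * np.exp(-(t**2) / (2 * sd**2))
        kernel /= np.linalg.norm(kernel)
        conv = signal.fftconvolve(x, kernel, mode="same")
        rows.append(np.abs(conv) ** 2)
    return np.stack(rows)


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Cohen's d with (n-1)-weighted pooled SD; NaN when the pooled SD is 0."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least two values")
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 0.0
        return math.nan
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


@dataclass
class MetricReport:
    """Per-recording movement metrics, serializable to JSON."""

    haf: float
    aai: float
    aai_signed: float
    n_left: int
    n_right: int
    sleep_hours: float
    activity_amplitude: dict[str, float]
    aa_by_timezone: dict[int, float]
    n_transitions: int
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["aa_by_timezone"] = {str(k): v for k, v in self.aa_by_timezone.items()}
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def compute_report(
    rec: IMURecording,
    crit: SelectionCriteria | None = None,
    band_thresholds: tuple[float, float] = (0.1, 0.3),
    threshold_g: float = HIGH_ACCEL_THRESHOLD_G,
    log_base: float = 10.0,
) -> MetricReport:
    """Compute the full metric suite for one recording."""
    crit = crit or SelectionCriteria()
    try:
        haf = higher_acceleration_fraction(rec, crit, threshold_g, log_base)
    except ValueError:
        haf = math.nan
    aai = acceleration_asymmetry_index(rec, crit, threshold_g, log_base)
    _, sleep_hours = detect_sleep(rec)
    amps = activity_amplitude(rec, band_thresholds)
    transitions = detect_transitions(rec)
    return MetricReport(
        haf=haf,
        aai=aai.aai,
        aai_signed=aai.signed,
        n_left=aai.n_left,
        n_right=aai.n_right,
        sleep_hours=sleep_hours,
        activity_amplitude=amps.by_band,
        aa_by_timezone=amps.by_zone,
        n_transitions=len(transitions),
        config={
            "selection_criteria": crit.to_dict(),
            "band_thresholds": list(band_thresholds),
            "high_accel_threshold_g": threshold_g,
            "log_base": log_base,
        },
    )


def batch_report_csv(
    reports: Mapping[str, MetricReport], path: str | Path
) -> None:
    """Write one CSV row per recording for cohort-level comparisons."""
    import pandas as pd

    rows = []
    for name, r in reports.items():
        row = {
            "recording": name,
            "haf": r.haf,
            "aai": r.aai,
            "aai_signed": r.aai_signed,
            "n_left": r.n_left,
            "n_right": r.n_right,
            "sleep_hours": r.sleep_hours,
            "n_transitions": r.n_transitions,
        }
        row.update({f"aa_{band}": v for band, v in r.activity_amplitude.items()})
        row.update({f"aa_zone{z}": v for z, v in r.aa_by_timezone.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
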