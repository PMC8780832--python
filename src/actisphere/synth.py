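"""Seeded generator of realistic multi-day waist-worn IMU recordings.

The generator emulates the study conditions the rest of the package is
designed for: 1-3 day recordings at 100 Hz from a sensor at the low back,
with gravity along -y when upright.  A recording is a piecewise signal:

* upright rest: a = [0, -1, 0] g plus white noise (the south pole of the
  unit acceleration sphere);
* supine sleep inside configured wall-clock windows: a = [0, 0, -1] g plus
  noise, which pins the x-z resultant near 1 g (the sleep-detector band);
* gait bouts: Poisson-arriving, amplitude-modulated sinusoids (fundamental
  ~1.8 Hz plus a harmonic) superposed on gravity, with small lateral sway,
  at per-time-zone hourly rates;
* sporadic high-acceleration events (|a| > 2 g, ~0.25 s) whose azimuthal
  direction is biased right (phi < 0) with probability
  asymmetry_factor / (1 + asymmetry_factor) — the "stroke-like" lateral
  asymmetry dial;
* gyro channels as smoothed noise with bout-locked oscillation (plumbing).

``amp_scale`` < 1 scales all movement amplitudes down, emulating the
reduced activity amplitudes of stroke profiles.  Everything is a pure
function of the seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .imu_io import DEFAULT_START_CLOCK, IMURecording
from .uas import SpherePoint, spherical_to_cartesian

#: peak-DRA ranges (g) from which bout amplitudes are drawn, per band.
BAND_AMP_RANGES = {"low": (0.055, 0.095), "medium": (0.11, 0.28), "high": (0.32, 0.7)}


def _parse_clock(value: str) -> float:
    """'HH:MM' -> seconds of day."""
    h, m = value.split(":")
    return int(h) * 3600.0 + int(m) * 60.0


@dataclass(frozen=True)
class ProfileConfig:
    """Generator parameters for one subject profile.

    Defaults describe a healthy older adult over three days: nocturnal
    sleep 23:00-07:00, a few gait bouts per daytime hour, stride frequency
    1.8 +/- 0.3 Hz, mostly low/medium-amplitude bouts, symmetric
    high-acceleration events at 24 per awake-daytime hour (enough counts
    for a stable left/right log-ratio), and 0.01 g sensor noise.
    Stroke-like profiles raise ``asymmetry_factor`` above 1, lower
    ``amp_scale`` below 1 and reduce ``high_g_event_rate``.
    """

    days: float = 3.0
    sample_rate_hz: float = 100.0
    sleep_windows: tuple[tuple[str, str], ...] = (("23:00", "07:00"),)
    gait_bout_rate_per_hour: tuple[float, float, float, float] = (0.2, 5.0, 5.0, 2.5)
    gait_freq_hz: tuple[float, float] = (1.8, 0.3)
    bout_amp_weights: tuple[float, float, float] = (0.5, 0.35, 0.15)
    bout_duration_s: tuple[float, float] = (30.0, 90.0)
    asymmetry_factor: float = 1.0
    amp_scale: float = 1.0
    tremor_amp_g: float = 0.0
    tremor_freq_hz: float = 6.0
    high_g_event_rate: float = 24.0
    high_g_peak_g: tuple[float, float] = (2.2, 3.0)
    high_g_duration_s: float = 0.25
    noise_sd_g: float = 0.01
    gyro_noise_sd: float = 4.0
    seed: int = 0
    start_clock: dt.datetime = DEFAULT_START_CLOCK

    def __post_init__(self) -> None:
        if self.asymmetry_factor < 1.0:
            raise ValueError("asymmetry_factor must be >= 1")
        if any(r < 0 for r in self.gait_bout_rate_per_hour) or self.high_g_event_rate < 0:
            raise ValueError("rates must be >= 0")
        if abs(sum(self.bout_amp_weights) - 1.0) > 1e-9:
            raise ValueError("bout_amp_weights must sum to 1")
        self._check_sleep_overlap()

    def _check_sleep_overlap(self) -> None:
        covered = np.zeros(1440, dtype=bool)  # minute-of-day occupancy
        for start, end in self.sleep_windows:
            s = int(_parse_clock(start) // 60)
            e = int(_parse_clock(end) // 60)
            minutes = (
                list(range(s, e)) if s < e else list(range(s, 1440)) + list(range(0, e))
            )
            if covered[minutes].any():
                raise ValueError("sleep windows overlap")
            covered[minutes] = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["start_clock"] = self.start_clock.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileConfig":
        d = dict(d)
        if isinstance(d.get("start_clock"), str):
            d["start_clock"] = dt.datetime.fromisoformat(d["start_clock"])
        for key in ("sleep_windows", "gait_bout_rate_per_hour", "gait_freq_hz",
                    "bout_amp_weights", "bout_duration_s", "high_g_peak_g"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(tuple(v) if isinstance(v, list) else v for v in d[key]) \
                    if key == "sleep_windows" else tuple(d[key])
        return cls(**d)


def _sleep_mask(cfg: ProfileConfig, seconds_of_day: np.ndarray) -> np.ndarray:
    mask = np.zeros(seconds_of_day.shape, dtype=bool)
    for start, end in cfg.sleep_windows:
        s, e = _parse_clock(start), _parse_clock(end)
        if s < e:
            mask |= (seconds_of_day >= s) & (seconds_of_day < e)
        else:  # wraps midnight
            mask |= (seconds_of_day >= s) | (seconds_of_day < e)
    return mask


def _draw_bout_amplitude(rng: np.random.Generator, cfg: ProfileConfig) -> float:
    band = rng.choice(("low", "medium", "high"), p=cfg.bout_amp_weights)
    lo, hi = BAND_AMP_RANGES[band]
    return float(rng.uniform(lo, hi)) * cfg.amp_scale


def _stamp_bout(
    accel: np.ndarray,
    gyro: np.ndarray,
    rng: np.random.Generator,
    cfg: ProfileConfig,
    start_idx: int,
    n_bout: int,
) -> None:
    """Superpose one gait bout on gravity.

    The waveform is a fundamental at the stride frequency plus a weaker
    harmonic, amplitude-modulated by a raised-sine envelope and by slow
    stride-to-stride jitter, with small lateral sway and fore-aft
    components.  A constant postural tilt (torso lean, 3-7 degrees) holds
    the bout's orientations away from the upright-rest bins, as walking
    does in real torso recordings.  Component amplitudes are bounded so the
    elevation stays in the south polar cap (theta < -pi/3) throughout.
    """
    fs = cfg.sample_rate_hz
    amp = min(_draw_bout_amplitude(rng, cfg), 0.55)
    freq = max(0.5, rng.normal(*cfg.gait_freq_hz))
    tau = np.arange(n_bout) / fs
    envelope = np.sin(np.pi * tau / tau[-1]) ** 2 if n_bout > 1 else np.ones(1)
    ph2, ph_lat, tilt_dir = rng.uniform(0, 2 * np.pi, size=3)
    # stride-to-stride amplitude variability (~12%, lowpassed at stride scale)
    slow = uniform_filter1d(rng.standard_normal(n_bout), size=max(3, int(fs / freq)))
    sd = slow.std()
    jitter = 1.0 + 0.12 * (slow / sd if sd > 0 else slow)
    np.clip(jitter, 0.6, 1.4, out=jitter)
    wave = np.sin(2 * np.pi * freq * tau) + 0.25 * np.sin(4 * np.pi * freq * tau + ph2)
    wave /= np.max(np.abs(wave))
    # hemiparetic step-to-step asymmetry: strides alternate between the two
    # legs at half the fundamental frequency; the affected-side stride's
    # vertical push-off is attenuated by the asymmetry factor (1 = none),
    # which imprints a subharmonic "limp" on the waveform
    stride_side = np.sin(np.pi * freq * tau + ph_lat)
    affected = stride_side < 0
    wave = np.where(affected, wave / cfg.asymmetry_factor, wave)
    vert = amp * envelope * jitter * wave
    if cfg.tremor_amp_g > 0:
        # spasticity/clonus-like oscillation riding on movement
        ph_tr = rng.uniform(0, 2 * np.pi)
        tremor = cfg.tremor_amp_g * envelope * np.sin(
            2 * np.pi * cfg.tremor_freq_hz * tau + ph_tr
        )
        vert = vert + tremor
    tilt = rng.uniform(0.06, 0.12)
    sway = np.where(affected, stride_side / cfg.asymmetry_factor, stride_side)
    lateral = envelope * (tilt * np.sin(tilt_dir) + 0.12 * amp * sway)
    fore_aft = envelope * (
        tilt * np.cos(tilt_dir) + 0.06 * amp * np.sin(2 * np.pi * freq * tau + ph2)
    )
    sl = slice(start_idx, start_idx + n_bout)
    accel[sl, 0] += lateral
    accel[sl, 1] -= vert
    accel[sl, 2] += fore_aft
    gyro[sl, 0] += 40.0 * amp * envelope * np.sin(2 * np.pi * freq * tau)
    gyro[sl, 2] += 25.0 * amp * envelope * np.sin(np.pi * freq * tau + ph_lat)


def _stamp_event(
    accel: np.ndarray,
    rng: np.random.Generator,
    cfg: ProfileConfig,
    start_idx: int,
) -> None:
    fs = cfg.sample_rate_hz
    n_ev = max(3, int(round(cfg.high_g_duration_s * fs)))
    if start_idx + n_ev > accel.shape[0]:
        return
    peak = rng.uniform(*cfg.high_g_peak_g)
    theta = rng.uniform(-1.45, -1.10)  # stay inside the south polar cap
    p_right = cfg.asymmetry_factor / (1.0 + cfg.asymmetry_factor)
    sign = -1.0 if rng.random() < p_right else 1.0  # phi < 0 is the right side
    phi = sign * rng.uniform(0.3, 1.2)
    direction = spherical_to_cartesian(SpherePoint(1.0, theta, phi))
    tau = np.arange(n_ev) / (n_ev - 1)
    mag = 1.0 + (peak - 1.0) * np.sin(np.pi * tau)
    accel[start_idx : start_idx + n_ev] = direction[None, :] * mag[:, None]


def generate_recording(cfg: ProfileConfig) -> IMURecording:
    """Generate one recording; deterministic given ``cfg`` (incl. its seed)."""
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate_hz
    n = int(round(cfg.days * 86400.0 * fs))
    timestamps = np.arange(n) / fs
    start_sec = (
        cfg.start_clock.hour * 3600 + cfg.start_clock.minute * 60 + cfg.start_clock.second
    )
    sod = (start_sec + timestamps) % 86400.0

    accel = np.zeros((n, 3))
    accel[:, 1] = -1.0  # upright rest
    sleep = _sleep_mask(cfg, sod)
    accel[sleep, 1] = 0.0
    accel[sleep, 2] = -1.0  # supine

    gyro = np.zeros((n, 3))

    # gait bouts, per-hour Poisson arrivals at the hour's time-zone rate
    from .metrics import time_zone_of  # zone bounds live with the metrics

    n_hours = int(math.ceil(cfg.days * 24.0))
    for h in range(n_hours):
        hour_start_s = h * 3600.0
        zone = time_zone_of(start_sec + hour_start_s + 1.0)
        rate = cfg.gait_bout_rate_per_hour[zone - 1]
        for _ in range(rng.poisson(rate)):
            t0 = hour_start_s + rng.uniform(0, 3600.0)
            dur = rng.uniform(*cfg.bout_duration_s)
            i0 = int(round(t0 * fs))
            n_bout = int(round(dur * fs))
            if i0 + n_bout > n:
                continue
            if sleep[i0 : i0 + n_bout].any():
                continue
            _stamp_bout(accel, gyro, rng, cfg, i0, n_bout)

    # high-acceleration events in awake daytime (07:00-20:00)
    awake_day = ~sleep & (sod >= 7 * 3600.0) & (sod < 20 * 3600.0)
    eligible = np.flatnonzero(awake_day)
    if eligible.size and cfg.high_g_event_rate > 0:
        awake_hours = eligible.size / fs / 3600.0
        n_events = rng.poisson(cfg.high_g_event_rate * awake_hours)
        if n_events:
            starts = np.sort(rng.choice(eligible, size=n_events, replace=False))
            for i0 in starts:
                _stamp_event(accel, rng, cfg, int(i0))

    accel += rng.normal(0.0, cfg.noise_sd_g, size=(n, 3))
    gyro += uniform_filter1d(
        rng.normal(0.0, cfg.gyro_noise_sd, size=(n, 3)), size=9, axis=0
    )
    return IMURecording(
        timestamps,
        accel,
        gyro,
        sample_rate_hz=fs,
        start_clock=cfg.start_clock,
        subject_meta={"seed": cfg.seed},
    )


def generate_pulse_train(
    n_pulses: int,
    pulse_amp_g: float = 0.5,
    pulse_s: float = 2.0,
    gap_s: float = 8.0,
    lead_s: float = 5.0,
    sample_rate_hz: float = 100.0,
    noise_sd_g: float = 0.0,
    seed: int = 0,
) -> IMURecording:
    """Upright rest with ``n_pulses`` rectangular |a| excursions.

    Each pulse raises |a| to ``1 + pulse_amp_g`` for ``pulse_s`` seconds —
    a minimal stand-in for sit-to-stand-like transitions, used to validate
    planted-event recovery by the transition detector.
    """
    fs = sample_rate_hz
    total_s = lead_s + n_pulses * (pulse_s + gap_s) + lead_s
    n = int(round(total_s * fs))
    timestamps = np.arange(n) / fs
    accel = np.zeros((n, 3))
    accel[:, 1] = -1.0
    for k in range(n_pulses):
        t0 = lead_s + k * (pulse_s + gap_s)
        i0, i1 = int(round(t0 * fs)), int(round((t0 + pulse_s) * fs))
        accel[i0:i1, 1] = -(1.0 + pulse_amp_g)
    if noise_sd_g:
        rng = np.random.default_rng(seed)
        accel += rng.normal(0.0, noise_sd_g, size=(n, 3))
    gyro = np.zeros((n, 3))
    return IMURecording(timestamps, accel, gyro, sample_rate_hz=fs)


#: group BMI distributions (mean, SD) used when drawing cohort subjects.
BMI_DISTRIBUTIONS = {"healthy": (26.1, 3.0), "stroke": (30.8, 5.6)}


@dataclass
class CohortSubject:
    """One generated subject: recording plus group label and metadata."""

    recording: IMURecording
    label: str
    bmi: float
    seed: int
    config: ProfileConfig


def _subject_config(
    base: ProfileConfig,
    label: str,
    bmi: float,
    seed: int,
    rng: np.random.Generator,
    bmi_event_slope: float,
) -> ProfileConfig:
    mean, sd = BMI_DISTRIBUTIONS[label]
    if label == "healthy":
        asym = rng.uniform(1.0, 1.25)
        amp = rng.uniform(0.9, 1.1)
        rate_scale = 1.0
        freq_scale = 1.0
        tremor = 0.0
    else:
        asym = rng.uniform(1.8, 3.2)
        amp = rng.uniform(0.5, 0.75)
        rate_scale = 0.5
        freq_scale = 0.75  # hemiparetic gait is slower-cadenced
        tremor = rng.uniform(0.08, 0.14)  # spasticity/clonus-like oscillation
    # negative BMI coupling, linear in log event rate
    rate_scale *= 10.0 ** (-bmi_event_slope * (bmi - mean) / sd)
    bout_rates = tuple(
        r * rng.uniform(0.8, 1.2) for r in base.gait_bout_rate_per_hour
    )
    return dataclasses.replace(
        base,
        seed=seed,
        asymmetry_factor=asym,
        amp_scale=amp,
        high_g_event_rate=base.high_g_event_rate * rate_scale,
        gait_bout_rate_per_hour=bout_rates,
        gait_freq_hz=(base.gait_freq_hz[0] * freq_scale, base.gait_freq_hz[1]),
        tremor_amp_g=tremor,
    )


def generate_cohort(
    n_healthy: int = 14,
    n_stroke: int = 14,
    base_healthy: ProfileConfig | None = None,
    base_stroke: ProfileConfig | None = None,
    seed: int = 0,
    bmi_event_slope: float = 0.1,
) -> list[CohortSubject]:
    """Generate a labelled cohort with per-subject jittered configurations.

    Stroke subjects receive asymmetry_factor > 1, amp_scale < 1 and a
    reduced high-acceleration event rate; BMI is drawn per group (healthy
    26.1 +/- 3.0, stroke 30.8 +/- 5.6 kg/m^2) and couples negatively to the
    event rate.  Deterministic given ``seed``.
    """
    base_healthy = base_healthy or ProfileConfig()
    base_stroke = base_stroke or base_healthy
    master = np.random.default_rng(seed)
    subjects: list[CohortSubject] = []
    plan = [("healthy", base_healthy)] * n_healthy + [("stroke", base_stroke)] * n_stroke
    for k, (label, base) in enumerate(plan):
        sub_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        mean, sd = BMI_DISTRIBUTIONS[label]
        bmi = float(rng.normal(mean, sd))
        cfg = _subject_config(base, label, bmi, sub_seed, rng, bmi_event_slope)
        rec = generate_recording(cfg)
        assert rec.subject_meta is not None
        rec.subject_meta.update({"group": label, "bmi": bmi, "subject": k})
        subjects.append(CohortSubject(rec, label, bmi, sub_seed, cfg))
    return subjects


def cohort_manifest_csv(subjects: Sequence[CohortSubject], path: str | Path) -> None:
    """Write subject id, label, BMI and seed for a generated cohort."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "subject": s.recording.subject_meta.get("subject", i),
                "label": s.label,
                "bmi": s.bmi,
                "seed": s.seed,
            }
            for i, s in enumerate(subjects)
        ]
    ).to_csv(path, index=False)
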