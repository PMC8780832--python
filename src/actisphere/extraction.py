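"""Information-rich window selection for sequence classification.

Multi-day recordings are dominated by rest and sleep, which carry little
movement information.  Selection keeps only samples that (1) sit in the
south-polar cap of the unit acceleration sphere (theta in [-pi/2, -pi/3] at
defaults — the neighbourhood of the upright-standing gravity direction),
(2) fall inside the daytime window (07:00-20:00 at defaults), and (3) land
in orientation bins whose |a| statistics show actual movement (bin SD of
|a| >= 0.02 g combined with |mean |a| - 1 g| > 0.02 g).  Surviving samples
are cut into contiguous, non-overlapping 3-s windows of 12 channels each
(a_x, a_y, a_z, w_x, w_y, w_z, |a|, the three unit-sphere components,
theta, phi) for the recurrent classifier.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .imu_io import IMURecording
from .uas import BinGrid, bin_index, to_spherical

FEATURE_NAMES = (
    "ax", "ay", "az", "wx", "wy", "wz",
    "a_mag", "ax_s", "ay_s", "az_s", "theta", "phi",
)
N_FEATURES = len(FEATURE_NAMES)


def _parse_time(value: str | dt.time) -> dt.time:
    if isinstance(value, dt.time):
        return value
    return dt.time.fromisoformat(value)


@dataclass(frozen=True)
class SelectionCriteria:
    """Filters defining which samples are information-rich.

    ``combine_rule`` joins the two bin-statistic conditions: ``"OR"`` (the
    default) accepts a bin showing either elevated SD of |a| or a mean |a|
    away from 1 g — equivalently it excludes exactly the bins that are both
    low-variability and near-gravity, i.e. the rest bins; ``"AND"`` requires
    both signs of movement simultaneously, which in practice interrupts
    contiguous movement runs wherever a bin's mean |a| crosses 1 g
    mid-bout, and is kept as a stricter alternative.
    """

    theta_max: float = -np.pi / 3
    sd_min: float = 0.02
    mean_dev_min: float = 0.02
    day_start: dt.time = dt.time(7, 0)
    day_end: dt.time = dt.time(20, 0)
    combine_rule: str = "OR"

    def __post_init__(self) -> None:
        if self.theta_max >= 0:
            raise ValueError("theta_max must be negative (south polar cap)")
        if self.sd_min < 0 or self.mean_dev_min < 0:
            raise ValueError("sd_min and mean_dev_min must be >= 0")
        object.__setattr__(self, "day_start", _parse_time(self.day_start))
        object.__setattr__(self, "day_end", _parse_time(self.day_end))
        if self._sec(self.day_start) >= self._sec(self.day_end):
            raise ValueError("day_start must precede day_end")
        if self.combine_rule not in ("AND", "OR"):
            raise ValueError("combine_rule must be 'AND' or 'OR'")

    @staticmethod
    def _sec(t: dt.time) -> float:
        return t.hour * 3600 + t.minute * 60 + t.second

    def to_dict(self) -> dict:
        return {
            "theta_max": self.theta_max,
            "sd_min": self.sd_min,
            "mean_dev_min": self.mean_dev_min,
            "day_start": self.day_start.isoformat(),
            "day_end": self.day_end.isoformat(),
            "combine_rule": self.combine_rule,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionCriteria":
        return cls(**d)


@dataclass
class WindowSample:
    """One fixed-length training sample: (timesteps, 12) features + label."""

    features: np.ndarray
    label: str | None
    start_clock: dt.datetime


def daytime_mask(rec: IMURecording, crit: SelectionCriteria) -> np.ndarray:
    """True where a sample's wall-clock time lies in [day_start, day_end)."""
    sod = rec.seconds_of_day()
    return (sod >= crit._sec(crit.day_start)) & (sod < crit._sec(crit.day_end))


def select_samples(
    rec: IMURecording, grid: BinGrid, crit: SelectionCriteria | None = None
) -> np.ndarray:
    """Boolean mask of information-rich samples.

    A sample passes when its elevation lies in [-pi/2, theta_max], its
    wall-clock time in the daytime window, and its 1-degree bin passes the
    SD / mean-deviation filter under ``combine_rule``.  ``grid`` is normally
    computed from ``rec`` itself (per-subject); a reference grid of matching
    sample count is also accepted.
    """
    crit = crit or SelectionCriteria()
    if grid.n_total != rec.n_samples:
        raise ValueError(
            f"grid built from {grid.n_total} samples does not match "
            f"recording of {rec.n_samples}"
        )
    sp = to_spherical(rec.accel)
    theta_ok = np.asarray(sp.theta) <= crit.theta_max
    day_ok = daytime_mask(rec, crit)
    i, j = bin_index(sp)
    bin_mean = grid.mean_a[i - 1, j - 1]
    bin_sd = grid.sd_a[i - 1, j - 1]
    sd_ok = bin_sd >= crit.sd_min
    mean_ok = np.abs(bin_mean - 1.0) > crit.mean_dev_min
    if crit.combine_rule == "AND":
        bin_ok = sd_ok & mean_ok
    else:
        bin_ok = sd_ok | mean_ok
    return theta_ok & day_ok & bin_ok


def _contiguous_runs(mask: np.ndarray, timestamps: np.ndarray, max_dt: float):
    """Yield (start, stop) index pairs of masked runs without timestamp gaps."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    # break where indices are non-consecutive or the clock jumps
    gaps = np.flatnonzero(
        (np.diff(idx) != 1) | (np.diff(timestamps[idx]) > max_dt)
    )
    starts = np.concatenate(([0], gaps + 1))
    stops = np.concatenate((gaps + 1, [idx.size]))
    for s, e in zip(starts, stops):
        yield int(idx[s]), int(idx[e - 1]) + 1


def window_features(rec: IMURecording, start: int, stop: int) -> np.ndarray:
    """Assemble the 12-channel feature matrix for samples [start, stop)."""
    accel = rec.accel[start:stop]
    gyro = rec.gyro[start:stop]
    sp = to_spherical(accel)
    mag = np.asarray(sp.rho)
    unit = accel / mag[:, None]
    return np.column_stack(
        [accel, gyro, mag, unit, np.asarray(sp.theta), np.asarray(sp.phi)]
    )


def segment_windows(
    rec: IMURecording,
    mask: np.ndarray,
    window_s: float = 3.0,
    stride: int | None = None,
) -> list[WindowSample]:
    """Cut masked samples into contiguous fixed-length windows.

    Within every maximal contiguous masked run (runs also end at timestamp
    gaps larger than 1.5 sample intervals), non-overlapping windows of
    ``window_s * sample_rate_hz`` samples are taken left to right; a run
    shorter than one window yields nothing, so a run of length L gives
    floor(L / window) windows at the default stride.
    """
    w = int(round(window_s * rec.sample_rate_hz))
    stride = stride or w
    if w < 1 or stride < 1:
        raise ValueError("window and stride must be at least one sample")
    max_dt = 1.5 / rec.sample_rate_hz
    label = rec.label()
    out: list[WindowSample] = []
    for run_start, run_stop in _contiguous_runs(mask, rec.timestamps, max_dt):
        for s in range(run_start, run_stop - w + 1, stride):
            feats = window_features(rec, s, s + w)
            start_clock = rec.start_clock + dt.timedelta(
                seconds=float(rec.timestamps[s])
            )
            out.append(WindowSample(feats, label, start_clock))
    return out


def split_train_val(
    samples: Sequence[WindowSample], train_frac: float = 0.8, seed: int = 0
) -> tuple[list[WindowSample], list[WindowSample]]:
    """Random shuffle-and-split into training and validation partitions."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    if len(samples) < 2:
        raise ValueError("need at least two samples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = int(len(samples) * train_frac)
    train = [samples[k] for k in order[:n_train]]
    val = [samples[k] for k in order[n_train:]]
    return train, val


def windows_to_arrays(
    samples: Sequence[WindowSample], label_map: dict[str, int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into (n, timesteps, 12) features and an int label vector.

    ``label_map`` defaults to {"healthy": 0, "stroke": 1}.
    """
    label_map = label_map or {"healthy": 0, "stroke": 1}
    X = np.stack([s.features for s in samples]).astype(np.float32)
    y = np.array([label_map[s.label] for s in samples], dtype=np.int64)
    return X, y


def save_windows(
    path: str | Path,
    samples: Sequence[WindowSample],
    crit: SelectionCriteria | None = None,
) -> None:
    """Archive windows as HDF5 (features, labels, start clocks) + JSON sidecar."""
    path = Path(path)
    X = np.stack([s.features for s in samples]) if samples else np.zeros((0, 0, N_FEATURES))
    labels = [s.label or "" for s in samples]
    starts = [s.start_clock.isoformat() for s in samples]
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=X)
        f.create_dataset("labels", data=np.array(labels, dtype="S32"))
        f.create_dataset("start_clock", data=np.array(starts, dtype="S32"))
    if crit is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"selection_criteria": crit.to_dict()}, indent=2)
        )


def load_windows(path: str | Path) -> list[WindowSample]:
    with h5py.File(path, "r") as f:
        X = f["features"][()]
        labels = [s.decode() or None for s in f["labels"][()]]
        starts = [dt.datetime.fromisoformat(s.decode()) for s in f["start_clock"][()]]
    return [WindowSample(x, l, s) for x, l, s in zip(X, labels, starts)]
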