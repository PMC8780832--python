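"""Data model and I/O for multi-day waist-worn IMU recordings.

A recording is a gapless-or-gappy 100 Hz stream of triaxial acceleration
(canonical unit: g) and triaxial angular velocity (canonical unit: deg/s),
anchored to one wall-clock datetime so time-of-day filters can be applied
without per-sample datetimes.  Readers accept delimited text with a declared
column schema and unit declarations; a binary HDF5 cache round-trips
recordings losslessly.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: 1 g in m/s^2, used when converting declared-m/s^2 input columns.
STANDARD_GRAVITY = 9.81

DEFAULT_START_CLOCK = dt.datetime(2022, 1, 10, 0, 0, 0)


class SchemaError(ValueError):
    """A declared column is missing or a unit declaration is unknown."""


class DataError(ValueError):
    """The file content violates a recording invariant (e.g. time order)."""


@dataclass(frozen=True)
class ColumnSchema:
    """Column names and unit declarations for a delimited-text recording.

    ``accel_unit`` is ``"g"`` or ``"m/s^2"``; ``gyro_unit`` is ``"deg/s"``
    or ``"rad/s"``.  Values are converted to the canonical units (g, deg/s)
    on read.
    """

    time: str = "time"
    ax: str = "ax"
    ay: str = "ay"
    az: str = "az"
    gx: str = "gx"
    gy: str = "gy"
    gz: str = "gz"
    accel_unit: str = "g"
    gyro_unit: str = "deg/s"
    delimiter: str = ","

    def channel_columns(self) -> list[str]:
        return [self.ax, self.ay, self.az, self.gx, self.gy, self.gz]


@dataclass
class IMURecording:
    """A timestamped stream of triaxial acceleration and angular velocity.

    Attributes
    ----------
    timestamps : float seconds since recording start, strictly increasing.
        Nominal spacing is ``1 / sample_rate_hz``; sensor-off gaps appear as
        timestamp jumps, never as NaN padding.
    accel : (n, 3) acceleration in g.  A resting sample has magnitude ~1.
    gyro : (n, 3) angular velocity in deg/s.
    sample_rate_hz : nominal sampling rate (100 Hz for the study protocol).
    start_clock : local wall-clock datetime of sample 0.
    subject_meta : optional metadata (group label, BMI, age, sex, ...).
    """

    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    sample_rate_hz: float = 100.0
    start_clock: dt.datetime = DEFAULT_START_CLOCK
    subject_meta: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.timestamps.shape[0]
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise DataError(
                f"channel shapes {self.accel.shape}, {self.gyro.shape} "
                f"do not match {n} timestamps"
            )
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise DataError("timestamps must be strictly increasing")
        if n and not np.all(np.isfinite(self.accel)):
            raise DataError("acceleration contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.timestamps.shape[0]

    @property
    def duration_s(self) -> float:
        if self.n_samples < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])

    def magnitude(self) -> np.ndarray:
        """Resultant acceleration |a| per sample, in g."""
        return np.linalg.norm(self.accel, axis=1)

    def seconds_of_day(self) -> np.ndarray:
        """Wall-clock second-of-day (0..86400) of every sample."""
        start = (
            self.start_clock.hour * 3600
            + self.start_clock.minute * 60
            + self.start_clock.second
            + self.start_clock.microsecond * 1e-6
        )
        return (start + self.timestamps) % 86400.0

    def label(self) -> str | None:
        """Group label from subject metadata, if any."""
        if self.subject_meta:
            return self.subject_meta.get("group")
        return None


def read_recording(
    path: str | Path,
    schema: ColumnSchema | None = None,
    *,
    sample_rate_hz: float = 100.0,
    start_clock: dt.datetime = DEFAULT_START_CLOCK,
    subject_meta: dict[str, Any] | None = None,
) -> IMURecording:
    """Read a delimited-text recording and convert to canonical units.

    Rows containing NaN in any declared column are dropped (count logged).
    Raises :class:`SchemaError` for missing columns / unknown units and
    :class:`DataError` for non-monotone timestamps.
    """
    schema = schema or ColumnSchema()
    if schema.accel_unit not in ("g", "m/s^2"):
        raise SchemaError(f"unknown acceleration unit {schema.accel_unit!r}")
    if schema.gyro_unit not in ("deg/s", "rad/s"):
        raise SchemaError(f"unknown gyro unit {schema.gyro_unit!r}")

    df = pd.read_csv(path, sep=schema.delimiter)
    needed = [schema.time, *schema.channel_columns()]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns {missing} in {path}")
    df = df[needed]
    n_before = len(df)
    df = df.dropna()
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("dropped %d NaN rows while reading %s", n_dropped, path)

    timestamps = df[schema.time].to_numpy(dtype=float)
    accel = df[[schema.ax, schema.ay, schema.az]].to_numpy(dtype=float)
    gyro = df[[schema.gx, schema.gy, schema.gz]].to_numpy(dtype=float)
    if schema.accel_unit == "m/s^2":
        accel = accel / STANDARD_GRAVITY
    if schema.gyro_unit == "rad/s":
        gyro = np.rad2deg(gyro)
    return IMURecording(
        timestamps,
        accel,
        gyro,
        sample_rate_hz=sample_rate_hz,
        start_clock=start_clock,
        subject_meta=subject_meta,
    )


def write_recording(
    rec: IMURecording, path: str | Path, schema: ColumnSchema | None = None
) -> None:
    """Write a recording as delimited text in canonical units (g, deg/s).

    Values are written as shortest round-trip decimal representations, so a
    read/write round trip reproduces them bitwise.
    """
    schema = schema or ColumnSchema()
    df = pd.DataFrame(
        {
            schema.time: rec.timestamps,
            schema.ax: rec.accel[:, 0] if rec.n_samples else [],
            schema.ay: rec.accel[:, 1] if rec.n_samples else [],
            schema.az: rec.accel[:, 2] if rec.n_samples else [],
            schema.gx: rec.gyro[:, 0] if rec.n_samples else [],
            schema.gy: rec.gyro[:, 1] if rec.n_samples else [],
            schema.gz: rec.gyro[:, 2] if rec.n_samples else [],
        }
    )
    df.to_csv(path, sep=schema.delimiter, index=False)


def save_cache(rec: IMURecording, path: str | Path) -> None:
    """Save a recording to an HDF5 cache (one dataset per channel group)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("timestamps", data=rec.timestamps)
        f.create_dataset("accel", data=rec.accel)
        f.create_dataset("gyro", data=rec.gyro)
        f.attrs["sample_rate_hz"] = rec.sample_rate_hz
        f.attrs["start_clock"] = rec.start_clock.isoformat()
        if rec.subject_meta is not None:
            f.attrs["subject_meta"] = json.dumps(rec.subject_meta)


def load_cache(path: str | Path) -> IMURecording:
    """Load a recording previously written by :func:`save_cache`."""
    with h5py.File(path, "r") as f:
        meta = f.attrs.get("subject_meta")
        return IMURecording(
            f["timestamps"][()],
            f["accel"][()],
            f["gyro"][()],
            sample_rate_hz=float(f.attrs["sample_rate_hz"]),
            start_clock=dt.datetime.fromisoformat(f.attrs["start_clock"]),
            subject_meta=json.loads(meta) if meta is not None else None,
        )
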