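"""Unit acceleration sphere (UAS): spherical transform, projection, binning.

Each acceleration sample ``a = [a_x, a_y, a_z]`` (in g) is expressed in
spherical coordinates — magnitude rho, polar/elevation angle theta in
[-pi/2, pi/2] measured from the equatorial x-z plane, and azimuthal angle
phi in [-pi, pi] — and projected onto the sphere of unit radius by setting
rho = 1.  Upright standing, ``a = [0, -1, 0]``, maps to the south pole
(theta = -pi/2); the sign of phi separates left- from right-directed
accelerations (+x, the wearer's left, maps to phi = +pi/2).

The sphere surface is discretized into 360 x 180 one-degree bins on which
per-bin occupancy probability, mean |a| and SD of |a| are accumulated; these
three fields are the visualization substrate from which information-rich
movement data is selected downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import h5py
import numpy as np

from .imu_io import IMURecording

N_PHI = 360
N_THETA = 180
_DELTA = np.pi / 180.0  # 1 degree


@dataclass
class SpherePoint:
    """A point (or array of points) in spherical acceleration coordinates.

    ``rho`` is |a| in g, ``theta`` the elevation from the equator in
    [-pi/2, pi/2], ``phi`` the azimuth in [-pi, pi].  Fields may be scalars
    or equally-shaped arrays.
    """

    rho: np.ndarray | float
    theta: np.ndarray | float
    phi: np.ndarray | float


def to_spherical(a: np.ndarray, phi_convention: str = "neg_z") -> SpherePoint:
    """Transform Cartesian acceleration(s) ``a`` (..., 3) to spherical.

    rho = sqrt(ax^2 + ay^2 + az^2); theta = atan2(ay, hypot(ax, az)).
    The azimuth is phi = atan2(ax, -az) (``phi_convention="neg_z"``, the
    default, which maps +x to +pi/2) or atan2(ax, az) (``"pos_z"``).  At the
    poles (ax = az = 0) the azimuth is undefined and set to 0 by convention.

    Raises ``ValueError`` for any zero vector (undefined direction).
    """
    a = np.asarray(a, dtype=float)
    ax, ay, az = a[..., 0], a[..., 1], a[..., 2]
    hyp = np.hypot(ax, az)
    rho = np.hypot(hyp, ay)
    if np.any(rho == 0):
        raise ValueError("zero acceleration vector has no direction")
    theta = np.arctan2(ay, hyp)
    ref = -az if phi_convention == "neg_z" else az
    if phi_convention not in ("neg_z", "pos_z"):
        raise ValueError(f"unknown phi convention {phi_convention!r}")
    phi = np.where(hyp == 0, 0.0, np.arctan2(ax, ref))
    if a.ndim == 1:
        return SpherePoint(float(rho), float(theta), float(phi))
    return SpherePoint(rho, theta, phi)


def spherical_to_cartesian(
    p: SpherePoint, phi_convention: str = "neg_z"
) -> np.ndarray:
    """Inverse of :func:`to_spherical`; returns (..., 3) Cartesian vectors."""
    hyp = np.asarray(p.rho) * np.cos(p.theta)
    ay = np.asarray(p.rho) * np.sin(p.theta)
    ax = hyp * np.sin(p.phi)
    ref = hyp * np.cos(p.phi)
    az = -ref if phi_convention == "neg_z" else ref
    return np.stack(np.broadcast_arrays(ax, ay, az), axis=-1)


def project_to_uas(p: SpherePoint) -> SpherePoint:
    """Project onto the unit sphere: rho = 1, angles unchanged."""
    return SpherePoint(np.ones_like(np.asarray(p.rho, dtype=float)), p.theta, p.phi)


def bin_index(p: SpherePoint) -> tuple[np.ndarray, np.ndarray]:
    """1-based 1-degree bin indices (i in 1..360 over phi, j in 1..180 over theta).

    Bins are half-open [lo, hi) with the top edge closed, so the 64,800 bins
    partition the closed angle ranges exactly.  Out-of-range angles raise.
    """
    phi = np.asarray(p.phi, dtype=float)
    theta = np.asarray(p.theta, dtype=float)
    if np.any(phi < -np.pi) or np.any(phi > np.pi):
        raise ValueError("phi out of [-pi, pi]")
    if np.any(theta < -np.pi / 2) or np.any(theta > np.pi / 2):
        raise ValueError("theta out of [-pi/2, pi/2]")
    i = np.floor((phi + np.pi) / _DELTA).astype(np.int64) + 1
    j = np.floor((theta + np.pi / 2) / _DELTA).astype(np.int64) + 1
    i = np.minimum(np.maximum(i, 1), N_PHI)
    j = np.minimum(np.maximum(j, 1), N_THETA)
    return i, j


@dataclass
class BinGrid:
    """Per-bin statistics of |a| over the 360 x 180 orientation grid.

    Arrays are indexed ``[i-1, j-1]`` (phi-bin, theta-bin).  Empty bins
    hold 0 in ``prob`` but NaN ("missing") in ``mean_a`` / ``sd_a`` so they
    can never pass a statistic-based filter; single-sample bins have
    ``sd_a`` = 0.  ``prob`` sums to 1 over all bins.
    """

    counts: np.ndarray
    prob: np.ndarray
    mean_a: np.ndarray
    sd_a: np.ndarray
    n_total: int

    STATISTICS = ("prob", "mean", "sd")

    def statistic(self, name: str) -> np.ndarray:
        if name == "prob":
            return self.prob
        if name == "mean":
            return self.mean_a
        if name == "sd":
            return self.sd_a
        raise ValueError(f"unknown statistic {name!r}")


def compute_bin_grid(
    rec: IMURecording, ddof: int = 0, phi_convention: str = "neg_z"
) -> BinGrid:
    """Accumulate per-bin count, probability, mean |a| and SD of |a|.

    The SD is the population SD (``ddof=0``) by default: bins are
    descriptive summaries of the samples they contain.
    """
    if rec.n_samples == 0:
        raise ValueError("cannot bin an empty recording")
    sp = to_spherical(rec.accel, phi_convention)
    i, j = bin_index(sp)
    flat = (i - 1) * N_THETA + (j - 1)
    mag = np.asarray(sp.rho)
    n_bins = N_PHI * N_THETA
    counts = np.bincount(flat, minlength=n_bins).astype(np.int64)
    # accumulate moments of (|a| - 1): resting magnitudes sit near 1 g, so
    # the shift keeps the one-pass variance well conditioned
    dev = mag - 1.0
    s1 = np.bincount(flat, weights=dev, minlength=n_bins)
    s2 = np.bincount(flat, weights=dev * dev, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dev = s1 / counts
        mean = 1.0 + mean_dev
        var = s2 / counts - mean_dev * mean_dev
        if ddof:
            var = var * counts / np.maximum(counts - ddof, 1)
    var = np.clip(var, 0.0, None)
    sd = np.sqrt(var)
    mean[counts == 0] = np.nan
    sd[counts == 0] = np.nan
    sd[counts == 1] = 0.0
    n_total = int(counts.sum())
    shape = (N_PHI, N_THETA)
    return BinGrid(
        counts=counts.reshape(shape),
        prob=(counts / n_total).reshape(shape),
        mean_a=mean.reshape(shape),
        sd_a=sd.reshape(shape),
        n_total=n_total,
    )


def bin_stats_for_samples(grid: BinGrid, i: np.ndarray, j: np.ndarray):
    """Per-sample (mean_a, sd_a, count) looked up from their bins."""
    return (
        grid.mean_a[i - 1, j - 1],
        grid.sd_a[i - 1, j - 1],
        grid.counts[i - 1, j - 1],
    )


def hemisphere_view(
    grid: BinGrid,
    which: Literal["north", "south"],
    statistic: Literal["prob", "mean", "sd"] = "prob",
    log_scale: bool = False,
) -> np.ma.MaskedArray:
    """Polar-view raster of a bin statistic for one hemisphere.

    Returns a (360, 90) masked array: rows are phi bins, columns the radial
    coordinate pi/2 - |theta| from the pole (column 0) outward to the
    equator.  Empty bins are masked; with ``log_scale`` (probability only)
    log10 is applied and zero-probability bins are masked rather than -inf.
    """
    values = grid.statistic(statistic)
    if which == "south":
        # j = 1..90 covers theta in [-pi/2, 0); column 0 is already the pole
        half = values[:, : N_THETA // 2]
        counts = grid.counts[:, : N_THETA // 2]
    elif which == "north":
        # j = 91..180 covers theta in [0, pi/2]; reverse so column 0 is the pole
        half = values[:, N_THETA // 2 :][:, ::-1]
        counts = grid.counts[:, N_THETA // 2 :][:, ::-1]
    else:
        raise ValueError(f"unknown hemisphere {which!r}")
    mask = counts == 0
    half = np.array(half, dtype=float)
    if log_scale:
        if statistic != "prob":
            raise ValueError("log scale applies to the probability view only")
        mask = mask | (half <= 0)
        with np.errstate(divide="ignore"):
            half = np.log10(half, where=half > 0, out=np.full_like(half, np.nan))
    mask = mask | ~np.isfinite(half)
    return np.ma.masked_array(half, mask=mask)


def plot_hemisphere(
    grid: BinGrid,
    which: Literal["north", "south"],
    statistic: Literal["prob", "mean", "sd"] = "prob",
    log_scale: bool = False,
    ax=None,
    cmap: str | None = None,
):
    """Render a hemisphere view as a matplotlib polar pcolormesh.

    The angular coordinate is phi and the radial coordinate pi/2 - |theta|,
    i.e. the sphere viewed along the y-axis with the pole at the center.
    Returns the matplotlib Axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    view = hemisphere_view(grid, which, statistic, log_scale)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    phi_edges = np.linspace(-np.pi, np.pi, N_PHI + 1)
    r_edges = np.linspace(0.0, np.pi / 2, N_THETA // 2 + 1)
    mesh = ax.pcolormesh(phi_edges, r_edges, view.T, cmap=cmap)
    label = {"prob": "probability", "mean": "mean |a| (g)", "sd": "SD |a| (g)"}[
        statistic
    ]
    if log_scale:
        label = f"log10 {label}"
    ax.figure.colorbar(mesh, ax=ax, label=label)
    ax.set_title(f"{which}ern hemisphere, {label}")
    ax.set_yticklabels([])
    return ax


def save_grid_text(grid: BinGrid, directory: str | Path) -> None:
    """Export each statistic as a delimited-text matrix (phi-index rows)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / "counts.csv", grid.counts, fmt="%d", delimiter=",")
    for name in ("prob", "mean", "sd"):
        np.savetxt(
            directory / f"{name}.csv",
            grid.statistic(name),
            fmt="%.10g",
            delimiter=",",
        )


def save_grid(grid: BinGrid, path: str | Path) -> None:
    """Save a grid to the HDF5 cache."""
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=grid.counts)
        f.create_dataset("prob", data=grid.prob)
        f.create_dataset("mean_a", data=grid.mean_a)
        f.create_dataset("sd_a", data=grid.sd_a)
        f.attrs["n_total"] = grid.n_total


def load_grid(path: str | Path) -> BinGrid:
    with h5py.File(path, "r") as f:
        return BinGrid(
            counts=f["counts"][()],
            prob=f["prob"][()],
            mean_a=f["mean_a"][()],
            sd_a=f["sd_a"][()],
            n_total=int(f.attrs["n_total"]),
        )
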