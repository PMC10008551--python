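"""Drinking-water δ18O baseline surfaces and probabilistic residence assignment.

A gridded environmental baseline (an *isoscape*) is smoothed from
point predictions of mean annual water δ18O — in practice the RCWIP
precipitation model sampled at station locations — by Gaussian-process
regression with a Matérn-5/2 kernel and per-point observation noise.
A measured individual's (or cluster's) modelled δ18O_water value is
then compared cell-by-cell against the surface to produce a
normalised origin-probability map: cells whose predicted water value
is close to the measurement, relative to the combined measurement and
surface uncertainty, receive high probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

__all__ = [
    "GridSpec",
    "Isoscape",
    "ResidenceMap",
    "load_isoscape_points",
    "fit_isoscape",
    "assign_residence",
    "map_summary",
]

SD_FLOOR = 1e-6


@dataclass(frozen=True)
class GridSpec:
    """Cell-centred regular lon/lat lattice (WGS84 decimal degrees)."""

    lon_min: float = -10.0
    lon_max: float = 30.0
    lat_min: float = 35.0
    lat_max: float = 60.0
    cell: float = 0.5

    def __post_init__(self) -> None:
        if self.lon_min >= self.lon_max or self.lat_min >= self.lat_max:
            raise ValueError("empty bounding box")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def lons(self) -> np.ndarray:
        n = int(round((self.lon_max - self.lon_min) / self.cell))
        return self.lon_min + self.cell * (np.arange(n) + 0.5)

    @property
    def lats(self) -> np.ndarray:
        n = int(round((self.lat_max - self.lat_min) / self.cell))
        return self.lat_min + self.cell * (np.arange(n) + 0.5)


@dataclass
class Isoscape:
    """Predictive mean and sd (‰ VSMOW) of water δ18O on a regular grid."""

    lons: np.ndarray  # (nx,)
    lats: np.ndarray  # (ny,)
    mean: np.ndarray  # (ny, nx)
    sd: np.ndarray  # (ny, nx), strictly positive
    meta: dict = field(default_factory=dict)

    def local_estimate(self, lon: float, lat: float) -> tuple[float, float]:
        """Bilinear interpolation of (mean, se) at a query point."""
        mean_i = RegularGridInterpolator(
            (self.lats, self.lons), self.mean, bounds_error=True
        )
        sd_i = RegularGridInterpolator((self.lats, self.lons), self.sd, bounds_error=True)
        pt = np.array([[lat, lon]])
        return float(mean_i(pt)[0]), float(sd_i(pt)[0])

    def to_frame(self) -> pd.DataFrame:
        lon_g, lat_g = np.meshgrid(self.lons, self.lats)
        return pd.DataFrame(
            {
                "lon": lon_g.ravel(),
                "lat": lat_g.ravel(),
                "mean_d18O_water": self.mean.ravel(),
                "sd": self.sd.ravel(),
            }
        )


@dataclass
class ResidenceMap:
    """Normalised per-cell origin probabilities on the isoscape grid."""

    lons: np.ndarray
    lats: np.ndarray
    probs: np.ndarray  # (ny, nx), sums to 1

    def __post_init__(self) -> None:
        if np.any(self.probs < 0):
            raise ValueError("negative probabilities")
        if abs(float(self.probs.sum()) - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    def entropy(self) -> float:
        p = self.probs[self.probs > 0]
        return float(-(p * np.log(p)).sum())

    def argmax_cell(self) -> tuple[float, float]:
        iy, ix = np.unravel_index(int(np.argmax(self.probs)), self.probs.shape)
        return float(self.lons[ix]), float(self.lats[iy])

    def to_frame(self) -> pd.DataFrame:
        lon_g, lat_g = np.meshgrid(self.lons, self.lats)
        return pd.DataFrame(
            {"lon": lon_g.ravel(), "lat": lat_g.ravel(), "probability": self.probs.ravel()}
        )


def load_isoscape_points(source) -> pd.DataFrame:
    """CSV with columns lon, lat, mean_d18O_water, se."""
    df = pd.read_csv(source)
    required = {"lon", "lat", "mean_d18O_water", "se"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"isoscape point table missing columns: {sorted(missing)}")
    if not df["lon"].between(-180, 180).all() or not df["lat"].between(-90, 90).all():
        raise ValueError("coordinates outside WGS84 bounds")
    if (df["se"] < 0).any():
        raise ValueError("negative standard errors")
    return df


def fit_isoscape(
    points: pd.DataFrame,
    grid_spec: GridSpec = GridSpec(),
    seed: int = 0,
    length_scale: float = 5.0,
    n_restarts: int = 2,
) -> Isoscape:
    """Smooth point δ18O_water values into a gridded baseline surface.

    Gaussian-process regression on (lon, lat) with an anisotropy-free
    Matérn-5/2 kernel; each point contributes its squared standard
    error as observation noise, and a fitted white-noise nugget absorbs
    residual microscale variation.  Kernel hyperparameters are set by
    marginal-likelihood maximisation from ``length_scale`` (degrees).
    """
    if len(points) < 10:
        raise ValueError("need at least 10 points to fit an isoscape")
    X = points[["lon", "lat"]].to_numpy(dtype=float)
    if np.allclose(X.std(axis=0), 0.0):
        raise ValueError("degenerate design: all points coincident")
    y = points["mean_d18O_water"].to_numpy(dtype=float)
    se = points["se"].to_numpy(dtype=float)

    kernel = (
        ConstantKernel(1.0, (1e-3, 1e4))
        * Matern(length_scale=length_scale, length_scale_bounds=(1e-2, 1e3), nu=2.5)
        + WhiteKernel(noise_level=1e-4, noise_level_bounds=(1e-10, 1.0))
    )
    gp = GaussianProcessRegressor(
        kernel=kernel,
        alpha=se**2 + 1e-10,
        normalize_y=True,
        n_restarts_optimizer=n_restarts,
        random_state=seed,
    )
    gp.fit(X, y)

    lons, lats = grid_spec.lons, grid_spec.lats
    lon_g, lat_g = np.meshgrid(lons, lats)
    grid_X = np.column_stack([lon_g.ravel(), lat_g.ravel()])
    mean, sd = gp.predict(grid_X, return_std=True)
    return Isoscape(
        lons=lons,
        lats=lats,
        mean=mean.reshape(lat_g.shape),
        sd=np.maximum(sd.reshape(lat_g.shape), SD_FLOOR),
        meta={
            "kernel": str(gp.kernel_),
            "seed": seed,
            "n_points": int(len(points)),
            "grid": grid_spec.__dict__.copy(),
        },
    )


def assign_residence(iso: Isoscape, measured: float, sigma_m: float) -> ResidenceMap:
    """Normalised origin-probability surface for one measured δ18O_water value.

    Per cell c:  w_c ∝ exp(−(x − μ_c)² / (2(σ_m² + σ_c²))) / sqrt(σ_m² + σ_c²),
    normalised over the grid.  Use the 2‰ conversion uncertainty for an
    individual and the cluster standard error for a cluster mean.
    """
    if sigma_m <= 0:
        raise ValueError("sigma_m must be > 0")
    var = sigma_m**2 + iso.sd**2
    logw = -0.5 * (measured - iso.mean) ** 2 / var - 0.5 * np.log(var)
    logw -= logw.max()
    w = np.exp(logw)
    return ResidenceMap(lons=iso.lons, lats=iso.lats, probs=w / w.sum())


def map_summary(m: ResidenceMap, level: float = 0.95) -> dict:
    """Smallest cell set with cumulative probability ≥ level, plus the mode.

    Cells are accumulated greedily in decreasing probability order.
    """
    if not (0.0 < level <= 1.0):
        raise ValueError("level must be in (0, 1]")
    flat = m.probs.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    n_cells = int(np.searchsorted(csum, level - 1e-12) + 1)
    n_cells = min(n_cells, flat.size)
    chosen = order[:n_cells]
    iy, ix = np.unravel_index(chosen, m.probs.shape)
    cells = [
        {"lon": float(m.lons[j]), "lat": float(m.lats[i]), "probability": float(m.probs[i, j])}
        for i, j in zip(iy, ix)
    ]
    return {
        "level": level,
        "n_cells": n_cells,
        "cumulative_probability": float(csum[n_cells - 1]),
        "argmax": dict(zip(("lon", "lat"), m.argmax_cell())),
        "cells": cells,
    }
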