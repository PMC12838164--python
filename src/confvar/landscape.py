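"""Empirical conformational-density landscapes and metastable basins.

A Gaussian kernel density over the 2-D latent coordinates is inverted to a
potential-of-mean-force-like surface F = -kBT ln P + C, min-normalized to
zero, in units of kBT (T = 300 K by default; kB = 0.0083145 kJ/(mol K) for
conversion). Because the underlying ensembles come from structure prediction
rather than time-resolved dynamics, the surface describes the sampled
conformational distribution, not kinetics.

Basins are high-density regions found by HDBSCAN on the latent coordinates;
each basin's representative is the member frame of maximal kernel density
(nearest sample to the cluster mode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN

__all__ = [
    "KB_KJ_PER_MOL_K",
    "DensityGrid",
    "BasinSet",
    "scott_bandwidth",
    "kde_density",
    "point_density",
    "boltzmann_invert",
    "find_basins",
    "pick_representatives",
]

KB_KJ_PER_MOL_K = 0.0083145
DENSITY_FLOOR_FACTOR = 1e-12  # cells below this fraction of P_max are masked


@dataclass
class DensityGrid:
    """Regular lattice over (sigma1, sigma2) with density P and landscape F."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    P: np.ndarray                     # (nx, ny), integrates to 1 over the grid
    bandwidth: float
    temperature: float = 300.0
    F: np.ndarray | None = None       # kBT units, min-normalized; NaN where masked
    mask: np.ndarray | None = None    # True where density below floor

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @property
    def cell_area(self) -> float:
        return float((self.x_edges[1] - self.x_edges[0]) * (self.y_edges[1] - self.y_edges[0]))

    def F_kj_per_mol(self) -> np.ndarray:
        """Landscape converted from kBT to kJ/mol at the grid temperature."""
        if self.F is None:
            raise ValueError("call boltzmann_invert first")
        return self.F * KB_KJ_PER_MOL_K * self.temperature

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: sigma1, sigma2, P, F, masked."""
        xx, yy = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        f = np.full_like(self.P, np.nan) if self.F is None else self.F
        m = np.zeros(self.P.shape, bool) if self.mask is None else self.mask
        return pd.DataFrame({
            "sigma1": xx.ravel(), "sigma2": yy.ravel(),
            "P": self.P.ravel(), "F": f.ravel(), "masked": m.ravel(),
        })


def scott_bandwidth(coords: np.ndarray) -> float:
    """Scott's rule for a 2-D isotropic kernel: mean marginal sd * n^(-1/6)."""
    coords = np.asarray(coords, float)
    n = len(coords)
    sd = coords.std(axis=0, ddof=1).mean()
    return float(sd * n ** (-1.0 / 6.0))


def _grid_edges(coords: np.ndarray, bandwidth: float, n_cells: int,
                ) -> tuple[np.ndarray, np.ndarray]:
    lo = coords.min(axis=0) - 3.0 * bandwidth
    hi = coords.max(axis=0) + 3.0 * bandwidth
    return (np.linspace(lo[0], hi[0], n_cells + 1),
            np.linspace(lo[1], hi[1], n_cells + 1))


def kde_density(latent_coords: np.ndarray, bandwidth: float | str = "auto",
                grid_cells: int = 100,
                grid_edges: tuple[np.ndarray, np.ndarray] | None = None,
                temperature: float = 300.0) -> DensityGrid:
    """Isotropic Gaussian KDE evaluated on a regular lattice.

    The default grid spans the data extent padded by three bandwidths and is
    renormalized so that sum(P) * cell_area = 1. An explicit grid that fails
    to cover the padded extent raises.
    """
    coords = np.asarray(latent_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("latent_coords must be (n, 2)")
    if len(coords) < 2:
        raise ValueError("need at least 2 points for density estimation")
    if bandwidth == "auto":
        bw = scott_bandwidth(coords)
    else:
        bw = float(bandwidth)
    if bw <= 0:
        raise ValueError("bandwidth must be > 0")
    if grid_edges is None:
        xe, ye = _grid_edges(coords, bw, grid_cells)
    else:
        xe, ye = (np.asarray(e, float) for e in grid_edges)
        lo = coords.min(axis=0) - 3.0 * bw
        hi = coords.max(axis=0) + 3.0 * bw
        if xe[0] > lo[0] or xe[-1] < hi[0] or ye[0] > lo[1] or ye[-1] < hi[1]:
            raise ValueError("grid does not cover data extent + 3 bandwidths")
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    # separable kernel: outer product of per-axis Gaussians summed over points
    gx = np.exp(-0.5 * ((xc[:, None] - coords[None, :, 0]) / bw) ** 2)
    gy = np.exp(-0.5 * ((yc[:, None] - coords[None, :, 1]) / bw) ** 2)
    P = gx @ gy.T / (2.0 * np.pi * bw ** 2 * len(coords))
    area = float((xe[1] - xe[0]) * (ye[1] - ye[0]))
    P = P / (P.sum() * area)
    return DensityGrid(x_edges=xe, y_edges=ye, P=P, bandwidth=bw,
                       temperature=temperature)


def point_density(latent_coords: np.ndarray, eval_points: np.ndarray | None = None,
                  bandwidth: float | str = "auto") -> np.ndarray:
    """KDE evaluated at sample points (used for mode-nearest representatives)."""
    coords = np.asarray(latent_coords, dtype=float)
    pts = coords if eval_points is None else np.asarray(eval_points, float)
    bw = scott_bandwidth(coords) if bandwidth == "auto" else float(bandwidth)
    if bw <= 0:
        raise ValueError("bandwidth must be > 0")
    d2 = ((pts[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-0.5 * d2 / bw ** 2).sum(axis=1) / (2.0 * np.pi * bw ** 2 * len(coords))


def boltzmann_invert(dg: DensityGrid) -> DensityGrid:
    """Fill F = -ln(P / P_max) in kBT units; global minimum is exactly zero.

    Cells with P below the density floor (1e-12 x P_max) are masked (NaN)
    rather than assigned an infinite landscape value.
    """
    pmax = dg.P.max()
    if pmax <= 0:
        raise ValueError("density is identically zero")
    floor = DENSITY_FLOOR_FACTOR * pmax
    mask = dg.P < floor
    if mask.all():
        raise ValueError("all cells below the density floor")
    F = np.full(dg.P.shape, np.nan)
    F[~mask] = -np.log(dg.P[~mask] / pmax)
    dg.F = F
    dg.mask = mask
    return dg


@dataclass
class BasinSet:
    """HDBSCAN cluster labels (-1 = noise) with per-basin representatives."""

    labels: np.ndarray
    representatives: dict[int, int] = field(default_factory=dict)
    cluster_sizes: dict[int, int] = field(default_factory=dict)
    probabilities: np.ndarray | None = None

    @property
    def n_basins(self) -> int:
        return int(len(set(self.labels) - {-1}))


def find_basins(latent_coords: np.ndarray,
                min_cluster_size: int | None = None,
                min_samples: int | None = None) -> BasinSet:
    """Density-based basins via HDBSCAN on the 2-D latent coordinates.

    Defaults: min_cluster_size = max(25, N // 100), min_samples equal to it.
    If min_cluster_size exceeds N every point is noise (structured warning,
    not an error).
    """
    coords = np.asarray(latent_coords, dtype=float)
    n = len(coords)
    if min_cluster_size is None:
        min_cluster_size = max(25, n // 100)
    if min_samples is None:
        min_samples = min_cluster_size
    if min_cluster_size > n:
        warnings.warn(f"min_cluster_size={min_cluster_size} exceeds N={n}; "
                      "all points labeled noise")
        return BasinSet(labels=np.full(n, -1, dtype=int))
    model = HDBSCAN(min_cluster_size=min_cluster_size, min_samples=min_samples,
                    copy=True)
    labels = model.fit_predict(coords)
    if labels.max() < 0:
        # no multi-cluster structure: a tight unimodal ensemble is one basin,
        # not noise — re-test allowing the root cluster itself
        model = HDBSCAN(min_cluster_size=min_cluster_size,
                        min_samples=min_samples, allow_single_cluster=True,
                        copy=True)
        labels = model.fit_predict(coords)
    sizes = {int(c): int(np.sum(labels == c)) for c in np.unique(labels) if c != -1}
    return BasinSet(labels=labels.astype(int), cluster_sizes=sizes,
                    probabilities=getattr(model, "probabilities_", None))


def pick_representatives(basins: BasinSet, latent_coords: np.ndarray,
                         density: np.ndarray | None = None,
                         bandwidth: float | str = "auto") -> BasinSet:
    """Per-basin representative: the member frame of maximal kernel density
    (ties broken by lowest frame index)."""
    coords = np.asarray(latent_coords, dtype=float)
    if density is None:
        density = point_density(coords, bandwidth=bandwidth)
    density = np.asarray(density, dtype=float)
    reps: dict[int, int] = {}
    for c in sorted(set(basins.labels) - {-1}):
        members = np.flatnonzero(basins.labels == c)
        assert len(members) > 0, "empty cluster cannot occur by construction"
        best = members[np.argmax(density[members])]  # argmax takes first on ties
        reps[int(c)] = int(best)
    basins.representatives = reps
    return basins
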