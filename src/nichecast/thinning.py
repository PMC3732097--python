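"""Density-based probabilistic occurrence thinning.

Geographically biased sampling (many records along well-surveyed coasts, few
elsewhere) distorts presence-only models. The remedy implemented here removes
records in densely sampled areas with a probability driven by a binned 2-D
Gaussian kernel density surface of the records themselves, gated by two
thresholds on the max-normalized density d:

* d < t1          : never removed,
* t1 <= d < t2    : removed with probability d,
* d >= t2         : always removed.

With the defaults (bandwidth 3.0 degrees, t1 = 0.5, t2 = 1.0) the procedure is
repeated over independent replicates to propagate thinning stochasticity into
downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .grids import OccurrenceSet

__all__ = [
    "ThinningConfig",
    "DensitySurface",
    "binned_kde_2d",
    "removal_probability",
    "thin_once",
    "thin_replicates",
]


@dataclass
class ThinningConfig:
    """Parameters of the thinning procedure.

    bandwidth : Gaussian kernel standard deviation, degrees, per axis.
    t1, t2 : lower/upper removal-probability thresholds on normalized density.
    replicates : number of independent thinned datasets to produce.
    gridsize : density grid nodes per axis.
    margin_bandwidths : grid margin beyond the record bounding box, in units
        of the bandwidth; wide margins keep the density integral at 1.
    """

    bandwidth: float = 3.0
    t1: float = 0.5
    t2: float = 1.0
    replicates: int = 10
    gridsize: int = 201
    margin_bandwidths: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.t1 <= self.t2 <= 1.0):
            raise ValueError("thresholds must satisfy 0 <= t1 <= t2 <= 1")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class DensitySurface:
    """Kernel density values on a regular (lon, lat) grid.

    ``density[iy, ix]`` corresponds to ``(lats[iy], lons[ix])``; axes ascend.
    """

    density: np.ndarray
    lons: np.ndarray
    lats: np.ndarray
    bandwidth: float
    normalized: bool = False

    def normalize(self):
        """Return a copy scaled so the maximum value is 1."""
        peak = self.density.max()
        if peak <= 0:
            raise ValueError("cannot normalize an all-zero density surface")
        return DensitySurface(self.density / peak, self.lons, self.lats,
                              self.bandwidth, normalized=True)

    def interpolate(self, lons, lats, method="linear"):
        """Density at arbitrary points (bilinear by default)."""
        interp = RegularGridInterpolator(
            (self.lats, self.lons), self.density,
            method=method, bounds_error=True)
        pts = np.column_stack([np.atleast_1d(lats), np.atleast_1d(lons)])
        return interp(pts)


def binned_kde_2d(occ, config=None):
    """Binned two-dimensional Gaussian kernel density of occurrence records.

    Records are linearly binned onto a regular grid which is then convolved
    with an axis-aligned Gaussian kernel (standard-deviation bandwidth). The
    result integrates to 1 over the grid. The grid covers the records' bounding
    box with a margin of ``config.margin_bandwidths`` bandwidths.
    """
    config = config or ThinningConfig()
    if len(occ) == 0:
        raise ValueError("cannot estimate a density from zero occurrences")
    x = occ.longitudes
    y = occ.latitudes
    m = config.margin_bandwidths * config.bandwidth
    gx = np.linspace(x.min() - m, x.max() + m, config.gridsize)
    gy = np.linspace(y.min() - m, y.max() + m, config.gridsize)
    dx = gx[1] - gx[0]
    dy = gy[1] - gy[0]

    # linear binning: each record splits its weight over the 4 surrounding nodes
    counts = np.zeros((config.gridsize, config.gridsize))
    fx = (x - gx[0]) / dx
    fy = (y - gy[0]) / dy
    ix = np.clip(np.floor(fx).astype(int), 0, config.gridsize - 2)
    iy = np.clip(np.floor(fy).astype(int), 0, config.gridsize - 2)
    wx = fx - ix
    wy = fy - iy
    np.add.at(counts, (iy, ix), (1 - wy) * (1 - wx))
    np.add.at(counts, (iy, ix + 1), (1 - wy) * wx)
    np.add.at(counts, (iy + 1, ix), wy * (1 - wx))
    np.add.at(counts, (iy + 1, ix + 1), wy * wx)

    # wide truncation keeps the integral at 1 to ~1e-6 with the default margin
    smooth = ndimage.gaussian_filter(
        counts, sigma=(config.bandwidth / dy, config.bandwidth / dx),
        mode="constant", truncate=8.0)
    density = smooth / (len(occ) * dx * dy)
    return DensitySurface(density, gx, gy, config.bandwidth)


def removal_probability(d, t1=0.5, t2=1.0):
    """Piecewise removal probability from normalized density d in [0, 1]."""
    d = np.asarray(d, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValueError("normalized density must lie in [0, 1]")
    p = np.where(d < t1, 0.0, np.where(d < t2, d, 1.0))
    return p if p.ndim else float(p)


def thin_once(occ, surface, config=None, seed=0, interp="linear"):
    """One probabilistic thinning pass.

    Each record is independently retained with probability
    ``1 - removal_probability(d)`` where d is the (bilinearly interpolated)
    normalized density at the record's position.
    """
    config = config or ThinningConfig()
    if not surface.normalized:
        raise ValueError("thin_once requires a normalized density surface")
    d = np.clip(surface.interpolate(occ.longitudes, occ.latitudes, method=interp),
                0.0, 1.0)
    p_remove = removal_probability(d, config.t1, config.t2)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(occ)) < (1.0 - p_remove)
    return OccurrenceSet(occ.records[keep])


def thin_replicates(occ, config=None):
    """Produce ``config.replicates`` independent thinned datasets.

    The density surface is computed once from the full record set and reused;
    replicate seeds are spawned deterministically from ``config.seed``.
    """
    config = config or ThinningConfig()
    surface = binned_kde_2d(occ, config).normalize()
    children = np.random.SeedSequence(config.seed).spawn(config.replicates)
    return [thin_once(occ, surface, config, seed=child)
            for child in children]
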