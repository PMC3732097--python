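"""Virtual environments, virtual species, and biased occurrence sampling.

Every other module is testable without downloads: this generator emulates the
role of multi-layer, spatially autocorrelated marine environmental grids with
a land/sea mask, a virtual species whose suitability is a product of Gaussian
responses to a small subset of informative layers, and geographically biased
occurrence sampling with configurable effort hotspots. The truth (the species'
suitability surface) is available for oracle comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import EnvStack, OccurrenceSet
from .maxent import SuitabilityGrid

__all__ = [
    "VirtualEnvSpec",
    "VirtualSpecies",
    "SamplingBiasSpec",
    "gen_env",
    "gen_occurrences",
    "ground_truth",
    "two_region_scenario",
    "TwoRegionScenario",
]


@dataclass
class VirtualEnvSpec:
    """Specification of a synthetic environmental stack.

    Layers are white noise smoothed with a Gaussian of ``autocorr_length``
    cells, standardized over the grid, optionally cross-correlated in pairs,
    then rescaled to ``value_range``. The land mask is carved either from an
    extra smoothed noise field thresholded at ``land_fraction`` (random
    coast-like blobs) or as a longitudinal half-split (``hemispheric``).
    """

    n_layers: int = 6
    shape: tuple = (100, 100)  # (n_rows, n_cols)
    extent: tuple = (-50.0, 50.0, -50.0, 50.0)
    autocorr_length: object = 8.0  # scalar, or one length per layer
    land_fraction: float = 0.2
    mask_style: str = "blobs"
    correlations: list = field(default_factory=list)  # (i, j, r) triples
    value_range: tuple = (0.0, 10.0)
    seed: int = 0

    @property
    def layer_lengths(self):
        if np.isscalar(self.autocorr_length):
            return [float(self.autocorr_length)] * self.n_layers
        return [float(l) for l in self.autocorr_length]

    def __post_init__(self):
        lengths = self.layer_lengths
        if len(lengths) != self.n_layers:
            raise ValueError("need one autocorrelation length per layer")
        if any(l < 1 for l in lengths):
            raise ValueError("autocorrelation length must be >= 1 cell")
        if not (0.0 <= self.land_fraction < 1.0):
            raise ValueError("land fraction must be in [0, 1)")
        for _, _, r in self.correlations:
            if abs(r) > 1:
                raise ValueError(f"impossible correlation target {r}")


def _smooth_field(rng, shape, length):
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), length,
                                     mode="wrap")
    field_ -= field_.mean()
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def gen_env(spec):
    """Generate the synthetic :class:`EnvStack` described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    nrows, ncols = spec.shape
    fields = [_smooth_field(rng, spec.shape, length)
              for length in spec.layer_lengths]
    for i, j, r in spec.correlations:
        # mix standardized fields: corr(f_i, r f_i + sqrt(1-r^2) f_j) = r
        fields[j] = r * fields[i] + np.sqrt(1 - r * r) * fields[j]
        fields[j] = (fields[j] - fields[j].mean()) / fields[j].std()

    lo, hi = spec.value_range
    # map ~N(0,1) into the value range, clipping the far tails
    layers = [lo + (hi - lo) * (np.clip(f, -3, 3) + 3) / 6 for f in fields]

    if spec.land_fraction == 0:
        valid = np.ones(spec.shape, dtype=bool)
    elif spec.mask_style == "blobs":
        land_field = _smooth_field(rng, spec.shape, spec.layer_lengths[0])
        thr = np.quantile(land_field, 1 - spec.land_fraction)
        valid = land_field < thr
    elif spec.mask_style == "hemispheric":
        n_land = int(round(spec.land_fraction * ncols))
        valid = np.ones(spec.shape, dtype=bool)
        if n_land:
            valid[:, -n_land:] = False
    else:
        raise ValueError(f"unknown mask style {spec.mask_style!r}")

    names = [f"env{i}" for i in range(spec.n_layers)]
    resolution = (spec.extent[1] - spec.extent[0]) / ncols
    return EnvStack(names, np.stack(layers), spec.extent, resolution, valid)


@dataclass
class VirtualSpecies:
    """A species with Gaussian responses to a subset of informative layers.

    Suitability is the product over informative layers of
    exp(-(x - optimum)^2 / (2 tolerance^2)), so it peaks at 1 where every
    informative layer sits at its optimum. ``skew`` switches a layer's
    response to a misspecified (log-normal-shaped) curve for robustness
    experiments. ``truncation`` optionally zeroes suitability where a layer
    exceeds a bound inside a lon/lat box — a region-specific realized niche
    narrower than the fundamental one.
    """

    informative: list
    optima: dict
    tolerances: dict
    skew: dict = field(default_factory=dict)
    truncation: dict = None  # {"box": (...), "layer": str, "max": float}

    def __post_init__(self):
        if not self.informative:
            raise ValueError("informative layer subset must be non-empty")

    def response(self, layer, x):
        x = np.asarray(x, dtype=float)
        mu = self.optima[layer]
        sd = self.tolerances[layer]
        if self.skew.get(layer):
            z = np.log1p(np.maximum(x - mu + sd, 1e-9) / sd)
            return np.exp(-z * z / 0.5)
        return np.exp(-((x - mu) ** 2) / (2 * sd * sd))


def ground_truth(species, stack):
    """True suitability surface of the species on the stack's canvas."""
    missing = [l for l in species.informative if l not in stack.layer_names]
    if missing:
        raise ValueError(f"informative layers missing from stack: {missing}")
    suit = np.ones(stack.valid_mask.shape)
    for layer in species.informative:
        suit = suit * species.response(layer, stack.layer(layer))
    if species.truncation:
        box = species.truncation["box"]
        lon_ok = (stack.lon_centers >= box[0]) & (stack.lon_centers <= box[1])
        lat_ok = (stack.lat_centers >= box[2]) & (stack.lat_centers <= box[3])
        inside = lat_ok[:, None] & lon_ok[None, :]
        over = stack.layer(species.truncation["layer"]) > species.truncation["max"]
        suit = np.where(inside & over, 0.0, suit)
    vals = np.where(stack.valid_mask, suit, np.nan)
    return SuitabilityGrid(vals, stack.valid_mask.copy(), stack.extent,
                           stack.resolution, stack.nodata_value)


@dataclass
class SamplingBiasSpec:
    """Geographic sampling-effort surface: baseline plus Gaussian hotspots."""

    hotspots: list = field(default_factory=list)  # (lon, lat, intensity, radius)
    baseline: float = 1.0

    def effort(self, lons, lats):
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        e = np.full(np.broadcast(lons, lats).shape, float(self.baseline))
        for lon0, lat0, intensity, radius in self.hotspots:
            d2 = (lons - lon0) ** 2 + (lats - lat0) ** 2
            e = e + intensity * np.exp(-d2 / (2 * radius * radius))
        return e


def gen_occurrences(species, stack, n, bias=None, box=None, region="other",
                    seed=0):
    """Sample occurrence cells with probability ~ suitability x effort x cos(lat).

    Cells are drawn without replacement (mirroring the one-record-per-cell
    reality after per-cell deduplication), restricted to valid cells inside
    the optional box.
    """
    bias = bias or SamplingBiasSpec()
    truth = ground_truth(species, stack)
    candidate = stack.valid_mask.copy()
    if box is not None:
        lon_ok = (stack.lon_centers >= box[0]) & (stack.lon_centers <= box[1])
        lat_ok = (stack.lat_centers >= box[2]) & (stack.lat_centers <= box[3])
        candidate &= lat_ok[:, None] & lon_ok[None, :]
    rows, cols = np.nonzero(candidate)
    lons = stack.lon_centers[cols]
    lats = stack.lat_centers[rows]
    w = truth.values[rows, cols] * bias.effort(lons, lats) \
        * np.cos(np.radians(lats))
    w = np.clip(w, 0.0, None)
    positive = int((w > 0).sum())
    if positive < n:
        raise ValueError(
            f"only {positive} cells with positive sampling probability, need {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n, replace=False, p=w / w.sum())
    return OccurrenceSet.from_points(lons[idx], lats[idx], region=region)


# ---------------------------------------------------------------------------
# Canned two-region study scenario
# ---------------------------------------------------------------------------

@dataclass
class TwoRegionScenario:
    """A complete synthetic study: environment, species, truth, occurrences."""

    stack: EnvStack
    species: VirtualSpecies
    truth: SuitabilityGrid
    native: OccurrenceSet
    invaded: OccurrenceSet
    native_box: tuple
    invaded_box: tuple
    informative: list
    noise: list


def two_region_scenario(seed=0, shape=(80, 100), n_layers=6,
                        n_informative=2, n_native=120, n_invaded=120,
                        land_fraction=0.25, autocorr_length=8.0,
                        noise_autocorr_length=2.0, hotspot=True,
                        tolerance=0.8):
    """Build the default in-silico transferability study.

    The species responds to the first ``n_informative`` layers (Gaussian
    optima at the grid-wide layer mean, tolerance in layer units); the
    remaining layers are spatially structured noise. Informative layers vary
    at broad spatial scales (``autocorr_length`` cells, like climatic
    drivers); noise layers vary at finer scales (``noise_autocorr_length``),
    so their values at clustered presence sites are close to exchangeable
    draws from their background distribution rather than proxies for
    geography. Occurrences are sampled in two disjoint longitudinal regions
    (west = native, east = invaded); the native region optionally carries a
    strong sampling hotspot emulating uneven survey effort.
    """
    # square cells: latitude span follows the grid aspect ratio
    nrows, ncols = shape
    res = 100.0 / ncols
    half_lat = res * nrows / 2.0
    extent = (-50.0, 50.0, -half_lat, half_lat)
    lengths = [autocorr_length] * n_informative + \
        [noise_autocorr_length] * (n_layers - n_informative)
    spec = VirtualEnvSpec(n_layers=n_layers, shape=shape, extent=extent,
                          autocorr_length=lengths,
                          land_fraction=land_fraction, seed=seed)
    stack = gen_env(spec)
    informative = stack.layer_names[:n_informative]
    noise = stack.layer_names[n_informative:]
    optima = {l: float(stack.layer(l)[stack.valid_mask].mean())
              for l in informative}
    tolerances = {l: tolerance for l in informative}
    species = VirtualSpecies(informative, optima, tolerances)
    truth = ground_truth(species, stack)

    native_box = (extent[0], 0.0, extent[2], extent[3])
    invaded_box = (0.0, extent[1], extent[2], extent[3])
    rng = np.random.default_rng(seed)
    if hotspot:
        # survey effort concentrates where the species occurs but not at its
        # niche center (ports, marinas): a marginally suitable native cell,
        # so the densely sampled records systematically distort the niche
        # estimate — the regime occurrence thinning is designed for
        cand = stack.valid_mask & (truth.values > 0.05) & (truth.values < 0.35)
        cand[:, stack.lon_centers >= -5.0] = False
        rr, cc = np.nonzero(cand)
        if len(rr) == 0:
            rr, cc = np.nonzero(stack.valid_mask)
        j = rng.integers(len(rr))
        bias = SamplingBiasSpec(
            hotspots=[(float(stack.lon_centers[cc[j]]),
                       float(stack.lat_centers[rr[j]]), 100.0, 4.0)],
            baseline=1.0)
    else:
        bias = SamplingBiasSpec()
    native = gen_occurrences(species, stack, n_native, bias=bias,
                             box=native_box, region="native",
                             seed=int(rng.integers(2 ** 31)))
    invaded = gen_occurrences(species, stack, n_invaded,
                              box=invaded_box, region="invaded",
                              seed=int(rng.integers(2 ** 31)))
    return TwoRegionScenario(stack, species, truth, native, invaded,
                             native_box, invaded_box, informative, noise)
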