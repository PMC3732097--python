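"""Model evaluation and transferability metrics.

Implements the presence-background test AUC (rank-based Mann-Whitney
estimator), Schoener's D niche overlap between suitability surfaces, the
multivariate environmental similarity surface (MESS) with its most-dissimilar
variable (MoD) companion, and suitability thresholding rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .grids import EnvStack, SWDTable
from .maxent import SuitabilityGrid

__all__ = [
    "ROCResult",
    "NicheOverlap",
    "MESSResult",
    "ThresholdRule",
    "test_auc",
    "schoener_d",
    "mess_mod",
    "resolve_threshold",
    "binarize",
]


@dataclass
class ROCResult:
    auc: float
    n_presence: int
    n_background: int
    ties: str = "midrank"


@dataclass
class NicheOverlap:
    d: float
    n_cells: int


@dataclass
class MESSResult:
    """MESS values with the argmin (most dissimilar) predictor per point/cell.

    ``mess`` is the minimum per-predictor similarity (<= 100; negative iff at
    least one predictor is outside its training range). ``mod_index`` indexes
    into ``predictors``; ``mod`` gives the names. On grid input, off-mask
    entries are NaN (mess) / -1 (mod_index).
    """

    mess: np.ndarray
    mod_index: np.ndarray
    predictors: list

    @property
    def mod(self):
        names = np.asarray(self.predictors, dtype=object)
        out = np.empty(self.mod_index.shape, dtype=object)
        ok = self.mod_index >= 0
        out[~ok] = None
        out[ok] = names[self.mod_index[ok]]
        return out


def test_auc(presence_scores, background_scores):
    """Presence-background AUC via the rank-sum (Mann-Whitney) estimator.

    Midranks handle ties, so exchangeable score sets give exactly 0.5. The
    statistic depends on scores only through their ranks and is therefore
    invariant under strictly monotone transforms.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("presence and background score sets must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    auc = (ranks[: p.size].sum() - p.size * (p.size + 1) / 2) / (p.size * b.size)
    return ROCResult(float(auc), p.size, b.size)


def _grid_values(g):
    if isinstance(g, SuitabilityGrid):
        return g.values, g.valid_mask
    g = np.asarray(g, dtype=float)
    return g, np.isfinite(g)


def schoener_d(a, b):
    """Schoener's D overlap between two suitability surfaces.

    Each surface is normalized to sum 1 over the cells valid in both grids;
    D = 1 - 0.5 * sum |p_i - q_i|, i.e. one minus the total variation
    distance: 1 for identical surfaces, 0 for disjoint support.
    """
    va, ma = _grid_values(a)
    vb, mb = _grid_values(b)
    if va.shape != vb.shape:
        raise ValueError("suitability grids are on different canvases")
    if isinstance(a, SuitabilityGrid) and isinstance(b, SuitabilityGrid):
        if a.extent != b.extent or a.resolution != b.resolution:
            raise ValueError("suitability grids are on different canvases")
    shared = ma & mb
    pa = va[shared]
    pb = vb[shared]
    sa, sb = pa.sum(), pb.sum()
    if shared.sum() == 0 or sa <= 0 or sb <= 0:
        raise ValueError("need at least one shared valid cell with positive total")
    d = 1.0 - 0.5 * np.abs(pa / sa - pb / sb).sum()
    return NicheOverlap(float(d), int(shared.sum()))


def _mess_one_predictor(train, v):
    """Similarity of target values v to the training sample of one predictor."""
    train = np.sort(np.asarray(train, dtype=float))
    lo, hi = train[0], train[-1]
    if hi == lo:
        raise ValueError("degenerate training sample (max == min)")
    n = train.size
    # f = percentage of training values strictly below v
    f = 100.0 * np.searchsorted(train, v, side="left") / n
    sim = np.where(
        f == 0, 100.0 * (v - lo) / (hi - lo),
        np.where(f <= 50, 2 * f,
                 np.where(f < 100, 2 * (100 - f),
                          100.0 * (hi - v) / (hi - lo))))
    return sim


def mess_mod(target, training):
    """MESS and MoD of target environments relative to a training sample.

    For each predictor the similarity of a target value v to the training
    sample is piecewise in f, the percentage of training values strictly
    below v: 100(v-min)/(max-min) if f = 0; 2f if f <= 50; 2(100-f) if
    f < 100; 100(max-v)/(max-min) if f = 100. MESS is the minimum over
    predictors and MoD its argmin (ties go to the first predictor in layer
    order). Negative MESS flags extrapolation beyond the training range.

    ``target`` may be an :class:`SWDTable` (returns per-row values) or an
    :class:`EnvStack` (returns per-cell grids, NaN off-mask).
    """
    if len(training) == 0:
        raise ValueError("training table is empty")
    if isinstance(target, EnvStack):
        predictors = [p for p in target.layer_names
                      if p in training.layer_names]
    else:
        predictors = [p for p in training.layer_names
                      if p in target.layer_names]
    if not predictors:
        raise ValueError("no shared predictors between target and training")

    usable = []
    sims = []

    def target_values(p):
        if isinstance(target, EnvStack):
            return target.layer(p)[target.valid_mask]
        return target.data[p].to_numpy(float)

    for p in predictors:
        train = training.data[p].to_numpy(float)
        if train.max() == train.min():
            warnings.warn(f"predictor {p!r} has max == min in training; "
                          "excluded from MESS")
            continue
        usable.append(p)
        sims.append(_mess_one_predictor(train, target_values(p)))
    if not usable:
        raise ValueError("no predictor with a non-degenerate training range")
    sims = np.vstack(sims)
    mod_idx = np.argmin(sims, axis=0)  # argmin takes the first on ties
    mess = sims[mod_idx, np.arange(sims.shape[1])]

    if isinstance(target, EnvStack):
        mess_grid = np.full(target.valid_mask.shape, np.nan)
        mod_grid = np.full(target.valid_mask.shape, -1, dtype=int)
        mess_grid[target.valid_mask] = mess
        mod_grid[target.valid_mask] = mod_idx
        return MESSResult(mess_grid, mod_grid, usable)
    return MESSResult(mess, mod_idx, usable)


@dataclass
class ThresholdRule:
    kind: str
    threshold: float


def resolve_threshold(rule_kind, training_predictions,
                      background_predictions=None):
    """Resolve a named thresholding rule to a numeric suitability threshold.

    ``ten_percentile_training``: the largest attained prediction value t such
    that fewer than 10% of training predictions fall strictly below t (the
    lower-interpolation 10th percentile, always an attained value).

    ``equal_sens_spec``: scanning the attained scores as candidate thresholds
    (background as pseudo-absences, suitable means score >= t), the candidate
    minimizing |sensitivity - specificity|; ties go to the smaller threshold.
    """
    t = np.sort(np.asarray(training_predictions, dtype=float))
    if t.size == 0:
        raise ValueError("training predictions are empty")
    if rule_kind == "ten_percentile_training":
        below = np.searchsorted(t, t, side="left")  # strictly-below counts
        ok = below < 0.10 * t.size
        return ThresholdRule(rule_kind, float(t[ok][-1]))
    if rule_kind == "equal_sens_spec":
        if background_predictions is None:
            raise ValueError("equal_sens_spec requires background predictions")
        b = np.asarray(background_predictions, dtype=float)
        if b.size == 0:
            raise ValueError("background predictions are empty")
        candidates = np.unique(np.concatenate([t, b]))
        best = None
        for c in candidates:
            sens = np.mean(t >= c)
            spec = np.mean(b < c)
            gap = abs(sens - spec)
            if best is None or gap < best[0] - 1e-15:
                best = (gap, c)
        return ThresholdRule(rule_kind, float(best[1]))
    raise ValueError(f"unknown threshold rule {rule_kind!r}")


def binarize(grid, rule):
    """Threshold a suitability grid: cell true iff suitability >= threshold."""
    thr = rule.threshold if isinstance(rule, ThresholdRule) else float(rule)
    vals, mask = _grid_values(grid)
    return mask & (vals >= thr)
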