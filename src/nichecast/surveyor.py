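"""Exhaustive predictor-subset surveying by held-out test AUC.

With p candidate predictors there are 2^p - 1 non-empty subsets (255 for
p = 8). For each subset a simple-features (linear + quadratic) maximum-entropy
model is trained on a random half of the occurrences and scored by test AUC on
the held-out half against the shared background. Repeating the survey over
thinning replicates, the predictors appearing in the top-k models are tallied
into per-region representation percentages, and a consensus rule keeps the
predictors that exceed a representation threshold in enough regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import extract_swd
from .maxent import ConvergenceError, Maxent, build_features
from .evaluation import test_auc

__all__ = [
    "SubsetScore",
    "RepresentationTable",
    "ConsensusRule",
    "enumerate_subsets",
    "survey",
    "survey_replicates",
    "top_k_representation",
    "consensus",
    "subset_members",
]


@dataclass
class SubsetScore:
    """Test AUC of one predictor subset (bitmask over the predictor list)."""

    subset: int
    replicate: int
    test_auc: float  # NaN when the subset was degenerate


@dataclass
class RepresentationTable:
    """Top-k membership counts per (replicate, predictor) and their summary.

    ``summary`` maps predictor name to 100 * total appearances /
    (replicates * k).
    """

    region: str
    predictors: list
    k: int
    counts: pd.DataFrame  # index: replicate id, columns: predictors
    summary: pd.Series


@dataclass
class ConsensusRule:
    top_k: int = 10
    threshold: float = 60.0  # percent
    min_regions: int = 2
    strict: bool = True

    def __post_init__(self):
        if not (0 < self.threshold <= 100):
            raise ValueError("threshold must be in (0, 100]")
        if self.min_regions < 1:
            raise ValueError("min_regions must be >= 1")


def enumerate_subsets(p):
    """All 2^p - 1 non-empty predictor subsets, ascending bitmask order."""
    if not (1 <= p <= 20):
        raise ValueError("predictor count must be between 1 and 20")
    return list(range(1, 2 ** p))


def subset_members(mask, predictors):
    """Predictor names selected by a bitmask (bit i = predictors[i])."""
    return [name for i, name in enumerate(predictors) if mask >> i & 1]


def survey(occurrences, stack, background, predictors, split=0.5, seed=0,
           replicate=0, beta_multiplier=1.0, tol=1e-6, max_iter=2000):
    """Score every non-empty predictor subset by held-out test AUC.

    A single random presence split (per seed) is shared by all subsets, so
    subset comparisons are paired. Models use simple (linear + quadratic)
    features. Subsets whose training data are degenerate get a NaN score.
    """
    predictors = list(predictors)
    n = len(occurrences)
    if n < 4:
        raise ValueError("need at least 4 occurrences for a 50/50 split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = max(2, int(round(split * n)))
    n_train = min(n_train, n - 2)
    train_idx, test_idx = perm[:n_train], perm[n_train:]

    from .grids import OccurrenceSet
    occ_train = OccurrenceSet(occurrences.records.iloc[train_idx])
    occ_test = OccurrenceSet(occurrences.records.iloc[test_idx])
    swd_train = extract_swd(occ_train, stack, predictors, "train")
    swd_test = extract_swd(occ_test, stack, predictors, "test")
    swd_bg = extract_swd(background, stack, predictors, "background")

    scores = []
    for mask in enumerate_subsets(len(predictors)):
        names = subset_members(mask, predictors)
        try:
            feats = build_features(swd_bg.subset(names), mode="simple")
            if feats.n_features == 0:
                raise ValueError("no usable features")
            res = Maxent(swd_train.subset(names), swd_bg.subset(names),
                         features=feats, beta_multiplier=beta_multiplier
                         ).fit(tol=tol, max_iter=max_iter)
            auc = test_auc(res.predict_raw(swd_test),
                           res.predict_raw(swd_bg)).auc
        except (ValueError, ConvergenceError) as exc:
            warnings.warn(f"subset {names} not scored: {exc}")
            auc = np.nan
        scores.append(SubsetScore(mask, replicate, float(auc)))
    return scores


def survey_replicates(occurrence_sets, stack, background, predictors,
                      split=0.5, seed=0, **kwargs):
    """Run :func:`survey` once per (thinned) occurrence replicate.

    Each replicate gets its own split seed derived from ``seed``.
    """
    seeds = np.random.SeedSequence(seed).spawn(len(occurrence_sets))
    out = {}
    for r, (occ, s) in enumerate(zip(occurrence_sets, seeds)):
        out[r] = survey(occ, stack, background, predictors, split=split,
                        seed=s, replicate=r, **kwargs)
    return out


def top_k_representation(scores_by_replicate, predictors, k=10, region="combined"):
    """Count predictor membership in the top-k subsets of each replicate.

    Subsets are ranked by test AUC descending; ties prefer the smaller subset,
    then the smaller bitmask. Degenerate (NaN) scores are excluded from the
    ranking. The summary percentage for a predictor is
    100 * total top-k appearances / (replicates * k).
    """
    predictors = list(predictors)
    counts = {}
    for rep, scores in scores_by_replicate.items():
        valid = [s for s in scores if np.isfinite(s.test_auc)]
        if len(valid) < k:
            raise ValueError(
                f"replicate {rep}: only {len(valid)} scored subsets, need {k}")
        ranked = sorted(valid, key=lambda s: (-s.test_auc,
                                              bin(s.subset).count("1"),
                                              s.subset))
        row = dict.fromkeys(predictors, 0)
        for s in ranked[:k]:
            for name in subset_members(s.subset, predictors):
                row[name] += 1
        counts[rep] = row
    counts = pd.DataFrame.from_dict(counts, orient="index")[predictors]
    summary = 100.0 * counts.sum(axis=0) / (len(counts) * k)
    return RepresentationTable(region, predictors, k, counts, summary)


def consensus(tables, rule=None):
    """Cross-region consensus predictor set.

    A predictor is retained iff its summary representation exceeds
    ``rule.threshold`` (strictly by default) in at least ``rule.min_regions``
    of the given region tables.
    """
    rule = rule or ConsensusRule()
    if len(tables) < rule.min_regions:
        raise ValueError("fewer region tables than min_regions")
    predictors = tables[0].predictors
    for t in tables[1:]:
        if t.predictors != predictors:
            raise ValueError("region tables have mismatched predictor lists")
    kept = []
    for name in predictors:
        if rule.strict:
            hits = sum(t.summary[name] > rule.threshold for t in tables)
        else:
            hits = sum(t.summary[name] >= rule.threshold for t in tables)
        if hits >= rule.min_regions:
            kept.append(name)
    return kept
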