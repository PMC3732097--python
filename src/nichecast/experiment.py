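"""The multifactorial transferability experiment and exact paired statistics.

Four binary modeling choices are crossed: occurrence thinning (on/off),
predictor set (full/consensus), model complexity (simple/auto features), and
background extent (global/regional) — 16 condition cells. For each cell,
models are trained in each of two regions and transferred: reciprocal test
AUC (train native, test on invaded presences, and vice versa; averaged) and
the global Schoener's D between the two projected suitability surfaces
measure transferability. A companion 8-row table (thinning x predictor set x
complexity, always global background) scores models trained on the pooled
occurrences with a random 50/50 presence split. Matched condition pairs are
compared with an exact Wilcoxon signed-rank test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import OccurrenceSet, dedupe_per_cell, extract_swd, sample_background
from .maxent import Maxent
from .evaluation import schoener_d, test_auc
from .thinning import ThinningConfig, thin_replicates

__all__ = [
    "ExperimentCondition",
    "TransferCell",
    "WSRTResult",
    "ExperimentData",
    "ExperimentReport",
    "wilcoxon_exact",
    "run_condition",
    "run_experiment",
    "prepare_experiment_data",
]

FACTORS = {
    "thinning": ("on", "off"),
    "predictor_set": ("consensus", "full"),
    "complexity": ("simple", "auto"),
    "background": ("global", "regional"),
}


@dataclass(frozen=True)
class ExperimentCondition:
    thinning: str
    predictor_set: str
    complexity: str
    background: str

    @property
    def key(self):
        return (f"thin={self.thinning},pred={self.predictor_set},"
                f"feat={self.complexity},bg={self.background}")


@dataclass
class TransferCell:
    """Per-condition reciprocal AUCs and global niche overlap."""

    condition: ExperimentCondition
    auc_native_to_invaded: list
    auc_invaded_to_native: list
    schoener_d_global: list

    @property
    def auc_mean_per_replicate(self):
        return [(a + b) / 2 for a, b in
                zip(self.auc_native_to_invaded, self.auc_invaded_to_native)]

    @property
    def auc_mean(self):
        return float(np.mean(self.auc_mean_per_replicate))

    @property
    def d_mean(self):
        return float(np.mean(self.schoener_d_global))


# ---------------------------------------------------------------------------
# Exact Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

@dataclass
class WSRTResult:
    n: int
    statistic: float  # the smaller signed-rank sum W
    p_value: float


def wilcoxon_exact(differences):
    """Exact two-sided Wilcoxon signed-rank test by full sign enumeration.

    Zero differences are dropped; tied magnitudes get midranks. The null
    distribution of the positive rank sum is built over all 2^n sign
    assignments, and p = 2 * min(lower tail, upper tail), capped at 1.
    Limited to n <= 20 nonzero pairs (exact enumeration guard).
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero: no test")
    if n > 20:
        raise ValueError("exact enumeration limited to n <= 20 nonzero pairs")
    from scipy.stats import rankdata
    ranks = rankdata(np.abs(d))
    s_obs = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    # distribution of the positive rank sum: iterative doubling over ranks
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    eps = 1e-9
    lower = np.mean(sums <= s_obs + eps)
    upper = np.mean(sums >= s_obs - eps)
    p = min(1.0, 2.0 * min(lower, upper))
    w = min(s_obs, total - s_obs)
    return WSRTResult(n, w, float(p))


# ---------------------------------------------------------------------------
# Data bundle
# ---------------------------------------------------------------------------

@dataclass
class ExperimentData:
    """Everything one experiment run needs, prepared once.

    ``replicates[region]`` holds the thinned occurrence replicates;
    ``occurrences[region]`` the full (deduplicated) sets. ``backgrounds`` maps
    'global', 'native', 'invaded' to prepared background samples.
    """

    stack: object
    occurrences: dict
    replicates: dict
    backgrounds: dict
    predictor_sets: dict  # {"full": [...], "consensus": [...]}
    region_boxes: dict


def prepare_experiment_data(stack, native, invaded, consensus_predictors,
                            native_box, invaded_box, n_background=2000,
                            thinning_config=None, seed=0):
    """Dedupe, thin, and sample backgrounds for a two-region experiment."""
    thinning_config = thinning_config or ThinningConfig()
    rng = np.random.SeedSequence(seed)
    bg_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in rng.spawn(3)]
    occurrences, replicates = {}, {}
    for region, occ in (("native", native), ("invaded", invaded)):
        occ = dedupe_per_cell(occ, stack)
        occurrences[region] = occ
        offset = {"native": 101, "invaded": 202}[region]
        cfg = ThinningConfig(**{**thinning_config.__dict__,
                                "seed": thinning_config.seed + offset})
        replicates[region] = [r for r in thin_replicates(occ, cfg) if len(r) >= 2]
        if not replicates[region]:
            raise ValueError(f"all thinned replicates of {region} are too small")
    backgrounds = {
        "global": sample_background(stack, n_background, seed=bg_seeds[0]),
        "native": sample_background(stack, n_background, box=native_box,
                                    seed=bg_seeds[1]),
        "invaded": sample_background(stack, n_background, box=invaded_box,
                                     seed=bg_seeds[2]),
    }
    full = list(stack.layer_names)
    return ExperimentData(
        stack=stack, occurrences=occurrences, replicates=replicates,
        backgrounds=backgrounds,
        predictor_sets={"full": full, "consensus": list(consensus_predictors)},
        region_boxes={"native": native_box, "invaded": invaded_box})


# ---------------------------------------------------------------------------
# Running conditions
# ---------------------------------------------------------------------------

def run_condition(cond, data, tol=1e-6, max_iter=2000):
    """Evaluate one factor combination: reciprocal AUCs and global D.

    Per replicate: train in each region (features per ``cond.complexity``,
    predictors per ``cond.predictor_set``, training background per
    ``cond.background``), score test AUC with the other region's records as
    test presences against the global background, project both models on the
    full canvas and compute Schoener's D between the projections.
    """
    predictors = data.predictor_sets[cond.predictor_set]
    stack = data.stack
    gbg = data.backgrounds["global"]
    gbg_swd = extract_swd(gbg, stack, predictors, "background")

    if cond.thinning == "on":
        n_rep = min(len(data.replicates["native"]), len(data.replicates["invaded"]))
        rep_sets = {r: {reg: data.replicates[reg][r] for reg in ("native", "invaded")}
                    for r in range(n_rep)}
    else:
        # without thinning the replicates are identical: run once, reuse
        rep_sets = {0: {reg: data.occurrences[reg] for reg in ("native", "invaded")}}

    auc_ni, auc_in, d_vals = [], [], []
    for r, occ in rep_sets.items():
        models = {}
        for region in ("native", "invaded"):
            bg_name = "global" if cond.background == "global" else region
            bg_swd = gbg_swd if bg_name == "global" else \
                extract_swd(data.backgrounds[bg_name], stack, predictors,
                            "background")
            pres = extract_swd(occ[region], stack, predictors, "presence")
            models[region] = Maxent(pres, bg_swd, mode=cond.complexity
                                    ).fit(tol=tol, max_iter=max_iter)
        test_inv = extract_swd(occ["invaded"], stack, predictors, "test")
        test_nat = extract_swd(occ["native"], stack, predictors, "test")
        bg_scores = {reg: models[reg].predict_raw(gbg_swd)
                     for reg in ("native", "invaded")}
        auc_ni.append(test_auc(models["native"].predict_raw(test_inv),
                               bg_scores["native"]).auc)
        auc_in.append(test_auc(models["invaded"].predict_raw(test_nat),
                               bg_scores["invaded"]).auc)
        proj_nat = models["native"].predict_logistic(stack)
        proj_inv = models["invaded"].predict_logistic(stack)
        d_vals.append(schoener_d(proj_nat, proj_inv).d)
    return TransferCell(cond, auc_ni, auc_in, d_vals)


def _combined_row(thinning, predictor_set, complexity, data, seed,
                  tol=1e-6, max_iter=2000):
    """Pooled-occurrence model with a random 50/50 split, global background."""
    predictors = data.predictor_sets[predictor_set]
    stack = data.stack
    gbg_swd = extract_swd(data.backgrounds["global"], stack, predictors,
                          "background")
    if thinning == "on":
        n_rep = min(len(data.replicates["native"]), len(data.replicates["invaded"]))
        pools = [OccurrenceSet(pd.concat(
            [data.replicates["native"][r].records,
             data.replicates["invaded"][r].records],
            ignore_index=True).assign(id=lambda d: d.index))
            for r in range(n_rep)]
    else:
        pools = [OccurrenceSet(pd.concat(
            [data.occurrences["native"].records,
             data.occurrences["invaded"].records],
            ignore_index=True).assign(id=lambda d: d.index))]
    aucs = []
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    seeds = seed.spawn(len(pools))
    for pool, s in zip(pools, seeds):
        rng = np.random.default_rng(s)
        n = len(pool)
        perm = rng.permutation(n)
        half = max(2, n // 2)
        train = OccurrenceSet(pool.records.iloc[perm[:half]])
        test = OccurrenceSet(pool.records.iloc[perm[half:]])
        res = Maxent(extract_swd(train, stack, predictors, "train"), gbg_swd,
                     mode=complexity).fit(tol=tol, max_iter=max_iter)
        aucs.append(test_auc(
            res.predict_raw(extract_swd(test, stack, predictors, "test")),
            res.predict_raw(gbg_swd)).auc)
    return float(np.mean(aucs)), aucs


@dataclass
class ExperimentReport:
    """Machine-readable experiment output.

    ``transfer`` (16 rows): condition factors, mean reciprocal AUC, mean D.
    ``combined`` (8 rows): pooled-occurrence test AUCs, global background.
    ``wsrt``: paired exact Wilcoxon comparisons between matched conditions.
    ``cells``: the per-replicate :class:`TransferCell` objects by key.
    """

    transfer: pd.DataFrame
    combined: pd.DataFrame
    wsrt: dict
    cells: dict

    def to_csv(self, outdir):
        import os
        os.makedirs(outdir, exist_ok=True)
        self.transfer.to_csv(os.path.join(outdir, "transfer_cells.csv"),
                             index=False)
        self.combined.to_csv(os.path.join(outdir, "combined_models.csv"),
                             index=False)
        import json
        with open(os.path.join(outdir, "wsrt_comparisons.json"), "w") as fh:
            json.dump({k: v.__dict__ for k, v in self.wsrt.items()}, fh,
                      indent=1)


def run_experiment(data, seed=0, tol=1e-6, max_iter=2000):
    """Run all 16 transfer conditions and the 8 combined-occurrence rows.

    Matched factor pairs are compared with :func:`wilcoxon_exact` over the 8
    cells that differ only in the factor under test (differences of the
    per-cell mean reciprocal AUC and of mean D).
    """
    cells = {}
    rows = []
    for thin, pred, feat, bg in itertools.product(*FACTORS.values()):
        cond = ExperimentCondition(thin, pred, feat, bg)
        cell = run_condition(cond, data, tol=tol, max_iter=max_iter)
        cells[cond.key] = cell
        rows.append({"thinning": thin, "predictor_set": pred,
                     "complexity": feat, "background": bg,
                     "auc_native_to_invaded": float(np.mean(cell.auc_native_to_invaded)),
                     "auc_invaded_to_native": float(np.mean(cell.auc_invaded_to_native)),
                     "auc_mean": cell.auc_mean, "schoener_d": cell.d_mean,
                     "n_replicates": len(cell.schoener_d_global)})
    transfer = pd.DataFrame(rows)

    combo_rows = []
    combo_seeds = np.random.SeedSequence(seed).spawn(8)
    for (thin, pred, feat), s in zip(
            itertools.product(FACTORS["thinning"], FACTORS["predictor_set"],
                              FACTORS["complexity"]), combo_seeds):
        mean_auc, per_rep = _combined_row(thin, pred, feat, data,
                                          seed=s, tol=tol, max_iter=max_iter)
        combo_rows.append({"thinning": thin, "predictor_set": pred,
                           "complexity": feat, "test_auc": mean_auc,
                           "n_replicates": len(per_rep)})
    combined = pd.DataFrame(combo_rows)

    wsrt = {}
    for factor, (lev_a, lev_b) in FACTORS.items():
        others = [f for f in FACTORS if f != factor]
        da, db = [], []
        for combo in itertools.product(*(FACTORS[f] for f in others)):
            sel = dict(zip(others, combo))
            row_a = transfer[(transfer[factor] == lev_a)
                             & np.logical_and.reduce(
                                 [transfer[f] == v for f, v in sel.items()])]
            row_b = transfer[(transfer[factor] == lev_b)
                             & np.logical_and.reduce(
                                 [transfer[f] == v for f, v in sel.items()])]
            da.append((float(row_a["auc_mean"].iloc[0]),
                       float(row_b["auc_mean"].iloc[0])))
            db.append((float(row_a["schoener_d"].iloc[0]),
                       float(row_b["schoener_d"].iloc[0])))
        auc_diffs = [a - b for a, b in da]
        d_diffs = [a - b for a, b in db]
        try:
            wsrt[f"{factor}:{lev_a}-vs-{lev_b}:auc"] = wilcoxon_exact(auc_diffs)
            wsrt[f"{factor}:{lev_a}-vs-{lev_b}:schoener_d"] = wilcoxon_exact(d_diffs)
        except ValueError as exc:  # all-zero differences
            warnings.warn(f"WSRT for factor {factor} skipped: {exc}")
    return ExperimentReport(transfer, combined, wsrt, cells)
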