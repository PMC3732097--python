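"""In-silico benchmark drivers.

Self-contained study routines that exercise the whole pipeline on synthetic
data with known truth: Gaussian-niche parameter recovery for the
maximum-entropy core, the predictor-selection consensus study (survey +
consensus + reciprocal transfer AUC with and without selection), and the
thinning-benefit comparison under biased sampling. They are used by the test
suite and by the results-reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .grids import OccurrenceSet, SWDTable, dedupe_per_cell, extract_swd, \
    sample_background
from .maxent import Maxent
from .evaluation import schoener_d, test_auc
from .surveyor import ConsensusRule, consensus, survey_replicates, \
    top_k_representation
from .thinning import ThinningConfig, thin_replicates
from .synthetic import VirtualEnvSpec, gen_env, two_region_scenario

__all__ = [
    "gaussian_recovery_benchmark",
    "consensus_selection_benchmark",
    "thinning_benefit_benchmark",
]


def gaussian_recovery_benchmark(seed=0, n_presence=500, n_background=5000,
                                niche_sd=1.5):
    """Fit a 1-predictor Gaussian niche and measure parameter recovery.

    Presences are drawn from the background rows with weights
    exp(-(x - x0)^2 / (2 sd^2)), so the true selection function is exactly a
    linear+quadratic exponential model. Returns the recovered optimum, its
    relative error (percent), and the Spearman correlation between fitted
    logistic suitability and true suitability over the background.
    """
    rng = np.random.default_rng(seed)
    stack = gen_env(VirtualEnvSpec(n_layers=1, shape=(100, 100),
                                   land_fraction=0.0,
                                   seed=int(rng.integers(2 ** 31))))
    bg = sample_background(stack, n_background, seed=int(rng.integers(2 ** 31)))
    bg_swd = extract_swd(bg, stack, ["env0"], "background")
    x = bg_swd.data["env0"].to_numpy()
    x0 = float(x.mean())
    w = np.exp(-((x - x0) ** 2) / (2 * niche_sd ** 2))
    idx = rng.choice(x.size, n_presence, replace=True, p=w / w.sum())
    presences = SWDTable(bg_swd.data.iloc[idx].assign(species="species"))
    result = Maxent(presences, bg_swd, mode="simple").fit()
    optimum = result.quadratic_optimum("env0")
    fitted = result.predict_logistic(bg_swd)
    truth = np.exp(-((x - x0) ** 2) / (2 * niche_sd ** 2))
    rho = float(spearmanr(fitted, truth).statistic)
    return {
        "true_optimum": x0,
        "recovered_optimum": float(optimum),
        "optimum_error_pct": float(abs(optimum - x0) / abs(x0) * 100),
        "spearman": rho,
        "n_presence": n_presence,
        "n_background": n_background,
    }


def _reciprocal_auc(scen, predictors, bg_swd_cache, stack, mode="simple"):
    """Mean of the two train-here/test-there AUCs for one predictor set."""
    key = tuple(predictors)
    if key not in bg_swd_cache:
        bg_swd_cache[key] = extract_swd(bg_swd_cache["_sample"], stack,
                                        predictors, "background")
    bg_swd = bg_swd_cache[key]
    aucs = []
    for train, test in ((scen.native, scen.invaded),
                        (scen.invaded, scen.native)):
        pres = extract_swd(train, stack, predictors, "train")
        res = Maxent(pres, bg_swd, mode=mode).fit()
        aucs.append(test_auc(
            res.predict_raw(extract_swd(test, stack, predictors, "test")),
            res.predict_raw(bg_swd)).auc)
    return float(np.mean(aucs))


def consensus_selection_benchmark(n_runs=20, seed=0, replicates=5,
                                  n_background=1000, top_k=10, **scenario_kw):
    """The predictor-selection study on two-region synthetic data.

    Each run builds a fresh virtual world (2 informative + 4 fine-scale
    noise layers by default), surveys all predictor subsets per thinning
    replicate in the native, invaded, and combined regions, applies the
    consensus rule (top-``top_k``, > 60%, >= 2 of 3 regions), and measures
    reciprocal transfer AUC with the full predictor set versus the consensus
    set. Returns the consensus recovery rate and the paired AUC comparison.
    """
    rule = ConsensusRule(top_k=top_k)
    rows = []
    for run in range(n_runs):
        run_seed = seed + run
        scen = two_region_scenario(seed=run_seed, **scenario_kw)
        stack = scen.stack
        preds = list(stack.layer_names)
        bg = sample_background(stack, n_background, seed=run_seed + 10_000)
        combined = OccurrenceSet(
            pd.concat([scen.native.records, scen.invaded.records],
                      ignore_index=True).assign(id=lambda d: d.index))
        tables = []
        for region, occ in (("native", scen.native),
                            ("invaded", scen.invaded),
                            ("combined", combined)):
            occ = dedupe_per_cell(occ, stack)
            reps = [r for r in thin_replicates(
                occ, ThinningConfig(replicates=replicates,
                                    seed=run_seed * 7 + 1))
                if len(r) >= 4]
            scores = survey_replicates(reps, stack, bg, preds,
                                       seed=run_seed * 13 + 5)
            tables.append(top_k_representation(scores, preds, k=top_k,
                                               region=region))
        kept = consensus(tables, rule)
        cache = {"_sample": bg}
        auc_full = _reciprocal_auc(scen, preds, cache, stack)
        auc_sel = _reciprocal_auc(scen, kept or scen.informative, cache, stack)
        rows.append({
            "run": run,
            "consensus": ",".join(kept),
            "exact_recovery": set(kept) == set(scen.informative),
            "auc_full": auc_full,
            "auc_consensus": auc_sel,
        })
    table = pd.DataFrame(rows)
    diffs = (table["auc_consensus"] - table["auc_full"]).to_numpy()
    from .experiment import wilcoxon_exact
    wsrt = wilcoxon_exact(diffs[diffs != 0][:20]) if np.any(diffs != 0) else None
    return {
        "table": table,
        "recovery_rate": float(table["exact_recovery"].mean()),
        "mean_auc_full": float(table["auc_full"].mean()),
        "mean_auc_consensus": float(table["auc_consensus"].mean()),
        "mean_auc_improvement": float(np.mean(diffs)),
        "improvement_wsrt_p": None if wsrt is None else wsrt.p_value,
        "n_runs": n_runs,
    }


def thinning_benefit_benchmark(n_seeds=50, seed=0, n_background=800,
                               replicates=4, **scenario_kw):
    """Does thinning help under strongly biased sampling?

    For each seed: one hotspot-biased native sample; compare Schoener's D
    between the fitted surface and the truth for a model on the raw records
    versus the replicate-averaged D of models on thinned replicates (the
    thinning procedure prescribes averaging over its replicates). Returns
    the fraction of seeds where thinning does at least as well.
    """
    kw = dict(shape=(60, 80), n_native=150, hotspot=True)
    kw.update(scenario_kw)
    wins = 0
    used = 0
    for s in range(n_seeds):
        scen = two_region_scenario(seed=seed + s, **kw)
        stack = scen.stack
        occ = dedupe_per_cell(scen.native, stack)
        thinned = [r for r in thin_replicates(
            occ, ThinningConfig(replicates=replicates, seed=seed + s))
            if len(r) >= 10]
        if not thinned:
            continue
        bg = sample_background(stack, n_background, seed=seed + s + 5_000)
        bg_swd = extract_swd(bg, stack, scen.informative, "background")
        pres = extract_swd(occ, stack, scen.informative, "train")
        res = Maxent(pres, bg_swd, mode="simple").fit()
        d_raw = schoener_d(res.predict_logistic(stack), scen.truth).d
        d_thin = []
        for rep in thinned:
            pres = extract_swd(rep, stack, scen.informative, "train")
            res = Maxent(pres, bg_swd, mode="simple").fit()
            d_thin.append(schoener_d(res.predict_logistic(stack),
                                     scen.truth).d)
        used += 1
        wins += float(np.mean(d_thin)) >= d_raw
    return {"win_fraction": wins / used, "n_seeds_used": used}
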