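"""Maximum-entropy core: features, penalized fitting, prediction."""

import numpy as np
import pandas as pd
import pytest

from nichecast.grids import SWDTable
from nichecast.maxent import (
    Maxent, build_features, default_class_multiplier, fit_maxent,
)

from conftest import make_swd


def multi_swd(n, p, seed=0, species="bg"):
    rng = np.random.default_rng(seed)
    data = {"species": species,
            "longitude": rng.uniform(-20, 20, n),
            "latitude": rng.uniform(-20, 20, n)}
    for j in range(p):
        data[f"v{j}"] = rng.uniform(j, j + 5, n)
    return SWDTable(pd.DataFrame(data))


class TestBuildFeatures:
    def test_simple_mode_two_per_predictor(self):
        bg = multi_swd(100, 4)
        feats = build_features(bg, mode="simple")
        assert feats.n_features == 2 * 4
        assert {f.kind for f in feats.features} == {"linear", "quadratic"}

    def test_auto_gate_closed_below_15_presences(self):
        bg = multi_swd(100, 3)
        auto = build_features(bg, mode="auto", n_presences=10)
        simple = build_features(bg, mode="simple")
        assert auto.feature_names == simple.feature_names

    def test_auto_feature_count_with_hinges(self):
        bg = multi_swd(200, 4)
        feats = build_features(bg, mode="auto", n_presences=25,
                               n_hinge_knots=10)
        # linear+quadratic per predictor plus 10 knots x 2 orientations
        assert feats.n_features == 2 * 4 + 2 * 10 * 4

    def test_scaling_maps_background_to_unit_interval(self):
        bg = multi_swd(150, 2, seed=3)
        feats = build_features(bg, mode="auto", n_presences=50)
        F = feats.design_matrix(bg)
        assert F.min() >= -1e-12 and F.max() <= 1 + 1e-12
        np.testing.assert_allclose(F.min(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(F.max(axis=0), 1, atol=1e-12)

    def test_constant_predictor_dropped_with_warning(self):
        bg = multi_swd(50, 2)
        bg.data["v0"] = 3.14
        with pytest.warns(UserWarning, match="constant"):
            feats = build_features(bg, mode="simple")
        assert all(f.predictor == "v1" for f in feats.features)

    def test_regularization_schedule(self):
        assert default_class_multiplier("linear", 10) == 1.0
        assert default_class_multiplier("quadratic", 30) == 0.2
        assert default_class_multiplier("linear", 500) == 0.05
        assert default_class_multiplier("hinge", 10) == 0.5


class TestFit:
    def test_presences_equal_background_gives_null_model(self):
        bg = multi_swd(400, 2, seed=1)
        pres = SWDTable(bg.data.copy())
        res = Maxent(pres, bg, mode="simple").fit()
        assert np.all(np.abs(res.params) < 1e-4)
        logistic = res.predict_logistic(bg)
        np.testing.assert_allclose(logistic, 0.5, atol=1e-4)

    def test_huge_penalty_zeroes_all_weights(self):
        bg = multi_swd(200, 3, seed=2)
        pres = SWDTable(bg.data.iloc[:40].copy())
        res = Maxent(pres, bg, mode="simple", beta_multiplier=1e6).fit()
        assert np.all(res.params == 0)

    def test_objective_ascends_every_iteration(self):
        bg = multi_swd(300, 2, seed=4)
        rng = np.random.default_rng(9)
        x = bg.data["v0"].to_numpy()
        w = np.exp(-(x - x.mean()) ** 2)
        idx = rng.choice(len(x), 80, p=w / w.sum())
        pres = SWDTable(bg.data.iloc[idx].copy())
        res = Maxent(pres, bg, mode="simple").fit()
        assert np.all(np.diff(res.objective_history) >= -1e-12)

    def test_kkt_conditions_hold_at_optimum(self):
        bg = multi_swd(300, 3, seed=5)
        rng = np.random.default_rng(10)
        idx = rng.choice(len(bg), 60)
        pres = SWDTable(bg.data.iloc[idx].copy())
        model = Maxent(pres, bg, mode="simple")
        res = model.fit(kkt_tol=1e-6)
        g = model._gradient(res.params)
        active = res.params != 0
        # |gradient| <= beta where the weight is zero; equality where active
        assert np.all(np.abs(g[~active]) <= model.betas[~active] + 1e-6)
        np.testing.assert_allclose(
            g[active], np.sign(res.params[active]) * model.betas[active],
            atol=1e-6)

    def test_sparsity_monotone_in_penalty(self):
        bg = multi_swd(300, 4, seed=6)
        rng = np.random.default_rng(11)
        x = bg.data["v1"].to_numpy()
        w = np.exp(-((x - x.mean()) / x.std()) ** 2)
        idx = rng.choice(len(bg), 100, p=w / w.sum())
        pres = SWDTable(bg.data.iloc[idx].copy())
        nnz = [Maxent(pres, bg, mode="simple", beta_multiplier=bm).fit().n_nonzero
               for bm in (0.5, 2.0, 8.0, 32.0, 128.0)]
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_gaussian_niche_optimum_recovery(self):
        """Presences ~ exp Gaussian over background: the implied quadratic
        optimum lands within 10% of the true one."""
        rng = np.random.default_rng(12)
        xb = rng.normal(5.0, 1.8, 5000).clip(0, 10)
        bg = make_swd(xb)
        x0, sd = 5.0, 1.5
        w = np.exp(-(xb - x0) ** 2 / (2 * sd * sd))
        idx = rng.choice(xb.size, 500, replace=True, p=w / w.sum())
        pres = SWDTable(bg.data.iloc[idx].assign(species="sp"))
        res = Maxent(pres, bg, mode="simple").fit()
        assert abs(res.quadratic_optimum("x") - x0) / x0 < 0.10

    def test_too_few_presences_rejected(self):
        bg = multi_swd(50, 1)
        pres = SWDTable(bg.data.iloc[:1].copy())
        with pytest.raises(ValueError):
            Maxent(pres, bg)


class TestPredict:
    @pytest.fixture
    def fitted(self):
        bg = multi_swd(400, 2, seed=20)
        rng = np.random.default_rng(21)
        x = bg.data["v0"].to_numpy()
        w = np.exp(-(x - 2.0) ** 2)
        idx = rng.choice(len(bg), 80, p=w / w.sum())
        pres = SWDTable(bg.data.iloc[idx].copy())
        model = Maxent(pres, bg, mode="simple")
        return model, model.fit()

    def test_raw_sums_to_one_over_training_background(self, fitted):
        model, res = fitted
        assert abs(res.predict_raw(model.background).sum() - 1.0) < 1e-8

    def test_stored_logZ_recomputable(self, fitted):
        from scipy.special import logsumexp
        model, res = fitted
        eta = model.features.design_matrix(model.background) @ res.params
        assert abs(res.logZ - logsumexp(eta)) < 1e-8

    def test_null_model_uniform_raw_and_half_logistic(self):
        bg = multi_swd(256, 1, seed=22)
        pres = SWDTable(bg.data.iloc[:30].copy())
        model = Maxent(pres, bg, beta_multiplier=1e9)
        res = model.fit()
        raw = res.predict_raw(bg)
        np.testing.assert_allclose(raw, 1.0 / 256, rtol=1e-10)
        # lambda = 0 means H = log N and eta + H = 0: logistic exactly 0.5
        np.testing.assert_allclose(res.predict_logistic(bg), 0.5, atol=1e-10)

    def test_logistic_preserves_raw_ranking_and_range(self, fitted):
        model, res = fitted
        raw = res.predict_raw(model.background)
        logistic = res.predict_logistic(model.background)
        assert np.all((logistic > 0) & (logistic < 1))
        np.testing.assert_array_equal(np.argsort(raw), np.argsort(logistic))

    def test_missing_predictor_column_rejected(self, fitted):
        _, res = fitted
        bad = make_swd(np.linspace(0, 1, 10), name="other")
        with pytest.raises(ValueError, match="missing predictor"):
            res.predict_raw(bad)

    def test_projection_respects_mask(self, small_stack):
        bg = multi_swd(200, 2, seed=23)
        bg.data.rename(columns={"v0": "alpha", "v1": "beta"}, inplace=True)
        bg = SWDTable(bg.data)
        pres = SWDTable(bg.data.iloc[:25].copy())
        res = Maxent(pres, bg, mode="simple").fit()
        grid = res.predict_logistic(small_stack)
        assert np.isnan(grid.values[~small_stack.valid_mask]).all()
        ok = grid.values[small_stack.valid_mask]
        assert np.all((ok > 0) & (ok < 1))

    def test_serialization_round_trips_weights(self, fitted, tmp_path):
        import json
        _, res = fitted
        path = tmp_path / "model.json"
        res.to_json(path)
        payload = json.loads(path.read_text())
        np.testing.assert_allclose(payload["weights"], res.params)
        assert payload["entropy"] == res.entropy
        assert payload["metadata"]["mode"] == "simple"

    def test_from_json_reproduces_predictions(self, fitted, tmp_path):
        from nichecast.maxent import MaxentResults
        model, res = fitted
        path = tmp_path / "model.json"
        res.to_json(path)
        loaded = MaxentResults.from_json(path)
        np.testing.assert_allclose(loaded.predict_raw(model.background),
                                   res.predict_raw(model.background))
        np.testing.assert_allclose(loaded.predict_logistic(model.background),
                                   res.predict_logistic(model.background))

    def test_functional_wrapper_matches_class(self):
        bg = multi_swd(200, 1, seed=30)
        pres = SWDTable(bg.data.iloc[:40].copy())
        r1 = fit_maxent(pres, bg, mode="simple")
        r2 = Maxent(pres, bg, mode="simple").fit()
        np.testing.assert_allclose(r1.params, r2.params)
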