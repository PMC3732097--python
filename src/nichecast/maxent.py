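"""Minimal maximum-entropy presence-background model.

The model fits a Gibbs distribution over background cells,

    q_lambda(x) = exp(lambda . f(x)) / Z,

choosing the feature weights ``lambda`` that maximize the L1-penalized
presence log-likelihood

    J(lambda) = mean_presences[lambda . f(x)] - log Z - sum_j beta_j |lambda_j|,

with per-feature penalties ``beta_j = beta_multiplier * class_multiplier *
sd_j(presences) / sqrt(n_presences)``. Features are linear, quadratic, and
(optionally) hinge transforms of the raw predictors, affinely scaled to [0, 1]
over the background sample. The familiar logistic output

    L(x) = q(x) e^H / (1 + q(x) e^H),

with H the entropy of the fitted distribution over the training background,
maps the raw density to (0, 1) so that a "typical" presence scores about 0.5
(the tau = 0.5 convention).

Organisation follows the statsmodels idiom: build a :class:`Maxent` model from
presence and background SWD tables, call :meth:`Maxent.fit`, and work with the
returned :class:`MaxentResults` (weights, logZ, entropy, diagnostics,
``summary()``, prediction and projection methods). Thin module-level
functions (:func:`build_features`, :func:`fit_maxent`, :func:`predict_raw`,
:func:`predict_logistic`) expose the same steps functionally.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .grids import EnvStack, SWDTable

__all__ = [
    "Feature",
    "FeatureExpansion",
    "SuitabilityGrid",
    "Maxent",
    "MaxentResults",
    "ConvergenceError",
    "build_features",
    "fit_maxent",
    "predict_raw",
    "predict_logistic",
    "default_class_multiplier",
]

# The classic sample-size-dependent regularization schedule: linear and
# quadratic features interpolate (n, multiplier) knots, hinge is constant.
_LQ_SCHEDULE = [(10.0, 1.0), (30.0, 0.2), (100.0, 0.05)]


def default_class_multiplier(kind, n_presences):
    """Class-level regularization multiplier as a function of sample size."""
    if kind == "hinge":
        return 0.5
    return float(np.interp(n_presences, *zip(*_LQ_SCHEDULE)))


class ConvergenceError(RuntimeError):
    """Optimizer failed to reach the requested tolerance."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class Feature:
    """One derived feature: a transform of a single source predictor.

    kind : 'linear' | 'quadratic' | 'hinge'
    knot : hinge knot location (raw predictor units); None otherwise.
    orientation : '+' for max(0, x - knot), '-' for max(0, knot - x).
    scale_min, scale_range : affine constants mapping the raw feature value
        to [0, 1] over the training background.
    """

    kind: str
    predictor: str
    knot: float = None
    orientation: str = None
    scale_min: float = 0.0
    scale_range: float = 1.0

    @property
    def name(self):
        if self.kind == "hinge":
            return f"hinge{self.orientation}({self.predictor}@{self.knot:.6g})"
        return f"{self.kind}({self.predictor})"

    def raw_value(self, x):
        if self.kind == "linear":
            return x
        if self.kind == "quadratic":
            return x * x
        if self.orientation == "+":
            return np.maximum(0.0, x - self.knot)
        return np.maximum(0.0, self.knot - x)

    def value(self, x):
        return (self.raw_value(np.asarray(x, dtype=float)) - self.scale_min) \
            / self.scale_range


@dataclass
class FeatureExpansion:
    """An ordered list of features over a fixed predictor set."""

    predictors: list
    features: list

    @property
    def n_features(self):
        return len(self.features)

    @property
    def feature_names(self):
        return [f.name for f in self.features]

    def design_matrix(self, table):
        """Feature matrix (n_points, n_features) from an SWD table or DataFrame."""
        if isinstance(table, SWDTable):
            df = table.data
        else:
            df = table
        missing = [p for p in self.predictors if p not in df.columns]
        if missing:
            raise ValueError(f"missing predictor columns: {missing}")
        cols = {p: df[p].to_numpy(float) for p in self.predictors}
        return np.column_stack([f.value(cols[f.predictor]) for f in self.features])


def build_features(background, mode="simple", n_presences=None,
                   n_hinge_knots=10):
    """Construct the feature expansion from the background sample.

    ``simple`` yields linear + quadratic features per predictor. ``auto``
    additionally yields hinge features (both orientations, knots at evenly
    spaced background quantiles) once ``n_presences >= 15`` — the sample-size
    gate of the classic auto-features rule. All scaling constants come from
    the background only.
    """
    if mode not in ("simple", "auto"):
        raise ValueError(f"unknown feature mode {mode!r}")
    if len(background) == 0:
        raise ValueError("background table is empty")
    predictors = background.layer_names
    use_hinge = mode == "auto" and n_presences is not None and n_presences >= 15
    features = []
    kept_predictors = []
    for pred in predictors:
        x = background.data[pred].to_numpy(float)
        if x.max() == x.min():
            warnings.warn(f"predictor {pred!r} is constant over the background; "
                          "its features are dropped")
            continue
        kept_predictors.append(pred)
        protos = [Feature("linear", pred), Feature("quadratic", pred)]
        if use_hinge:
            qs = np.quantile(x, (np.arange(n_hinge_knots) + 1) / (n_hinge_knots + 1))
            for knot in qs:
                if x.min() < knot < x.max():
                    protos.append(Feature("hinge", pred, knot=float(knot),
                                          orientation="+"))
                    protos.append(Feature("hinge", pred, knot=float(knot),
                                          orientation="-"))
        for proto in protos:
            raw = proto.raw_value(x)
            lo, hi = raw.min(), raw.max()
            if hi == lo:
                continue
            features.append(Feature(proto.kind, pred, proto.knot,
                                    proto.orientation, float(lo), float(hi - lo)))
    return FeatureExpansion(kept_predictors, features)


@dataclass
class SuitabilityGrid:
    """Per-cell logistic suitability on an EnvStack canvas (NaN off-mask)."""

    values: np.ndarray
    valid_mask: np.ndarray
    extent: tuple
    resolution: float
    nodata_value: float = -9999.0

    def write_ascii(self, path):
        from .grids import write_ascii_grid
        write_ascii_grid(path, np.where(self.valid_mask, self.values, np.nan),
                         self.extent, self.resolution, self.nodata_value)


class Maxent:
    """Maximum-entropy presence-background model.

    Parameters
    ----------
    presences, background : SWDTable
        Presence and background samples with matching predictor columns.
        Presences are *not* added to the background.
    features : FeatureExpansion, optional
        Prebuilt expansion; by default built from the background with ``mode``.
    mode : 'simple' | 'auto'
        Feature classes when ``features`` is not given.
    beta_multiplier : float
        Global multiplier on the per-feature L1 penalties.
    tau : float
        Logistic output at a typical presence (0.5, the classic default).
    """

    def __init__(self, presences, background, features=None, mode="simple",
                 beta_multiplier=1.0, tau=0.5, n_hinge_knots=10,
                 class_multipliers=None):
        if len(presences) < 2:
            raise ValueError("need at least 2 presence records")
        if features is None:
            features = build_features(background, mode=mode,
                                      n_presences=len(presences),
                                      n_hinge_knots=n_hinge_knots)
        if features.n_features == 0:
            raise ValueError("degenerate feature matrix: no usable features")
        self.presences = presences
        self.background = background
        self.features = features
        self.mode = mode
        self.beta_multiplier = float(beta_multiplier)
        self.tau = float(tau)
        self.class_multipliers = {
            kind: default_class_multiplier(kind, len(presences))
            for kind in ("linear", "quadratic", "hinge")}
        if class_multipliers:
            self.class_multipliers.update(class_multipliers)

        self._Fp = features.design_matrix(presences)
        self._Fb = features.design_matrix(background)
        self._presence_means = self._Fp.mean(axis=0)
        sd = self._Fp.std(axis=0, ddof=1)
        # linear/quadratic penalties scale with the presence spread (floored:
        # a feature constant over the presences must keep a positive penalty
        # or its weight diverges); hinge features take the constant 0.5/sqrt(n)
        # of the reference implementations
        base = np.array([
            self.class_multipliers["hinge"] if f.kind == "hinge"
            else self.class_multipliers[f.kind] * max(s, 0.05)
            for f, s in zip(features.features, sd)])
        self.betas = self.beta_multiplier * base / np.sqrt(len(presences))

    # -- objective pieces ---------------------------------------------

    def _loglik(self, lam):
        """Unpenalized objective: mean presence score minus log Z."""
        return float(self._presence_means @ lam - logsumexp(self._Fb @ lam))

    def _gradient(self, lam):
        eta = self._Fb @ lam
        q = np.exp(eta - logsumexp(eta))
        return self._presence_means - q @ self._Fb

    def _objective(self, lam):
        return self._loglik(lam) - float(self.betas @ np.abs(lam))

    def fit(self, tol=1e-9, max_iter=200, callback=None, kkt_tol=1e-5):
        """Maximize the penalized log-likelihood by proximal Newton ascent.

        Each outer iteration builds the exact quadratic model of the
        log-likelihood (Hessian = feature covariance under the current Gibbs
        distribution) and solves the resulting L1-penalized quadratic
        subproblem by coordinate descent, followed by a backtracking line
        search on the true penalized objective — the glmnet strategy, which
        is robust to the strong collinearity between linear and quadratic
        features of the same predictor. The iterates are monotone in the
        objective; convergence requires the L1 subgradient optimality
        conditions to hold within ``kkt_tol``. Raises
        :class:`ConvergenceError` otherwise.
        """
        m = self.features.n_features
        lam = np.zeros(m)
        obj = self._objective(lam)
        history = [obj]
        for it in range(max_iter):
            eta = self._Fb @ lam
            q = np.exp(eta - logsumexp(eta))
            g = self._presence_means - q @ self._Fb
            viol = self._kkt_violation(lam, g=g)
            if viol < kkt_tol:
                return self._make_results(lam, history, it, tol, converged=True)
            Fq = self._Fb * q[:, None]
            mean_f = q @ self._Fb
            cov = self._Fb.T @ Fq - np.outer(mean_f, mean_f)
            cov[np.diag_indices_from(cov)] += 1e-10  # guard singular models
            direction = _l1_quadratic_cd(lam, g, cov, self.betas) - lam
            # backtracking keeps the true objective monotone
            step = 1.0
            for _ in range(60):
                cand = lam + step * direction
                new_obj = self._objective(cand)
                if new_obj >= obj - 1e-13:
                    break
                step *= 0.5
            else:
                raise ConvergenceError(
                    "line search failed",
                    {"iteration": it, "objective": obj, "kkt_violation": viol})
            lam, obj = cand, new_obj
            history.append(obj)
            if callback is not None:
                callback(it, lam, obj)
        viol = self._kkt_violation(lam)
        if viol < kkt_tol:
            return self._make_results(lam, history, max_iter, tol,
                                      converged=True)
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations "
            f"(KKT violation {viol:.2e} > {kkt_tol:.0e})",
            {"iterations": max_iter, "objective": obj, "kkt_violation": viol})

    def _kkt_violation(self, lam, g=None):
        """Max violation of the L1 subgradient optimality conditions."""
        if g is None:
            g = self._gradient(lam)
        active = lam != 0
        v_inactive = np.maximum(np.abs(g[~active]) - self.betas[~active], 0.0)
        v_active = np.abs(g[active] - np.sign(lam[active]) * self.betas[active])
        parts = np.concatenate([v_inactive, v_active])
        return float(parts.max()) if parts.size else 0.0

    def _make_results(self, lam, history, n_iter, tol, converged):
        eta = self._Fb @ lam
        logZ = float(logsumexp(eta))
        logq = eta - logZ
        q = np.exp(logq)
        entropy = float(-(q @ logq))
        return MaxentResults(
            model=self, params=lam, logZ=logZ, entropy=entropy,
            n_iter=n_iter, tol=tol, converged=converged,
            objective_history=np.asarray(history),
            kkt_violation=self._kkt_violation(lam))


@dataclass
class MaxentResults:
    """Fitted maximum-entropy model: weights, normalization, diagnostics."""

    model: Maxent
    params: np.ndarray
    logZ: float
    entropy: float
    n_iter: int
    tol: float
    converged: bool
    objective_history: np.ndarray
    kkt_violation: float

    @property
    def feature_names(self):
        return self.model.features.feature_names

    @property
    def n_nonzero(self):
        return int(np.count_nonzero(self.params))

    def linear_predictor(self, table):
        return self.model.features.design_matrix(table) @ self.params

    def predict_raw(self, table):
        """Gibbs density e^{lambda.f(x)} / Z (Z from the training background)."""
        return np.exp(self.linear_predictor(table) - self.logZ)

    def predict_logistic(self, target):
        """Logistic suitability in (0, 1); on an EnvStack, a SuitabilityGrid."""
        if isinstance(target, EnvStack):
            return self._project(target)
        from scipy.special import expit
        eta = self.linear_predictor(target) - self.logZ + self.entropy
        return expit(eta)

    def _project(self, stack):
        rows, cols = np.nonzero(stack.valid_mask)
        df = pd.DataFrame({name: stack.layer(name)[rows, cols]
                           for name in self.model.features.predictors})
        from scipy.special import expit
        eta = (self.model.features.design_matrix(df) @ self.params
               - self.logZ + self.entropy)
        vals = np.full(stack.valid_mask.shape, np.nan)
        vals[rows, cols] = expit(eta)
        return SuitabilityGrid(vals, stack.valid_mask.copy(), stack.extent,
                               stack.resolution, stack.nodata_value)

    def quadratic_optimum(self, predictor):
        """Niche optimum implied by the linear+quadratic weights of a predictor.

        Undoes the [0, 1] feature scaling: with eta = a x + b x^2 + const the
        optimum is -a / (2 b). Requires a negative effective curvature.
        """
        feats = self.model.features.features
        a = b = 0.0
        for w, f in zip(self.params, feats):
            if f.predictor != predictor:
                continue
            if f.kind == "linear":
                a += w / f.scale_range
            elif f.kind == "quadratic":
                b += w / f.scale_range
        if b >= 0:
            raise ValueError("no interior optimum: curvature is non-negative")
        return -a / (2.0 * b)

    def summary(self):
        """Human-readable fit summary (weights, penalties, diagnostics)."""
        lines = [
            "Maximum-entropy presence-background model",
            "=" * 57,
            f"presences: {len(self.model.presences):>6}    "
            f"background: {len(self.model.background):>6}",
            f"features:  {len(self.params):>6}    nonzero:    {self.n_nonzero:>6}",
            f"mode: {self.model.mode}    beta_multiplier: "
            f"{self.model.beta_multiplier:g}    tau: {self.model.tau:g}",
            f"logZ: {self.logZ:.6f}    entropy H: {self.entropy:.6f}",
            f"converged: {self.converged} in {self.n_iter} iterations "
            f"(KKT violation {self.kkt_violation:.2e})",
            "-" * 57,
            f"{'feature':<36}{'weight':>12}{'beta':>9}",
        ]
        for name, w, b in zip(self.feature_names, self.params, self.model.betas):
            if w != 0:
                lines.append(f"{name:<36}{w:>12.5f}{b:>9.4f}")
        return "\n".join(lines)

    # -- serialization -------------------------------------------------

    def to_json(self, path=None):
        payload = {
            "format": "nichecast-maxent",
            "version": 1,
            "predictors": self.model.features.predictors,
            "features": [
                {"kind": f.kind, "predictor": f.predictor, "knot": f.knot,
                 "orientation": f.orientation, "scale_min": f.scale_min,
                 "scale_range": f.scale_range}
                for f in self.model.features.features
            ],
            "weights": self.params.tolist(),
            "logZ": self.logZ,
            "entropy": self.entropy,
            "tau": self.model.tau,
            "metadata": {
                "n_presences": len(self.model.presences),
                "n_background": len(self.model.background),
                "mode": self.model.mode,
                "beta_multiplier": self.model.beta_multiplier,
                "n_iter": self.n_iter,
                "converged": self.converged,
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path):
        """Rebuild a fitted model from its serialized form.

        The returned results object predicts and projects; the training
        tables themselves are not stored, so refitting is not possible.
        """
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "nichecast-maxent":
            raise ValueError(f"{path} is not a serialized maxent model")
        features = FeatureExpansion(
            list(payload["predictors"]),
            [Feature(f["kind"], f["predictor"], f["knot"], f["orientation"],
                     f["scale_min"], f["scale_range"])
             for f in payload["features"]])
        model = Maxent.__new__(Maxent)
        model.features = features
        model.mode = payload["metadata"]["mode"]
        model.tau = payload["tau"]
        model.beta_multiplier = payload["metadata"]["beta_multiplier"]
        model.presences = None
        model.background = None
        model.betas = np.full(features.n_features, np.nan)
        return cls(model=model, params=np.asarray(payload["weights"]),
                   logZ=payload["logZ"], entropy=payload["entropy"],
                   n_iter=payload["metadata"]["n_iter"], tol=np.nan,
                   converged=payload["metadata"]["converged"],
                   objective_history=np.empty(0), kkt_violation=np.nan)


def _soft_threshold(x, t):
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _l1_quadratic_cd(lam, g, cov, betas, sweeps=200, tol=1e-12):
    """Coordinate-descent solution of the L1-penalized quadratic model.

    Maximizes g.(z - lam) - 0.5 (z - lam)' cov (z - lam) - betas.|z| over z,
    the local model of the penalized log-likelihood around ``lam``.
    """
    z = lam.copy()
    v = np.zeros_like(z)  # cov @ (z - lam), maintained incrementally
    diag = np.diag(cov)
    for _ in range(sweeps):
        max_delta = 0.0
        for j in range(z.size):
            if diag[j] <= 0:
                continue
            # unregularized coordinate optimum given the others
            c = diag[j] * z[j] + g[j] - v[j]
            new = _soft_threshold(c, betas[j]) / diag[j]
            delta = new - z[j]
            if delta != 0.0:
                v += cov[:, j] * delta
                z[j] = new
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            break
    return z


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def fit_maxent(presences, background, features=None, beta_multiplier=1.0,
               tol=1e-8, max_iter=5000, **kwargs):
    """Fit a maximum-entropy model; functional wrapper around :class:`Maxent`."""
    model = Maxent(presences, background, features=features,
                   beta_multiplier=beta_multiplier, **kwargs)
    return model.fit(tol=tol, max_iter=max_iter)


def predict_raw(results, points):
    return results.predict_raw(points)


def predict_logistic(results, target):
    return results.predict_logistic(target)
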