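# Methods

`nichecast` builds presence-only species distribution models (SDMs) that are
meant to *transfer*: trained on occurrences from one geographic region and
projected onto another. This note documents the models and procedures it
implements, the numerical choices behind them, and what the synthetic
benchmarks do and do not demonstrate.

## Data model and preprocessing

Environmental predictors live on a stack of co-registered lat/lon rasters
(`EnvStack`) with square, cell-center-registered cells and a shared ocean/land
validity mask; a cell that is nodata in *any* layer is invalid in the whole
stack. Points map to cells with half-open intervals `[edge, edge+resolution)`.
File I/O uses the ESRI ASCII grid format; occurrences and samples-with-data
(SWD) tables are plain CSV.

Record preprocessing mirrors standard marine SDM practice: records falling on
land are moved to the center of the nearest ocean cell (great-circle distance
between cell centers; exact ties resolved to the smallest (row, column) index
for reproducibility), and multiple records per cell are collapsed to one (the
smallest record id is retained). Background samples of n cells are drawn
without replacement with probability proportional to cos(latitude) — the
equal-area correction for the poleward shrinkage of lat/lon cells — either
globally or inside a regional bounding box. A with-replacement mode exists
only for statistical tests of the sampling law.

## Occurrence thinning

Geographically biased sampling (dense survey effort near ports and marinas,
sparse elsewhere) distorts presence-only estimates. The thinning procedure
computes a binned two-dimensional Gaussian kernel density of the records
(linear binning onto a regular grid, then separable Gaussian convolution;
bandwidth is the kernel standard deviation in degrees, default 3.0),
normalizes it to a maximum of 1, and removes each record independently with
probability

* 0 where the normalized density d < t1 (default 0.5),
* d where t1 <= d < t2,
* 1 where d >= t2 (default 1.0).

The procedure is repeated over independent replicates (default 10) whose
seeds are spawned deterministically from the configuration seed, and
downstream analyses propagate all replicates. Numerical choices: the density
grid extends 6 bandwidths beyond the record bounding box and the convolution
is truncated at 8 standard deviations, which keeps the discrete integral
within 1e-6 of 1; the gate thresholds are applied to a bilinear interpolation
of the surface at record positions (nearest-node interpolation is available
for exact-oracle tests); grid size defaults to 201 nodes per axis.

## Maximum-entropy model core

The model is the classic presence-background maximum-entropy (Maxent) family:
a Gibbs distribution over background cells, q(x) ∝ exp(λ·f(x)), fitted by
maximizing the L1-penalized presence log-likelihood

    J(λ) = mean_presences[λ·f(x)] − log Σ_background e^{λ·f(x)} − Σ_j β_j |λ_j|.

Features f are linear and quadratic transforms of each predictor ("simple"
mode), plus hinge ramps in both orientations at 10 evenly spaced background
quantiles when the sample has at least 15 presences ("auto" mode — the
classic sample-size gate). Every feature is affinely scaled to [0, 1] over
the background; scaling constants never see the presences. Presences are not
added to the background.

Per-feature penalties follow the published reference behavior: for linear
and quadratic features β_j = m(n) · max(sd_j, 0.05) / √n, where sd_j is the
presence standard deviation of the scaled feature and m(n) interpolates the
classic sample-size schedule (1.0 at n ≤ 10, 0.2 at 30, 0.05 at n ≥ 100);
hinge features take the constant 0.5/√n. The sd floor matters: a feature
constant across the presences would otherwise carry zero penalty and its
weight would diverge. A global `beta_multiplier` rescales all penalties.

The optimizer is proximal Newton (the glmnet strategy): at each step the
exact quadratic model of the log-likelihood — whose Hessian is the feature
covariance under the current Gibbs distribution, ridge-stabilized by 1e-10 —
is solved under the L1 penalty by coordinate descent, followed by a
backtracking line search on the true objective, so the objective is monotone
non-decreasing. A first-order method is not an option here: linear and
quadratic features of the same predictor are nearly collinear and gradient
descent stalls in the resulting valley. Convergence is accepted only when
the L1 subgradient conditions hold (|∂J/∂λ_j| ≤ β_j at zero weights, equality
with sign at active ones) within `kkt_tol` (default 1e-5); otherwise the fit
raises with diagnostics rather than returning a silently unconverged model.

Predictions: `predict_raw` returns e^{λ·f(x)}/Z with Z from the training
background (the raw values over the training background sum to 1);
`predict_logistic` applies the entropy calibration L = q·e^H / (1 + q·e^H),
with H the entropy of the fitted distribution over the training background,
so that a null model (λ = 0) scores exactly 0.5 everywhere (the τ = 0.5
convention). Projection onto an `EnvStack` yields a suitability grid with
nodata exactly off the ocean mask. This is a re-implementation of the model
family, not a port of any particular program, and its contract is the
optimality conditions and the identities above, not output equality with
other software.

## Evaluation and transferability metrics

* **Test AUC** is the rank-based Mann–Whitney estimator with midranks for
  ties, computed between presence scores and background scores; it is
  invariant under strictly monotone transforms of the scores.
* **Schoener's D** between two suitability surfaces: both are normalized to
  sum 1 over the cells valid in *both* grids, and D = 1 − ½ Σ|p̂ − q̂| —
  one minus the total variation distance (1 identical, 0 disjoint).
* **MESS/MoD**: per predictor the similarity of a target value v to the
  training sample is 100(v−min)/(max−min) when v is below all training
  values, 2f when the strictly-below percentage f ≤ 50, 2(100−f) when
  f < 100, and 100(max−v)/(max−min) above the range. MESS is the minimum
  over predictors; MoD the argmin (ties to the first predictor in layer
  order). MESS < 0 flags extrapolation beyond the training range.
* **Thresholding**: the 10-percentile-training rule resolves to the largest
  attained prediction value with fewer than 10% of training predictions
  strictly below it (the lower-interpolation percentile, so the reported
  threshold is an attained value); equal-sensitivity-specificity scans the
  attained scores with the background as pseudo-absences. Binarization uses
  ≥ (cells at the threshold are suitable). A coastal mask restricts maps to
  valid cells less than k pixels (Chebyshev distance, default 7) from the
  nearest land cell.

## Predictor-subset survey and consensus

For p candidate predictors all 2^p − 1 non-empty subsets are scored: one
random 50/50 presence split per replicate (shared by all subsets, so the
comparison is paired), a simple-features model per subset on the training
half, test AUC on the held-out half against the shared background. Subsets
are ranked by test AUC with ties preferring smaller subsets, then smaller
bitmask; degenerate subsets are excluded rather than scored zero. Per
replicate the predictors in the top-k (default 10) models are tallied;
summaries are percentages over replicates. The consensus keeps predictors
whose representation is strictly above 60% in at least 2 of 3 regions
(native, invaded, combined); both the strictness and the threshold are
configurable.

## The multifactorial experiment

Four binary choices are crossed — thinning on/off, predictor set
full/consensus, features simple/auto, background global/regional — into 16
transfer conditions. Per condition and thinning replicate, models are
trained in each region and (a) scored by reciprocal test AUC (the other
region's records as test presences against the global background — the only
background shared by all conditions), averaged over the two directions, and
(b) projected globally to compute Schoener's D between the two surfaces.
With thinning off the replicates are identical, so the condition runs once.
A companion 8-row table trains on the pooled two-region occurrences with a
random 50/50 split and global background. Matched condition pairs are
compared with an exact Wilcoxon signed-rank test: zero differences dropped,
midranks for tied magnitudes, the null distribution of the signed rank sum
enumerated over all 2^n sign assignments (n ≤ 20), p = twice the smaller
tail, capped at 1.

## Synthetic worlds

The generator emulates the structure of multi-layer marine environmental
grids without mimicking any real dataset. Layers are white noise smoothed by
a Gaussian of the autocorrelation length (in cells), standardized, optionally
pairwise-correlated by mixing, and rescaled to a common range (0–10 by
default); the land mask is a smoothed-noise field thresholded at the land
fraction (coast-like blobs) or a longitudinal split. The virtual species has
Gaussian responses on a subset of informative layers — suitability is the
product of the per-layer responses, so linear+quadratic features are exactly
well-specified — with an optional misspecified (skewed) response and an
optional region-specific truncation of the fundamental niche. Occurrences
are drawn without replacement over cells with probability proportional to
suitability × survey effort × cos(latitude); effort is a baseline plus
Gaussian hotspots.

The default two-region study (`two_region_scenario`) uses a 80×100 grid
(1.25° cells), 25% land, six layers, and a species with tolerance 0.8 (layer
units; layers have sd ≈ 1.7) responding to the first two layers — a
specialist occupying roughly a tenth of the available environment, chosen
because a generalist whose suitability is high over half the map leaves no
between-region signal for any method to transfer. Two design choices deserve
emphasis:

* **Noise layers vary at finer spatial scales than informative ones**
  (autocorrelation 2 vs 8 cells). With equally broad scales, spatially
  clustered presences pin the local values of *any* smooth layer, so
  "noise" layers genuinely improve within-region test AUC (spatial
  pseudo-replication) and no survey procedure could reject them. Fine-scale
  noise is what "uninformative predictor" has to mean for a
  presence-background survey: its values at presence sites are exchangeable
  with background draws.
* **The survey-effort hotspot sits at a marginally suitable site** (true
  suitability 0.05–0.35, intensity 100×, radius 4°), emulating effort
  concentrated at ports rather than at the species' niche center; this is
  the regime in which density thinning demonstrably helps, because the
  dense cluster drags the niche estimate toward the hotspot's environment.

What passing the synthetic benchmarks shows — and does not. They show the
pipeline recovers a known niche from biased presence-only samples, that the
exhaustive survey plus cross-region consensus identifies the truly
informative predictors under realistic spatial structure, and that predictor
selection improves between-region transfer when irrelevant predictors would
otherwise absorb regional idiosyncrasies. They do not show anything about
dispersal limitation, biotic interactions, niche shifts between ranges,
observation error in coordinates, or correlated informative predictors —
real-data complications the generator deliberately omits.

## Benchmark problem sizes

The packaged studies run at sizes chosen to make the full suite quick on a
single CPU while keeping every effect measured rather than assumed:
parameter recovery uses 500 presences against 5,000 background points on a
100×100 all-ocean grid; the consensus study runs 20 seeded worlds (80×100
grid, 6 predictors = 63 subsets, 5 thinning replicates per region, 1,000
background points); the thinning comparison uses 60×80 grids over 30–50
seeds; the 16-condition experiment example uses a 50×80 grid with 3
replicates and 600 background points. All randomness flows from explicit
seeds; reruns are bit-identical.

## Known limitations

* Product and threshold feature classes are not implemented (they are never
  activated at the sample sizes this workflow targets); neither are
  clamping/fade extrapolation modes — use MESS/MoD to diagnose
  extrapolation instead.
* The regularization schedule reproduces the reference defaults only
  approximately (linear interpolation between published knots).
* Schoener's D is computed on logistic output by default (the quantity that
  is mapped); raw output can be compared instead by passing raw grids.
* Thinning is single-pass: the density surface is not recomputed after
  removals.
* No map reprojection; everything is plain geographic lat/lon.
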