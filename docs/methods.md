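# Methods

## Model and estimation

`catchmsi` classifies a binary outcome Y (1 = MSS, 2 = MSI) from a
metabolite tensor **M** (d₁ × d₂ per sample) and a covariate vector
**G** ∈ ℝ^q of metabolic-gene expression. The generative view is a
covariate-adjusted tensor discriminant model: given class k,

* G ~ N(φ_k, Ψ),
* M = μ_k + α ×̄₃ G + E, with E matrix-normal with separable covariance
  (Σ₁, Σ₂) independent of G,

so M^adj = M − α ×̄₃ G and G are conditionally independent given class and
the log-likelihood ratio is linear: a₂ + γ₂ᵀG + ⟨B, M^adj⟩ with
B = Σ₁⁻¹(μ₂−μ₁)Σ₂⁻¹ and γ₂ = Ψ⁻¹(φ₂−φ₁). Only the Bayes rule is taken as
given; the estimators are the package's own completion of it:

1. **α** — pooled within-class least squares of every tensor cell on G
   (class means removed from both sides). Solved in one Cholesky solve of
   the pooled covariate Gram matrix against all d₁·d₂ cross-covariance
   columns. Requires n > q + 2, or a ridge.
2. **Moments** — within-class means μ̂_k of the adjusted tensors; row
   covariance Σ̂₁ ∝ Σ_s R_sR_sᵀ / ((n−2)d₂), normalized to Σ̂₁[0,0] = 1
   because the Kronecker factorization Σ₁ ⊗ Σ₂ is only identified up to a
   scalar; then one flip-flop step Σ̂₂ = Σ_s R_sᵀΣ̂₁⁻¹R_s / ((n−2)d₁). The
   flip-flop step matters: the plain un-weighted column moment is only
   scale-consistent when tr(Σ₁) = d₁, whereas Σ̂₁ ⊗ Σ̂₂ as computed here is
   consistent for arbitrary separable covariances (verified by a
   Kronecker-scale recovery test).
3. **B** — coordinate descent on
   ½⟨B, Σ̂₁BΣ̂₂⟩ − ⟨B, μ̂₂−μ̂₁⟩ + λ‖B‖₁, with the exact univariate
   soft-threshold update per cell and an incrementally maintained product
   Σ̂₁BΣ̂₂ (refreshed every 64 sweeps to cap floating-point drift). Each
   update is an exact coordinate minimization, so the objective is
   non-increasing by construction; the test suite asserts this on every
   sweep. Convergence: max cell change < 1e-8, cap 10⁴ sweeps, error on
   non-convergence. λ ≥ max|μ̂₂−μ̂₁| provably gives B = 0 (KKT condition at
   the origin), which anchors the penalty path.
4. **γ₂, a₂** — pooled-covariance LDA on G (reference-class convention
   γ₁ = a₁ = 0) and the LDA intercept
   a₂ = log(π₂/π₁) − ½γ₂ᵀ(φ̂₁+φ̂₂) − ½⟨B, μ̂₁+μ̂₂⟩.

Prediction thresholds the linear score at zero; a tie (score exactly 0)
goes to MSS, the prevalent class. The monotone probability wrapper around
the score adds nothing to the argmax and is dropped.

### Penalty selection

Three modes, mutually exclusive:

* `penalty=λ` fixed;
* `cv=K` (default 5 when nothing is specified): stratified K-fold CV over
  20 log-spaced values from λ_max down to 0.01·λ_max, maximizing CV
  accuracy, ties resolved toward the sparser (larger) λ, with warm starts
  along the descending path;
* `n_features=K`: bisect λ on [0, λ_max] until exactly K cells are
  selected (60 bisection steps; if a plateau jump makes K unreachable the
  nearest achievable count is used with a warning). This mirrors reporting
  a fixed-size metabolite signature and is what the recovery experiments
  use, with K set to the generating support size — it makes support
  recovery a well-posed comparison rather than a function of CV noise.

### Numerical choices and degenerate inputs

* Standardization is z-scoring with the sample (ddof = 1) standard
  deviation, fit on training samples only and applied unchanged to test
  samples; constant columns are dropped with a warning and recorded.
* Near-singular covariate covariances (S_G or Ψ̂): error by default;
  `ridge='auto'` retries with ε = 10⁻⁶·tr/dim added to the diagonal and
  warns; a numeric ridge is applied unconditionally.
* Non-positive-definite mode covariances abort the coordinate descent
  with an explicit error rather than silently regularizing.
* A class with fewer than two samples, or residuals with zero variance at
  the anchor cell (0,0), raise informative errors.
* Padded tensor cells (when d₁d₂ > p) are identically zero, pinned out of
  the discriminant, and excluded from selection and naming.

## Tensorization

Metabolite vectors are folded row-major in input column order into
d₁ × d₂ = ⌈√p⌉ × ⌈√p⌉ by default (15 × 15 for a 225-metabolite panel);
explicit dimensions are accepted. No ordering of metabolites is canonical,
so the fold is recorded in an invertible FeatureMap making every reported
cell auditable back to a metabolite name. Folding is linear and exactly
invertible on real cells, properties the test suite asserts.

## Cohort matching

Controls are frequency-matched — stratum proportions, not 1:1 pairs — on
the joint (lineage group, APC, TP53) stratum at a fixed ratio (default
1:3), drawing uniformly without replacement within each stratum. Short
strata backfill by relaxing the key one component at a time in the fixed
order lineage → TP53 → APC, preserving mutation balance as long as
possible; every relaxed draw is logged. Raw lineage strings collapse into
five groups (GI, Breast/GYN, Hema, GU, other) through a user-editable
mapping; unknown strings are an error, not a silent "other".

## Synthetic cohorts

The generator emulates a matched case-control metabolomics study:

* fixed class counts — n_cases MSI and ratio·n_cases MSS in seed-shuffled
  order (a frequency-matched design has no sampling variability in its
  arm sizes, so priors are exact);
* stratum labels drawn per class from a joint (lineage × APC × TP53)
  table whose defaults reproduce the emulated cohort's composition
  (lineage shared across arms: GI 33.3%, Breast/GYN 34.7%, Hema 17.3%,
  remainder split GU/other; APC mutant 25.3% cases vs 20.4% controls;
  TP53 mutant 32% in both). Strata are independent of the molecular data
  given class: they exist to exercise matching;
* G ~ N(φ_k, I_q) with φ₂ − φ₁ = shift·**1**/√q (norm = `covariate_shift`,
  default 1) — Gaussian covariates are an assumption of convenience, made
  once and documented here;
* M = μ_k + α ×̄₃ G + E with E matrix-normal, AR(1) row/column
  correlations (ρ = 0.3 default, unit diagonal — so `delta` is an effect
  size in noise-sd units and the Σ̂₁[0,0] = 1 convention matches truth);
  μ₂ − μ₁ = delta·(alternating ±1) on s seed-chosen support cells
  (default s = 8, delta = 1); α has a Bernoulli(`alpha_density` = 0.1)
  support with entries ±`alpha_scale` (= 0.3).

`make_confounded_feature` forces one support cell's α row to
−(μ₂−μ₁)[cell]·(φ₂−φ₁)/‖φ₂−φ₁‖², cancelling the marginal class contrast
exactly while the direct effect stays at delta — the engineered analogue
of a metabolite that looks null marginally and significant after
adjustment. It requires delta, alpha_scale and covariate_shift all
nonzero; degenerate requests error.

The GroundTruth object exposes the population Bayes rule and its
closed-form accuracy: the score is within-class Gaussian with variance
Δ² = ‖φ₂−φ₁‖² + ⟨μ₂−μ₁, Σ₁⁻¹(μ₂−μ₁)Σ₂⁻¹⟩ and means log(π₂/π₁) ± Δ²/2,
giving accuracy π₂Φ((c+Δ²/2)/Δ) + π₁Φ((Δ²/2−c)/Δ).

What the generator does **not** emulate: missing values and imputation
artifacts, non-Gaussian or heavy-tailed abundance distributions,
batch/plate effects, non-separable noise covariance, and any dependence of
stratum labels on the molecular data. Tests passing on these cohorts
therefore certify the estimators and the pipeline plumbing under the
model's own assumptions, not robustness to real-data pathologies.

## Evaluation protocol

Repeated stratified splits: per class, round-half-up of n_k·0.10 samples
to the test partition (75/225 at 0.10 gives 8 + 23), refit everything on
the training split (standardizer included, so no leakage), score the test
split, average per-iteration metrics over 100 iterations. Averaging
per-iteration metrics (not pooling confusion counts) is deliberate — the
two differ, and per-iteration averaging is the convention this protocol
follows. MSI is the positive class throughout; 0/0 ratios report 0 and are
flagged. The baseline is a 500-tree random forest (library defaults
otherwise, seeded per iteration) on the unstandardized flat
[metabolites | genes] matrix, consuming byte-identical splits.

Wilcoxon rank-sum tests (two-sided) use exact enumeration when both
groups have ≤ 12 members and no ties, else the normal approximation with
tie and continuity corrections; scipy's implementation is the engine, with
the exact branch independently verified against a full enumeration oracle
in the tests. Significance is read at p < 0.05. The significance table
reports each selected feature under three variants — raw column,
standardized column, adjusted tensor cell — which is the package's
diagnostic for confounding.

## Problem sizes used in the shipped experiments

The test and acceptance runs use cohorts of 300–600 samples with 5 × 5
tensors and q = 10 covariates (scaled-down but fully determined analogues
of the 300-sample, 15 × 15, q = 87 study design), 20-seed recovery
batches, 50-seed confounding batches with 200-seed null calibration, and
one 10⁵-sample cohort for Bayes-rule consistency. These sizes were chosen
so every experiment is exactly reproducible from a single seed while still
giving the asymptotics room to show (e.g. the α RMSE ratio between n = 100
and n = 400 lands near its theoretical 0.5).

## Known limitations

* Two classes and order-2 tensors only; no p-values on B̂.
* CV inside `fit` reuses the training standardization across folds; the
  outer protocol's train/test separation is leakage-free, which is what
  matters for the reported metrics.
* The one-step flip-flop covariance estimator is not the full MLE; for
  the AR(1)-structured truths used here the difference is negligible, and
  the discriminant only needs the covariances up to their product.
* `n_features` bisection assumes the selected-cell count is monotone in
  λ; plateaus can make an exact count unreachable (warned, nearest count
  used).
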