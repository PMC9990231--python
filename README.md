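# catchmsi

Covariate-adjusted tensor classification of microsatellite instability
(MSI) from metabolomic profiles, with metabolic-gene expression treated as
a confounding covariate.

## The problem

The metabolome is the closest molecular readout of a cancer cell's
phenotype, but metabolite levels are partly driven by the expression of
metabolic enzyme genes. When those genes also track the outcome of
interest — here MSI versus microsatellite-stable (MSS) status — a naive
two-sample analysis confuses gene-driven metabolite shifts with metabolite
effects proper. `catchmsi` implements covariate-adjusted tensor
classification (CATCH) for this setting: it removes the gene-expression
component of each metabolite measurement *before* discrimination, so the
selected metabolite features carry a direct effect on MSI status rather
than an echo of transcription.

It is written for computational biologists working with paired
metabolomics/transcriptomics panels (for example DepMap/CCLE-style
cell-line tables: p metabolite columns and q metabolic-gene columns per
sample) who want a sparse, interpretable MSI classifier plus the
feature-gene coupling estimates that explain it.

## The model

Each sample carries a metabolite tensor **M** (the p metabolite values
z-scored and folded row-major into a d₁ × d₂ matrix), a covariate vector
**G** ∈ ℝ^q, and a label Y (1 = MSS, 2 = MSI). The adjusted tensor is

    M^adj = M − α ×̄₃ G

where α (d₁ × d₂ × q) holds the within-class regression of every tensor
cell on **G**. Classification is the Bayes rule of a linear discriminant
on (M^adj, G) under a tensor-normal model with separable row/column
covariance (Σ₁, Σ₂):

    Ŷ = 2  ⇔  a₂ + γ₂ᵀG + ⟨B, M^adj⟩ > 0

* **B** (d₁ × d₂) — the sparse *direct-effect* tensor, estimated by an
  ℓ₁-penalized discriminant `argmin_B ½⟨B, Σ̂₁BΣ̂₂⟩ − ⟨B, μ̂₂−μ̂₁⟩ + λ‖B‖₁`
  solved with cyclic coordinate descent. Its nonzero cells are the
  selected metabolite features; positive values indicate MSI association.
* **γ₂** = Ψ̂⁻¹(φ̂₂−φ̂₁) — the LDA direction on the covariates themselves.
* **a₂** — the LDA intercept `log(π₂/π₁) − ½γ₂ᵀ(φ̂₁+φ̂₂) − ½⟨B, μ̂₁+μ̂₂⟩`.
* α's rows for the selected cells form the feature × gene association
  matrix linking each selected metabolite to the genes that modulate it.

The penalty λ is chosen by stratified cross-validation, fixed, or bisected
to select an exact number of features. The package also ships 1:k
frequency matching of MSS controls to MSI cases on (lineage, APC, TP53)
strata, a synthetic cohort generator with known ground truth, and the
repeated stratified 90/10 split evaluation protocol with a random-forest
comparator on the flat [metabolites | genes] matrix.

## Worked example

```python
from catchmsi import (CatchClassifier, select_features,
                      adjustment_significance_table,
                      SplitSpec, repeated_evaluation)
from catchmsi.synthetic import (SimulationConfig, make_confounded_feature,
                                generate_cohort)

# 75 MSI cases + 225 MSS controls; 25 metabolites folded 5x5; 10 genes.
# Cell (2, 2) is engineered so genes exactly cancel its marginal contrast.
cfg = make_confounded_feature(
    SimulationConfig(n_cases=75, control_ratio=3, d1=5, d2=5, q=10, s=5,
                     delta=1.0, alpha_density=0.2, alpha_scale=0.5, seed=11),
    (2, 2))
cohort, truth = generate_cohort(cfg)

clf = CatchClassifier(d1=5, d2=5, n_covariates=10, n_features=5,
                      random_state=0)
clf.fit(cohort.design_matrix(), cohort.labels)
print(select_features(clf)[["feature", "coefficient"]].round(3))
print(adjustment_significance_table(cohort, clf).round(4))

report = repeated_evaluation(cohort, SplitSpec(iterations=20, seed=0),
                             catch_params=dict(d1=5, d2=5, cv=5))
print(report.summary.round(3))
```

prints

```
feature  coefficient
   M023       -0.645
   M012       -0.532
   M024        0.417
   M016        0.440
   M010        0.546

         non_adjusted  standardized  adjusted
feature
M023           0.0000        0.0000       0.0
M012           0.4959        0.4959       0.0
M024           0.0000        0.0000       0.0
M016           0.0000        0.0000       0.0
M010           0.0001        0.0001       0.0

          accuracy  sensitivity  specificity  precision     f1
method
catch        0.903        0.750        0.957      0.866  0.798
baseline     0.766        0.112        0.993      0.588  0.183
```

The five selected features are exactly the five generating signal cells
(M012 is cell (2, 2)). The significance table shows the confounding
signature the method exists to expose: M012's raw Wilcoxon p is 0.50 —
marginally it looks null because gene expression cancels its contrast —
while its covariate-adjusted p is < 10⁻⁴. The repeated-split summary shows
the direction the comparison is expected to take on confounded data: the
adjusted tensor discriminant keeps sensitivity (0.75) on the 25% MSI
minority while the flat-feature forest collapses to near-majority voting
(sensitivity 0.11), costing it F1.

The same pipeline is scriptable from the shell:

```bash
catchmsi simulate --n-cases 75 --ratio 3 --seed 1 --out cohort/
catchmsi match --annotation cohort/annotation.csv --ratio 3 --seed 2 --out matched.csv
catchmsi fit --cohort cohort/ --n-features 8 --model-out model.json
catchmsi evaluate --cohort cohort/ --iterations 100 --seed 3 --out metrics.csv
catchmsi associate --model model.json --out-alpha alpha.csv --out-effects effects.csv
```

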