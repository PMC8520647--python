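# Methods

`emrcost` predicts per-patient treatment cost from tabular electronic-medical-
record (EMR) data by a classify-then-regress pipeline. This note documents the
models, the tunable parameters, the synthetic cohort the tests run on, and the
numerical and design choices.

## 1. Text digitization

EMR descriptors come in two flavours. *Qualitative* descriptors (smoking,
abdominal pain, ...) are present/absent and map to {0, 1}. *Degree* descriptors
carry an ordinal severity with `a` levels; a patient at level `x` (1-based)
maps to

```
y = 0                if the symptom is absent
y = 0.5 + x / (2a)   if present at level x
```

so the image is {0} ∪ (0.5, 1]: presence contributes a base value of 0.5,
severity a linear share, and the maximum grade maps to exactly 1 for every
`a`. The transform keeps variables discrete (a + 1 distinct values) and on a
common [0, 1] scale with the binary descriptors, so no single column dominates
distance or penalty computations. Severity vocabularies are supplied per
column in the schema (default fixtures use 3 levels); a *present-but-level-0*
descriptor is rejected rather than mapped, since the present branch is only
defined for x ≥ 1.

A blank field is **not** an absent symptom: absence (y = 0) is information,
a blank cell is missing information. Digitization propagates blanks as NaN so
they reach the imputer; conflating the two would bias every downstream
estimate toward "no symptom".

## 2. Missing data

Records missing strictly more than `max_missing_fraction` (default 20%) of
their fields — the p features plus the cost target, so 17 fields in the
standard schema — are dropped outright: a mostly-blank record contributes more
imputation noise than signal. Remaining gaps are filled cell-wise by a
distance-weighted K-nearest-neighbour mean

```
f = Σ_i D_i W_i / Σ_i W_i ,    W_i = 1 / (d_i + ε)
```

over the k (default 5) donors nearest to the record that observe the missing
variable; `D_i` is donor i's value. Distances are Euclidean over co-observed
features after min–max scaling each feature to [0, 1] (age must not dominate
the digitized descriptors), rescaled by `sqrt(p / n_co)` so pairs with
different co-observation counts are comparable (the nan-Euclidean
convention). ε (default 1e-8) guards exact duplicates; ties at the k-th
distance break by record order, making the imputer deterministic. Imputed
values are convex combinations of donor values and therefore stay within the
donors' range — a degree column can never be imputed outside [0, 1].

Weighted KNN pays off exactly when the masked variable is predictable from
co-observed fields (clustered or scheme-structured records). On variables
that are mostly idiosyncratic — age in the default synthetic cohort, whose
within-scheme spread (sd 10 y) dwarfs its between-scheme shifts — KNN
performs on par with the global mean, and the package reports both honestly.
Baselines (`global_mean`, `fixed_value`) and a mask-and-recover
cross-validation harness (`crossvalidate_imputation`, reporting the deviation
rate 100·mean|imputed − true|/true, a downstream linear-regression accuracy,
and the error standard deviation) are provided for such comparisons.
Missingness is treated as MCAR throughout; informative missingness is out of
scope.

## 3. Scheme classification

Treatment schemes (four classes: systematic care, first-line chemotherapy,
second-line chemotherapy, targeted therapy) are predicted by a discrete
naive-Bayes model: conditional probability tables (CPTs) estimated by
maximum likelihood — frequencies, optionally Laplace-smoothed with
pseudocount α — and classification by

```
ŷ = argmax_j  P(y_j) Π_i P(x_i | y_j)
```

computed in log space (16 factors of small probabilities underflow a direct
product). The posterior over schemes is the normalized exponential of the
class log-scores; ties break toward the lowest class index. Default α = 1:
at a few hundred records, zero counts are likely and pure ML (α = 0, also
available) would veto classes on single unseen states.

Features enter the classifier discretized: binary/degree columns already live
on finite grids; numeric columns are quantile-binned (default 4 bins, edges
recorded for reuse on new data). Arbitrary user-supplied DAGs over the
variables are supported for CPT fitting and joint log-likelihood scoring
(`fit_cpts`, `log_likelihood`); structure learning is out of scope, and the
classifier itself always uses the naive factorization.

## 4. Locally weighted LASSO

Costs are modelled linearly, y = β₀ + xᵀβ + ε, fitted by minimizing

```
(1/2m) Σ_i w_i (y_i − β₀ − x_iᵀβ)²  +  (λ/m) Σ_j |β_j|
```

with cyclic coordinate descent and soft-thresholding; the intercept is
unpenalized. Features are standardized internally to weighted mean 0 /
variance 1 before penalization (L1 shrinkage is scale-sensitive); reported
coefficients are on the original scale. Convergence: maximum standardized
coefficient change < `tol` (default 1e-6) or `max_iter` (default 10,000)
sweeps, flagged if hit; the objective is recorded every sweep and is
non-increasing. Zero-variance features get coefficient 0 with a warning.
λ = 0 reproduces weighted OLS; λ ≥ λ_max = max_j |Σ_i w_i x̃_ij (y_i − ȳ_w)|
gives the fully shrunk fit (intercept = weighted mean). An optional
coefficient budget Σ|β_j| ≤ σ_cap is enforced through the standard
constrained↔penalized equivalence by bisecting on λ.

*Local* weighting sets w_i = exp(−‖x_i − x‖²/(2τ²)), a Gaussian kernel
centred at the query x, and refits at every query (warm-started from the
global solution). Kernel distances are computed on z-scored features; the
default bandwidth τ = √p/2 leaves weight e⁻⁴ at the typical random-pair
distance √(2p), i.e. genuinely local but never degenerate. Within each refit
the kernel weights are rescaled to mean 1 so the penalty strength is
comparable across queries; a query infinitely far from the data falls back to
uniform weights. τ → ∞ recovers the global LASSO exactly. The weights enter
the squared-error loss (locally weighted regression); an alternative reading
that weights the penalty terms instead is available as
`weighting="penalty"` with per-coefficient weights.

λ is chosen by k-fold cross-validation over a descending log grid from λ_max
(warm-started path; default 20 values down to λ_max·1e-4). The validation
loss is selectable: plain MSE (default for the standalone solver) or mean
absolute relative error (`objective="relative"`). The pipeline harness uses
the relative objective because the model comparison it reports is scored on
a relative-error accuracy; tuning the hyperparameter to the reported loss is
the same convention as glmnet's `type.measure`. With an MSE-tuned λ the
shrinkage bias concentrates on low-cost patients, where relative error is
most expensive.

## 5. Fusion: classify, then regress

`fit_fusion` runs digitize → filter → KNN-impute → discretize → naive-Bayes
CPTs, then partitions the *training* records by their true scheme label and
fits one locally weighted LASSO per scheme. `predict_fusion` routes each new
record through the classifier and predicts with the winning scheme's
regressor (ties to the lowest class index; missing fields are KNN-imputed
against the training matrix). Training on true labels and predicting through
inferred ones is the standard classify-then-regress protocol; misrouted
patients are scored by the wrong-scheme regressor, not excluded. A scheme
with fewer records than features falls back to a fully shrunk
(intercept-level) fit with a warning.

The rationale: scheme membership changes both the cost level and *which*
variables drive cost (sign-conflicting slopes across schemes). A pooled
linear model has to average those regimes; the local kernel can only blur
across them; an explicit partition removes the heterogeneity, at the price
of misclassification risk — so fusion's advantage grows with classifier
accuracy.

`evaluate` compares pooled OLS, pooled LASSO, locally weighted LASSO and
fusion under stratified k-fold cross-validation (default 5-fold, seeded),
reporting MSE, R² = 1 − SSE/SST per held-out fold, and an accuracy
percentage defined as 100·(1 − mean|ŷ − y|/y) clipped to [0, 100] (records
with y ≤ 0 are excluded from the relative error with a warning). Accuracy
for a continuous target has no canonical definition; this one mirrors the
"percent of the cost explained" reading and is monotone in the relative
error.

## 6. Synthetic cohort

No patient data ships with the package; `emrcost.simulate` generates a
cohort with the statistical structure the method assumes, and its defaults
are the package's study conditions:

- **Schema**: 16 variables — gender, age, months since bowel surgery,
  urinary/defecation symptoms, pathology grade, metastasis, radiotherapy,
  chemotherapy, fever, medication intensity, diabetes, hypertension, other
  surgery, smoking, drinking — plus a four-class scheme (priors
  0.35/0.30/0.20/0.15) and a continuous cost in thousands of currency units.
- **Scheme signatures**: the chemo/radiotherapy flags record what the scheme
  prescribed and are near-deterministic given it (logit shifts ±5–6, i.e.
  ~1% recording error); disease-state variables (metastasis, pathology,
  symptoms) and age shift probabilistically (older patients route to
  surgery-only care, younger to targeted therapy). Held-out naive-Bayes
  accuracy lands around 95–97%. The shifts are the difficulty knob: scaling
  them to zero drives accuracy to the majority rate.
- **Within-record couplings**: diabetes and hypertension prevalence rise
  with age (odds roughly ×1.8–2.2 per decade); smoking and drinking are more
  common in men. These exist in any real cohort and give the imputer
  something to condition on.
- **Cost model**: cost = scheme intercept + βₛᵀz + N(0, 6²), computed from
  the *digitized* feature vector z, so the regression estimand is exactly
  the configured coefficients. Intercepts (38/46/50/58) overlap — the pooled
  cost distribution is a single broad mode, not four separated bumps — while
  the slopes differ strongly and partly in sign across schemes (e.g. age
  +0.30/−0.25/+0.10/−0.25 per year). Six of the sixteen variables carry no
  cost signal in any scheme. noise_sd = 6 puts the per-scheme noise at
  roughly 10% of the mean cost.
- **Missingness**: each feature cell is blanked independently with
  probability `missing_rate` (default 0.05); scheme and cost are never
  blanked (they are the supervision). MCAR by construction.

What the generator does **not** emulate: free-text notes (descriptors arrive
pre-segmented), non-MCAR missingness, longitudinal structure, label noise in
the scheme, and heavy-tailed cost outliers. Passing tests therefore show the
pipeline recovers the structure it models — not that it survives every
pathology of real hospital data.

## 7. Numerical choices and degenerate inputs

- Coordinate-descent tolerance 1e-6 on standardized coefficients, 10,000
  sweep cap; objective monotonicity asserted in tests every sweep.
- Posterior, CPT and weight normalizations hold to 1e-12.
- KNN ties broken by record order; classifier ties by class index; both
  deterministic.
- Quantile bin edges are deduplicated, so a numeric column with heavy ties
  degrades gracefully to fewer bins.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  configs (including seed) reproduce byte-identical cohorts and reports.

## 8. Known limitations

- At cohort sizes around n = 1000 with 16 informative-ish features, pooled
  LASSO and pooled OLS are statistically indistinguishable on the
  relative-error accuracy (the attainable shrinkage gain, ~6 noise
  coefficients × σ²/n, is below per-seed resolution); the LASSO's edge over
  OLS appears in MSE and at smaller sample sizes. Comparisons between the
  two pooled baselines should be read accordingly.
- Fusion's MSE advantage over the locally weighted LASSO depends on
  classifier accuracy; below roughly 94% the misrouting tail can outweigh
  the per-scheme fit gains on squared error (the relative-error accuracy
  ordering is much more stable).
- Local prediction refits per query (O(n·p) per coordinate-descent sweep per
  query); for very large query batches use `local=False` or cache by scheme.
- The naive-Bayes independence assumption is knowingly violated by the
  generator's couplings; at the default separation this costs little, but
  strongly correlated features would double-count evidence.
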