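# emrcost

Treatment-cost prediction from tabular electronic-medical-record (EMR) data,
built for the small-cohort, single-disease setting where a handful of hundred
records must carry the whole analysis: health-economics and hospital-management
teams estimating per-patient cost from the admission record, and
biostatisticians who need every preprocessing step testable.

## The method

Four stages, each an importable module:

1. **Digitize** (`emrcost.digitize`). Text descriptors become numbers:
   present/absent symptoms map to {0, 1}; an ordinal symptom with *a* severity
   levels maps to

   y = 0 (absent),  y = 0.5 + x/(2a) (present at level x, so y ∈ (0.5, 1]),

   keeping variables discrete and on a common scale. Blank fields stay
   missing — no information is not the same as no symptom.

2. **Impute** (`emrcost.impute`). Records missing >20% of their fields are
   dropped; each remaining gap is filled by the distance-weighted mean of its
   k nearest donors, f = Σᵢ Dᵢ Wᵢ / Σᵢ Wᵢ with Wᵢ = 1/(dᵢ + ε), distances
   Euclidean over co-observed min–max-scaled features.

3. **Classify** (`emrcost.bayesnet`). A naive-Bayes model with
   maximum-likelihood (optionally Laplace-smoothed) conditional probability
   tables assigns each patient to one of four treatment schemes:
   ŷ = argmaxⱼ P(yⱼ) Πᵢ P(xᵢ|yⱼ), evaluated in log space. Fixed user-supplied
   DAGs can also be scored by joint log-likelihood.

4. **Regress** (`emrcost.lwlasso`, `emrcost.pipeline`). Per scheme, a locally
   weighted LASSO: minimize (1/2m) Σᵢ wᵢ(yᵢ − β₀ − xᵢᵀβ)² + (λ/m)‖β‖₁ by
   coordinate descent, with Gaussian kernel weights wᵢ = exp(−‖xᵢ − x‖²/2τ²)
   refitted at each query. The fusion model classifies first, then predicts
   cost with the winning scheme's regressor — removing the between-scheme
   heterogeneity a pooled regression must absorb as noise.

A synthetic-cohort generator (`emrcost.simulate`) emulates the 16-variable
record layout, scheme-dependent cost structure and injected missingness, so
the entire pipeline is testable without any patient data.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from emrcost import default_config, generate_records, evaluate

cfg = default_config(n_records=500, seed=11)     # synthetic cohort
records = generate_records(cfg)
report = evaluate(records, cfg.schema, n_folds=3, seed=11)
print(report.metrics.to_string(index=False))
print(f"scheme classifier accuracy: {report.classification_accuracy_pct:.1f}%")
```

prints

```
  model  accuracy_pct       mse       r2
 linear     89.854853 65.213714 0.750395
  lasso     89.828154 64.378394 0.753600
lwlasso     90.258955 59.848759 0.770690
 fusion     90.849418 57.353208 0.780632
scheme classifier accuracy: 96.8%
```

Accuracy is 100·(1 − mean |ŷ−y|/y): the fusion model is within ~9.2% of the
true cost on average, ahead of the locally weighted LASSO (~9.7%) and the
pooled linear/LASSO baselines (~10.2%); MSE (squared thousands of currency
units) and R² tell the same story. The classifier recovers the treatment
scheme for 97% of held-out patients, which is what makes routing to
scheme-specific regressors pay off.

The `examples/` directory has one short script per capability
(`simulate_cohort.py`, `digitize_records.py`, `impute_missing.py`,
`classify_schemes.py`, `local_lasso.py`, `predict_costs.py`); each prints the
numbers it computes and one line on how to read them. A thin CLI wraps the
same stages: `emrcost simulate-cohort`, `digitize`, `impute`, `evaluate`,
`train`, `predict` (see `emrcost --help`).

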