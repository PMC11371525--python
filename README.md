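# podqsar

Two-stage QSAR prediction of human-equivalent oral points of departure
(PODs), with margin-of-exposure risk screening.

A chemical's point of departure — the dose, in mg·(kg-d)⁻¹, where the
dose–response range used for risk extrapolation begins — exists for only
a small fraction of chemicals in commerce, because it normally requires
curated in vivo toxicity data. `podqsar` implements a two-stage
machine-learning workaround: Stage 1 (consumed here as a feature table,
not re-implemented) predicts ~39 interpretable
structural/physical/chemical/toxicological properties per chemical
(water solubility, predicted rat oral LD50, biodegradability, ...);
Stage 2 — this package — regresses log10 surrogate PODs on those
properties with a random forest, separately for two effect categories
(general noncancer and reproductive/developmental), and propagates the
cross-validated error into risk metrics.

It is written for computational toxicologists and risk assessors who
want screening-level toxicity values for data-poor chemicals, and for
anyone who needs the evaluation machinery: leakage-safe preprocessing,
permutation-importance feature selection nested in repeated
cross-validation, and replicate-based generalization-error estimates.

## The model

For an effect category *e*, the labeled data are a feature matrix
**X** (chemicals × properties, with per-cell applicability-domain
metadata) and a target vector **y**ₑ of log10 PODs. The pipeline:

1. **Filter** — chemicals whose surrogate POD rests on ≤ 3 in vivo
   studies are excluded (`study_count ≥ 4`).
2. **Flag** — a feature value is treated as missing iff it is outside
   the *global* applicability domain of its Stage-1 model **and** its
   *local* applicability-domain index is < 0.4.
3. **Preprocess** (fitted on training folds only) — drop features
   needing > 30% imputation; impute the rest with training medians.
4. **Select** — permutation importance (median increase in held-out
   RMSE over random permutations of one feature) inside a repeated
   5-fold loop; the top *k* = 10 features by median-across-splits
   importance are kept.
5. **Fit** — `RandomForestRegressor` with `max_features` =
   max(1, ⌊n/3⌋) and library defaults otherwise.
6. **Evaluate** — an outer loop of 30 repetitions × 5 folds (150
   replicate models, each re-running steps 3–5 from scratch) yields
   RMSE, MedAE and R² distributions, summarised as median [p5, p95].

The risk layer converts the median outer-CV RMSE into a 90% prediction
interval `10^(ŷ ± 1.645·RMSE)`, a fold-scale GSD error `10^RMSE`, a
margin of exposure MOE = POD/exposure with concern categories
(low: MOE > 100; moderate: 1 < MOE ≤ 100; high: MOE ≤ 1), and reference
doses RfD = POD / (UF_A·UF_H·UF_D).

## Worked example

The synthetic generator plants a known signal (3 informative features
among 39, noise 0.5 log10 units), so the whole pipeline runs without
any external data:

```python
import podqsar as pq
from podqsar import simulate

spec = simulate.SyntheticSpec(n_chemicals=300, seed=7)
features, pods = simulate.generate_labeled_data(spec)

model = pq.PODRegression(
    features, pods,
    forest_spec=pq.ForestSpec(n_trees=100, seed=7),
    selection_spec=pq.SelectionSpec(inner_repeats=2, n_permutations=5, seed=7),
)
results = model.fit(cv_spec=pq.CVSpec(outer_folds=5, outer_repeats=3, seed=7))
print(results.summary())
```

```
                      POD QSAR Regression Results
========================================================================
Effect category:                                       general_noncancer
No. labeled chemicals:                                               256
Estimator:                                                 random_forest
Features retained:                                                    36
Features dropped (sparse):                                             3
Features selected:                                                     9
------------------------------------------------------------------------
Generalization error (outer CV, median [p5, p95])
  RMSE (log10)           1.007   [0.786, 1.292]
  MedAE (log10)          0.576   [0.396, 0.792]
  R²                     0.681   [0.607, 0.757]
  GSD fold error         10.17   (GSD² = 103.4)
------------------------------------------------------------------------
Selected features (descending importance):
  F01  +0.4536
  F03  +0.4274
  F02  +0.3655
  F15  +0.0064
  ...
========================================================================
```

Reading it: 300 generated chemicals shrink to 256 after the study-count
filter; 3 heavily-missing features are dropped by the 30% rule; the
three planted informative features (F01–F03) dominate the importance
ranking (the 10th selected feature fell below the full-data missingness
cut, leaving 9). The median out-of-sample RMSE of ~1.0 log10 units
means predictions for a new chemical are typically within a factor of
~10 (the GSD fold error) of the truth; R² ≈ 0.68 of target variance is
explained.

Screening those chemicals against a generated exposure table and
deriving a reference dose from a conservative lower-bound POD of
1.9 mg·(kg-d)⁻¹:

```python
exposures = simulate.generate_exposure_table(features.chemical_ids, seed=8)
frame, assessments, missing = results.screen(exposures)
# concern categories: {'low': 248, 'moderate': 8, 'high': 0}

rfd = pq.derive_rfd(1.9, uf_a=3, uf_h=10, uf_d=1)
# 0.0633 -> displayed 0.06 mg/(kg-d)
```

## Command line

```bash
podqsar make-fixtures --out fixtures --seed 3      # synthetic CSVs
podqsar train    --config run.yaml                 # model bundle + summary
podqsar evaluate --config run.yaml                 # 150-row replicate CSV
podqsar screen   --config run.yaml --bundle out/model_bundle
podqsar benchmark --pred mine.csv --ref theirs.csv
```

All runs are driven by one YAML config (paths, effect category, specs,
seed); each command writes `run_info.json` with input digests, the
config echo and library versions, so identical config + seed reproduces
identical outputs.

## Layout

- `src/podqsar/ingest.py` — tables, validation, applicability-domain flagging
- `src/podqsar/preprocess.py` — leakage-safe drop + median imputation
- `src/podqsar/estimators.py` — forest spec, split-feature rule, plug-in registry
- `src/podqsar/selection.py` — permutation importance in repeated k-fold CV
- `src/podqsar/evaluation.py` — outer CV loop, metrics, benchmarking
- `src/podqsar/screening.py` — prediction intervals, MOE, RfD derivation
- `src/podqsar/simulate.py` — synthetic feature/POD/exposure generator
- `src/podqsar/model.py` — `PODRegression` / `PODRegressionResults` frontend
- `src/podqsar/cli.py` — `podqsar` command
- `docs/methods.md` — modelling assumptions, defaults, limitations
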