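# Methods

## Problem and model

`podqsar` estimates oral points of departure (PODs) for organic
chemicals from precomputed QSAR-predicted properties. The target is the
log10 of a surrogate human-equivalent benchmark dose in mg·(kg-d)⁻¹;
working on the log scale makes the regression error multiplicative on
the dose scale, which is how toxicity-value uncertainty is normally
expressed (fold errors, geometric standard deviations). Each effect
category (general noncancer; reproductive/developmental) is modelled
independently — the two targets measure different biology and are never
pooled.

The estimator is a random forest: bootstrapped, decorrelated regression
trees whose predictions are averaged. Two properties make it the
default here: it needs no feature scaling (tree splits are invariant to
monotone transforms) and it is robust to many irrelevant features. The
only hyperparameter changed from the scikit-learn defaults is
`max_features`, set to max(1, ⌊n/3⌋) of the available features — the
standard regression-forest heuristic that increases tree decorrelation.
Alternative estimators (gradient boosting, ridge, ordinary least
squares) satisfy the same `factory(spec, n_features)` contract via
`register_estimator` for sensitivity analyses; they are provided but
not tuned.

## Applicability-domain handling

Stage-1 property predictions come with two per-feature reliability
signals: a global in/out applicability-domain flag and a local
applicability-domain index in [0, 1] measuring similarity to the
feature model's nearest training neighbours. A value is demoted to
missing only when **both** signals are bad: outside the global domain
*and* local index < 0.4. Requiring both keeps values for chemicals that
fail only one criterion, which would otherwise discard a large fraction
of usable data. When a file carries no domain columns, values default
to in-domain (never flagged).

Chemicals whose entire feature row is missing after flagging are *not*
dropped: they pass through preprocessing fully imputed and are marked
in the screening output (`all_features_imputed`), because silently
changing the chemical count between input and output is worse than an
explicit low-information prediction.

## Leakage-safe preprocessing

All transformation parameters are estimated on training folds only:

- **Sparse-feature drop.** A feature whose training missing fraction
  exceeds 0.30 (strictly) is removed before imputation. Threshold
  rationale: imputing a third or more of a column mostly fabricates it,
  and the mean-reversion bias of median imputation grows with the
  imputed fraction. The drop happens before imputation so doomed
  columns never receive medians.
- **Median imputation.** Remaining missing cells get the training
  median. For binary features the median is rounded to the nearer of
  {0, 1} (ties to 0), i.e. the training mode, so imputation cannot
  create a third level.
- **No scaling.** The deployed estimator is a tree ensemble; monotone
  rescaling cannot change any split, so none is applied. A linear or
  kernel plug-in estimator would need its own scaling, which is out of
  scope for the deployed pipeline.

The leakage property is tested directly: perturbing held-out rows with
sentinel extremes changes neither the fitted medians nor the retained
features nor (in the outer loop) the predictions for co-tested
chemicals.

## Feature selection

Features are selected by permutation importance nested in a repeated
5-fold loop. In each inner split the preprocessor and forest are fitted
on the 4/5 training part; each retained feature is then scored on the
held-out 1/5 by the increase in RMSE when its column is randomly
permuted, taking the **median across permutations** as the per-split
score. Scoring on the held-out part (rather than the training part,
which the loop's description would also admit) is chosen because the
point of wrapping selection in cross-validation is to avoid
overoptimistic in-sample importance; the choice is configurable in
principle but not exposed, as the held-out reading is the conservative
one.

Per-feature scores are aggregated as the **median across splits**
(consistent with the median-across-permutations statistic and robust to
the occasional pathological split), and the top *k* = 10 features are
kept. *k* is fixed a priori, not tuned: a small interpretable subset is
the goal, and the no-selection variant (`feature_selection=False`) is
the built-in sensitivity check. Ties break lexicographically on feature
name so selection is reproducible. A feature dropped by preprocessing
in every inner split has no scores; its aggregate is NaN and it ranks
last. The final selected set is additionally intersected with the
full-data retained features, so a borderline-missingness feature can
reduce the deployed subset below *k*.

Defaults `inner_repeats = 10` and `n_permutations = 10` favour stable
rankings; the test suite and the acceptance script pass smaller values
(1–2 repeats, 3–5 permutations) and smaller forests (25–50 trees),
which leaves selection behaviour intact on the strongly-signalled
synthetic data while keeping runs to minutes. Those reduced settings
are this package's choice of test problem size.

## Generalization error

The outer loop is repeated 5-fold cross-validation with 30 repetitions:
150 replicate models, each re-running preprocessing, selection and
fitting on its outer-training split only. Splits are shuffled and
unstratified (the target is continuous). Per-replicate RMSE, MedAE and
R² are summarised by median and empirical 5th/95th percentiles (linear
interpolation); a fold with constant test targets has undefined R² and
is excluded from the R² summary with a logged count. Per-chemical
out-of-sample predictions are recorded per replicate and summarised by
the mean across repetitions. The whole report is bit-for-bit
reproducible given the seed: every replicate derives its forest and
selection seeds from the outer seed via `numpy` seed sequences.

The deployed model refits selection and the forest on the full labeled
set, and the outer loop's **median RMSE** is attached to it as the
model-level error for interval construction — per-chemical error
estimates are not available from this design.

## Risk layer

Treating log10 prediction errors as normal with SD equal to the
attached RMSE, a coverage-c prediction interval is
`10^(ŷ ± z·RMSE)` with `z = Φ⁻¹((1+c)/2)` (1.645 at 90%); the same
assumption gives the fold-scale GSD error `10^RMSE`, its square
`10^(2·RMSE)`, and a `10^(z·RMSE)` fold half-width at any coverage.
These closed forms reproduce the package's reference worked example (a
central POD of 26 mg·(kg-d)⁻¹ with RMSE 0.69 has a 90% lower bound of
1.9 mg·(kg-d)⁻¹).

The margin of exposure is MOE = POD/exposure (both mg·(kg-d)⁻¹).
Concern categories at the median population exposure: low (MOE > 100),
moderate (1 < MOE ≤ 100), high (0 < MOE ≤ 1); both boundaries belong to
the more concerning side, and the three categories partition the
positive reals. The uncertainty grid crosses every exposure percentile
with the three POD values (lower bound, central, upper bound); its most
conservative cell divides the lower POD bound by the highest exposure
percentile. Reference doses are POD/(UF_A·UF_H·UF_D), kept exact
internally and displayed at one significant figure; PODs display at
two.

## Synthetic data

The generator emulates the *statistical shape* of the real inputs, not
their content: continuous features are unit normal, binary features
Bernoulli(0.5), and the target is a sparse linear-in-features signal
plus N(0, σ) noise on the log10 scale. Defaults mirror the real
problem's scale — ~2,000 chemicals, 39 features (8 binary), three
informative features with effects ≥ 1, σ = 0.5, ~5% missingness on most
features with three features above the 30% drop threshold, study counts
uniform on 1..20, and exposure percentiles spanning ~4 orders of
magnitude between p5 and p95 (GSD 16) around lognormal medians centred
near 10⁻⁶ mg·(kg-d)⁻¹. Missingness is expressed through the
applicability-domain metadata (outside-global + local index < 0.4), so
tests exercise the flagging path rather than bypassing it.

What the generator does **not** emulate: real feature marginals (heavy
tails, bounded ranges), inter-feature correlation, structured
missingness, or any nonlinearity in the dose–property relationship.
Passing tests therefore demonstrate that the machinery is correct and
leakage-free and that known signals are recovered under honest noise —
not that real-data performance figures transfer.

One consequence matters for interpreting the noise-floor check: a
random forest approximates smooth additive signals with plateaus, so on
a purely *continuous* linear signal its out-of-sample RMSE stays well
above the generative σ even at n = 1000 (≈ 0.8 vs σ = 0.5 under the
default conditions). The noise-floor recovery test therefore plants the
signal on binary features — a piecewise-constant function the forest
can represent exactly — where the median outer-CV RMSE lands within 25%
of σ. The continuous-signal gap is a property of tree ensembles, not a
defect of the loop.

## Numerical choices and degenerate inputs

- Binary-feature detection on read: a feature whose observed values are
  all in {0, 1} is tagged binary. An explicit `feature_kind` mapping
  overrides the inference.
- CSV missing sentinels: empty cell and `NA` accepted on read; empty
  written on write.
- Constant-feature permutation importance is exactly 0 (permuting a
  constant column is the identity).
- Seeds everywhere are reduced mod 2³¹ before reaching library RNGs.
- Invalid inputs (local index outside [0, 1], nonpositive doses/MOEs,
  fewer rows than folds, schema mismatches) raise typed errors
  (`InvalidInputError`, `SchemaError`) that the CLI maps to exit codes
  2 (validation) and 3 (I/O).

## Known limitations

- Median imputation biases predictions toward central values
  (mean-reversion); the 30% drop rule limits but does not remove this.
- The attached RMSE is a model-level error; prediction intervals do not
  widen for chemicals far from the training distribution or heavily
  imputed ones (those are only flagged).
- Forest predictions cannot extrapolate beyond the training target
  range.
- Stage-1 property prediction is consumed as data; the applicability
  domain of the combined pipeline is bounded by the Stage-1 models'
  domains, which this package only reads, never recomputes.
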