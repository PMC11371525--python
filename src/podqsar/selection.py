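"""Permutation-importance feature selection nested in repeated k-fold CV.

A feature's importance is the increase in held-out RMSE when its values
are randomly permuted, breaking its association with the target while
preserving its marginal distribution; the median over permutations is
the per-split score. Scores are collected across every train/test split
of a repeated 5-fold loop (preprocessing re-fitted on each inner
training split, scoring on the held-out fifth, so no split's test data
influences the model it scores), aggregated per feature by the median
across splits, and the top ``k`` features (k = 10 a priori) are
selected. Ties break lexicographically on feature name for
reproducibility.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedKFold

from .estimators import FittedEstimator, ForestSpec, fit_estimator, predict
from .ingest import FeatureTable, InvalidInputError
from .preprocess import apply_preprocessor, fit_preprocessor

DEFAULT_K = 10


@dataclasses.dataclass(frozen=True)
class SelectionSpec:
    """Feature-selection settings.

    ``k`` features are kept (chosen a priori to limit overfitting while
    staying interpretable); the inner loop is ``inner_repeats`` x
    ``inner_folds`` cross-validation; each split scores each feature
    with ``n_permutations`` random permutations.
    """

    k: int = DEFAULT_K
    inner_folds: int = 5
    inner_repeats: int = 10
    n_permutations: int = 10
    scoring: str = "rmse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InvalidInputError("k must be >= 1")
        if self.inner_folds < 2:
            raise InvalidInputError("inner_folds must be >= 2")
        if self.n_permutations < 1:
            raise InvalidInputError("n_permutations must be >= 1")
        if self.scoring != "rmse":
            raise InvalidInputError("only rmse scoring is supported")

    def replace(self, **kwargs) -> "SelectionSpec":
        return dataclasses.replace(self, **kwargs)


@dataclasses.dataclass
class ImportanceResult:
    """Per-feature permutation-importance scores and the selected subset.

    ``per_feature_scores`` holds one median-over-permutations score per
    inner split in which the feature was retained; ``aggregate`` is the
    median of those across splits (NaN for a feature never retained);
    ``selected`` is the ordered top-k by descending aggregate;
    ``times_in_top_k`` counts, per feature, the inner splits in which it
    ranked in that split's top k.
    """

    per_feature_scores: dict[str, list[float]]
    aggregate: dict[str, float]
    selected: list[str]
    times_in_top_k: dict[str, int] = dataclasses.field(default_factory=dict)
    n_splits: int = 0

    def to_frame(self) -> pd.DataFrame:
        feats = _rank_features(self.aggregate)
        return pd.DataFrame(
            {
                "feature": feats,
                "aggregate_importance": [self.aggregate[f] for f in feats],
                "times_in_top_k": [self.times_in_top_k.get(f, 0) for f in feats],
                "n_splits_scored": [
                    len(self.per_feature_scores.get(f, [])) for f in feats
                ],
                "selected": [f in self.selected for f in feats],
            }
        )


def _rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(y_true) - np.asarray(y_pred)) ** 2)))


def permutation_importance(
    fitted: FittedEstimator,
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    feature: str,
    n_permutations: int,
    seed: int,
) -> float:
    """Median increase in RMSE on (X, y) when ``feature`` is permuted.

    Returns the median over ``n_permutations`` of
    ``rmse(permuted) - rmse(baseline)``; larger means more important.
    Permuting a constant column is the identity, so its importance is
    exactly 0. Deterministic given ``seed``.
    """
    if n_permutations < 1:
        raise InvalidInputError("n_permutations must be >= 1")
    if feature not in X.columns:
        raise InvalidInputError(f"feature {feature!r} not in columns")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    baseline = _rmse(y, predict(fitted, X))
    deltas = np.empty(n_permutations)
    Xp = X.copy()
    col = X[feature].to_numpy()
    for p in range(n_permutations):
        Xp[feature] = rng.permutation(col)
        deltas[p] = _rmse(y, predict(fitted, Xp)) - baseline
    return float(np.median(deltas))


def _all_permutation_importances(
    fitted: FittedEstimator,
    X: pd.DataFrame,
    y: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Per-feature median-over-permutations ΔRMSE, one batched predict
    per feature (all permuted copies stacked) to keep the inner loop fast."""
    cols = list(X.columns)
    Xv = X[cols].to_numpy(dtype=float)
    n = Xv.shape[0]
    baseline = _rmse(y, fitted.estimator.predict(Xv))
    out: dict[str, float] = {}
    for j, feat in enumerate(cols):
        big = np.tile(Xv, (n_permutations, 1))
        for p in range(n_permutations):
            big[p * n:(p + 1) * n, j] = rng.permutation(Xv[:, j])
        preds = np.asarray(fitted.estimator.predict(big), dtype=float)
        deltas = [
            _rmse(y, preds[p * n:(p + 1) * n]) - baseline
            for p in range(n_permutations)
        ]
        out[feat] = float(np.median(deltas))
    return out


def _rank_features(aggregate: Mapping[str, float]) -> list[str]:
    """Descending by aggregate (NaN last), ties lexicographic by name."""
    def key(f: str):
        a = aggregate[f]
        return (np.isnan(a), -a if not np.isnan(a) else 0.0, f)

    return sorted(aggregate, key=key)


def select_features(
    features: FeatureTable,
    y: pd.Series | Sequence[float],
    forest_spec: ForestSpec | None = None,
    sel_spec: SelectionSpec | None = None,
    estimator: str = "random_forest",
) -> ImportanceResult:
    """Run the inner selection loop and pick the top-k features.

    For each of ``inner_repeats`` x ``inner_folds`` train/test splits:
    fit the preprocessor and estimator on the 4/5 training part, then
    score every retained feature by permutation importance on the
    held-out 1/5. The per-feature aggregate is the median score across
    splits; the top ``k`` by aggregate (ties lexicographic) are
    selected. Deterministic given the specs' seeds.
    """
    forest_spec = forest_spec or ForestSpec()
    sel_spec = sel_spec or SelectionSpec()
    y = pd.Series(np.asarray(y, dtype=float), index=features.values.index)
    n = features.n_chemicals
    if n < sel_spec.inner_folds:
        raise InvalidInputError(
            f"need at least {sel_spec.inner_folds} rows, got {n}"
        )
    splitter = RepeatedKFold(
        n_splits=sel_spec.inner_folds,
        n_repeats=sel_spec.inner_repeats,
        random_state=sel_spec.seed % (2 ** 31),
    )
    ids = np.asarray(features.chemical_ids)
    scores: dict[str, list[float]] = {f: [] for f in features.feature_names}
    top_counts: dict[str, int] = {f: 0 for f in features.feature_names}
    n_splits = 0
    for split_i, (tr, te) in enumerate(splitter.split(ids)):
        n_splits += 1
        train_tbl = features.subset(ids[tr])
        test_tbl = features.subset(ids[te])
        state = fit_preprocessor(train_tbl)
        if not state.retained_features:
            continue
        Xtr = apply_preprocessor(state, train_tbl).values
        Xte = apply_preprocessor(state, test_tbl).values
        fitted = fit_estimator(
            Xtr, y.loc[ids[tr]],
            forest_spec.replace(seed=(forest_spec.seed + split_i) % (2 ** 31)),
            estimator=estimator,
        )
        rng = np.random.default_rng((sel_spec.seed, split_i))
        split_scores = _all_permutation_importances(
            fitted, Xte, y.loc[ids[te]].to_numpy(), sel_spec.n_permutations, rng
        )
        for f, s in split_scores.items():
            scores[f].append(s)
        for f in _rank_features(split_scores)[: sel_spec.k]:
            top_counts[f] += 1

    aggregate = {
        f: float(np.median(v)) if v else float("nan")
        for f, v in scores.items()
    }
    k_eff = min(sel_spec.k, features.n_features)
    selected = _rank_features(aggregate)[:k_eff]
    return ImportanceResult(
        per_feature_scores=scores,
        aggregate=aggregate,
        selected=selected,
        times_in_top_k=top_counts,
        n_splits=n_splits,
    )
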