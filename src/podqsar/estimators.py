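"""Stage-2 estimators behind a pluggable fit/predict contract.

The deployed estimator is a random-forest regressor on log10 POD with
the number of split-candidate features set to 1/3 of the available
features (at least 1) instead of the all-features default; every other
hyperparameter follows the scikit-learn defaults. Alternative estimators
(gradient boosting, ridge, ordinary least squares, ...) can be
registered for sensitivity analyses; they share the same contract:
``factory(spec, n_features) -> unfitted sklearn-style estimator``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable

import numpy as np
import pandas as pd

from .ingest import InvalidInputError, SchemaError

DEFAULT_N_TREES = 100
DEFAULT_SPLIT_FRACTION = 1.0 / 3.0


@dataclasses.dataclass(frozen=True)
class ForestSpec:
    """Random-forest hyperparameters.

    ``split_feature_fraction`` is the fraction of available features
    considered at each split (floor, but at least
    ``min_split_features``); ``bootstrap=False`` with ``n_trees=1``
    yields a single memorising tree, useful for diagnostics.
    """

    n_trees: int = DEFAULT_N_TREES
    split_feature_fraction: float = DEFAULT_SPLIT_FRACTION
    min_split_features: int = 1
    seed: int = 0
    bootstrap: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.split_feature_fraction <= 1.0:
            raise InvalidInputError("split_feature_fraction must be in (0, 1]")
        if self.n_trees < 1:
            raise InvalidInputError("n_trees must be >= 1")

    def replace(self, **kwargs) -> "ForestSpec":
        return dataclasses.replace(self, **kwargs)


def split_feature_count(n_features: int, spec: ForestSpec) -> int:
    """Number of features considered per split: max(min, floor(n * frac))."""
    if n_features < 1:
        raise InvalidInputError("n_features must be >= 1")
    return max(spec.min_split_features,
               math.floor(n_features * spec.split_feature_fraction))


def _make_random_forest(spec: ForestSpec, n_features: int):
    from sklearn.ensemble import RandomForestRegressor

    return RandomForestRegressor(
        n_estimators=spec.n_trees,
        max_features=split_feature_count(n_features, spec),
        bootstrap=spec.bootstrap,
        random_state=spec.seed,
    )


def _make_gradient_boosting(spec: ForestSpec, n_features: int):
    from sklearn.ensemble import GradientBoostingRegressor

    return GradientBoostingRegressor(random_state=spec.seed)


def _make_ridge(spec: ForestSpec, n_features: int):
    from sklearn.linear_model import Ridge

    return Ridge(random_state=spec.seed)


def _make_linear(spec: ForestSpec, n_features: int):
    from sklearn.linear_model import LinearRegression

    return LinearRegression()


ESTIMATOR_REGISTRY: dict[str, Callable] = {
    "random_forest": _make_random_forest,
    "gradient_boosting": _make_gradient_boosting,
    "ridge": _make_ridge,
    "linear": _make_linear,
}


def register_estimator(name: str, factory: Callable) -> None:
    """Register ``factory(spec, n_features) -> estimator`` under ``name``."""
    ESTIMATOR_REGISTRY[name] = factory


@dataclasses.dataclass
class FittedEstimator:
    """A fitted estimator plus the training feature schema."""

    estimator: object
    feature_names: tuple[str, ...]
    name: str = "random_forest"


def fit_estimator(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    spec: ForestSpec,
    estimator: str = "random_forest",
) -> FittedEstimator:
    """Fit the named estimator on a fully-imputed feature grid.

    Preconditions: at least 2 rows, rows(X) == len(y), and no missing
    values (preprocessing must run first).
    """
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y) or X.shape[0] < 2:
        raise InvalidInputError(
            f"need rows(X) == len(y) >= 2, got {X.shape[0]} and {len(y)}"
        )
    if X.isna().to_numpy().any():
        raise InvalidInputError(
            "feature grid contains missing values; run preprocessing first"
        )
    if estimator not in ESTIMATOR_REGISTRY:
        raise InvalidInputError(
            f"unknown estimator {estimator!r}; registered: "
            f"{sorted(ESTIMATOR_REGISTRY)}"
        )
    est = ESTIMATOR_REGISTRY[estimator](spec, X.shape[1])
    est.fit(X.to_numpy(dtype=float), y)
    return FittedEstimator(est, tuple(X.columns), estimator)


def predict(fitted: FittedEstimator, X: pd.DataFrame) -> np.ndarray:
    """Predict log10 PODs for a feature grid matching the training schema.

    Columns may arrive in any order but must be the same set; a
    different set raises :class:`SchemaError`. Empty input yields an
    empty vector.
    """
    if set(X.columns) != set(fitted.feature_names):
        raise SchemaError(
            f"feature columns {sorted(X.columns)} do not match training "
            f"columns {sorted(fitted.feature_names)}"
        )
    X = X[list(fitted.feature_names)]
    if X.isna().to_numpy().any():
        raise InvalidInputError("feature grid contains missing values")
    if X.shape[0] == 0:
        return np.empty(0, dtype=float)
    return np.asarray(fitted.estimator.predict(X.to_numpy(dtype=float)),
                      dtype=float)
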