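"""Outer evaluation loop, performance metrics, and benchmarking.

Generalization error is estimated with an outer repeated k-fold loop
(default 30 repetitions x 5 folds = 150 replicate models). Every
replicate re-runs the full training recipe — preprocessor fit, inner
feature-selection loop, estimator fit — on its outer-training split
only, then scores on the held-out outer-test split with RMSE, median
absolute error and R². Score distributions are summarised by the median
and the empirical 5th/95th percentiles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedKFold

from .estimators import ForestSpec, fit_estimator, predict
from .ingest import FeatureTable, InvalidInputError, PODDataset, SchemaError
from .preprocess import apply_preprocessor, fit_preprocessor
from .selection import SelectionSpec, select_features

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class CVSpec:
    """Outer cross-validation layout: ``outer_repeats`` x ``outer_folds``."""

    outer_folds: int = 5
    outer_repeats: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2:
            raise InvalidInputError("outer_folds must be >= 2")
        if self.outer_repeats < 1:
            raise InvalidInputError("outer_repeats must be >= 1")

    def replace(self, **kwargs) -> "CVSpec":
        return dataclasses.replace(self, **kwargs)


class MetricSet(NamedTuple):
    """RMSE and MedAE in log10 units; R² dimensionless (NaN if undefined)."""

    rmse: float
    medae: float
    r2: float


def compute_metrics(y_true, y_pred) -> MetricSet:
    """RMSE, median absolute error, and R² against the mean baseline.

    R² is 1 - SS_res/SS_tot; when ``y_true`` is constant SS_tot is 0 and
    R² is returned as NaN with a warning.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise InvalidInputError("y_true and y_pred must have equal length >= 2")
    if not (np.isfinite(y_true).all() and np.isfinite(y_pred).all()):
        raise InvalidInputError("metric inputs must be finite")
    resid = y_true - y_pred
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    medae = float(np.median(np.abs(resid)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("R² undefined for constant y_true; returning NaN",
                      stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return MetricSet(rmse, medae, r2)


def summarize_scores(values: Sequence[float]) -> dict[str, float]:
    """Median and empirical 5th/95th percentiles (linear interpolation).

    NaNs (e.g. R² on a constant-target fold) are excluded.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise InvalidInputError("no scores to summarise")
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return {"median": float("nan"), "p5": float("nan"), "p95": float("nan")}
    return {
        "median": float(np.median(arr)),
        "p5": float(np.percentile(arr, 5)),
        "p95": float(np.percentile(arr, 95)),
    }


@dataclasses.dataclass
class ReplicateResult:
    """One outer train/test replicate."""

    repeat: int
    fold: int
    test_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    metrics: MetricSet
    selected_features: list[str]


@dataclasses.dataclass
class CVReport:
    """Replicate-level scores and out-of-sample predictions."""

    replicates: list[ReplicateResult]
    cv_spec: CVSpec

    @property
    def replicate_scores(self) -> list[MetricSet]:
        return [r.metrics for r in self.replicates]

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for metric in MetricSet._fields:
            vals = [getattr(m, metric) for m in self.replicate_scores]
            n_nan = int(np.sum(np.isnan(vals)))
            if n_nan:
                logger.info("%d replicate(s) excluded from %s summary (NaN)",
                            n_nan, metric)
            out[metric] = summarize_scores(vals)
        return out

    @property
    def per_chemical_oos(self) -> dict[str, list[float]]:
        """Each chemical's out-of-sample predictions across repeats."""
        out: dict[str, list[float]] = {}
        for rep in self.replicates:
            for cid, pred in zip(rep.test_ids, rep.y_pred):
                out.setdefault(cid, []).append(float(pred))
        return out

    def mean_oos_prediction(self) -> pd.Series:
        """Mean out-of-sample prediction per chemical across repeats."""
        oos = self.per_chemical_oos
        return pd.Series({c: float(np.mean(v)) for c, v in oos.items()},
                         name="mean_oos_log10_pod")

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "repeat": [r.repeat for r in self.replicates],
                "fold": [r.fold for r in self.replicates],
                "n_test": [len(r.test_ids) for r in self.replicates],
                "rmse": [r.metrics.rmse for r in self.replicates],
                "medae": [r.metrics.medae for r in self.replicates],
                "r2": [r.metrics.r2 for r in self.replicates],
                "selected_features": [
                    "|".join(r.selected_features) for r in self.replicates
                ],
            }
        )

    def summary_json(self) -> str:
        return json.dumps(
            {
                "n_replicates": len(self.replicates),
                "outer_folds": self.cv_spec.outer_folds,
                "outer_repeats": self.cv_spec.outer_repeats,
                "metrics": self.summary(),
            },
            indent=2,
            sort_keys=True,
        )


def _derived_seed(base: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=base, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def nested_cv(
    features: FeatureTable,
    dataset: PODDataset,
    forest_spec: ForestSpec | None = None,
    sel_spec: SelectionSpec | None = None,
    cv_spec: CVSpec | None = None,
    estimator: str = "random_forest",
    feature_selection: bool = True,
) -> CVReport:
    """Nested cross-validation: inner selection loop, outer scoring loop.

    For every outer repeat x fold, the preprocessor, the inner
    feature-selection loop and the estimator are all (re)fitted on the
    outer-training chemicals only and scored on the held-out fold, so
    the replicate scores estimate performance on genuinely unseen
    chemicals. Deterministic given ``cv_spec.seed``.
    """
    forest_spec = forest_spec or ForestSpec()
    sel_spec = sel_spec or SelectionSpec()
    cv_spec = cv_spec or CVSpec()

    labeled = dataset.chemical_ids
    missing = [c for c in labeled if c not in features.values.index]
    if missing:
        raise SchemaError(
            f"labeled chemicals missing from feature table: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    if len(labeled) < cv_spec.outer_folds:
        raise InvalidInputError("fewer labeled chemicals than outer folds")
    ids = np.asarray(labeled)
    y = dataset.log10_pod

    splitter = RepeatedKFold(
        n_splits=cv_spec.outer_folds,
        n_repeats=cv_spec.outer_repeats,
        random_state=cv_spec.seed % (2 ** 31),
    )
    replicates: list[ReplicateResult] = []
    for split_i, (tr, te) in enumerate(splitter.split(ids)):
        repeat, fold = divmod(split_i, cv_spec.outer_folds)
        train_tbl = features.subset(ids[tr])
        test_tbl = features.subset(ids[te])
        ytr = y.loc[ids[tr]]
        yte = y.loc[ids[te]].to_numpy()

        rep_seed = _derived_seed(cv_spec.seed, repeat, fold)
        if feature_selection:
            imp = select_features(
                train_tbl, ytr,
                forest_spec.replace(seed=rep_seed),
                sel_spec.replace(seed=rep_seed),
                estimator=estimator,
            )
            selected = imp.selected
        else:
            selected = train_tbl.feature_names

        state = fit_preprocessor(train_tbl)
        selected = [f for f in selected if f in state.retained_features]
        Xtr = apply_preprocessor(state, train_tbl).values[selected]
        Xte = apply_preprocessor(state, test_tbl).values[selected]
        fitted = fit_estimator(
            Xtr, ytr, forest_spec.replace(seed=rep_seed), estimator=estimator
        )
        yp = predict(fitted, Xte)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant-target folds -> NaN R²
            metrics = compute_metrics(yte, yp)
        replicates.append(
            ReplicateResult(
                repeat=repeat,
                fold=fold,
                test_ids=list(ids[te]),
                y_true=yte,
                y_pred=yp,
                metrics=metrics,
                selected_features=list(selected),
            )
        )
    return CVReport(replicates=replicates, cv_spec=cv_spec)


def benchmark(
    pred_a: Mapping[str, float], ref: Mapping[str, float]
) -> tuple[MetricSet, int]:
    """Compare two prediction sets on their shared chemicals.

    Metrics are computed on the key intersection only (``ref`` as the
    truth); the overlap size is returned alongside. Fewer than 2 shared
    chemicals is an error.
    """
    common = sorted(set(pred_a) & set(ref))
    if len(common) < 2:
        raise InvalidInputError(
            f"need >= 2 overlapping chemicals, got {len(common)}"
        )
    a = np.array([pred_a[c] for c in common], dtype=float)
    r = np.array([ref[c] for c in common], dtype=float)
    return compute_metrics(r, a), len(common)
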