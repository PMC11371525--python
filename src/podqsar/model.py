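"""Model/Results frontend tying the pipeline together.

:class:`PODRegression` is constructed from a feature table and a
labeled POD dataset for one effect category; ``fit()`` runs the full
training recipe on the labeled chemicals — study-count filter,
applicability-domain flagging, preprocessor fit, permutation-importance
feature selection, random-forest fit — and returns a
:class:`PODRegressionResults` carrying the fitted pipeline, the
cross-validated generalization-error estimates (when requested), and
the downstream risk-screening methods.

Example
-------
>>> from podqsar import simulate, PODRegression, CVSpec
>>> feats, pods = simulate.generate_labeled_data(
...     simulate.SyntheticSpec(n_chemicals=300, seed=7))
>>> res = PODRegression(feats, pods).fit(cv_spec=CVSpec(outer_repeats=2))
>>> len(res.selected_features)
10
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import joblib
import numpy as np
import pandas as pd

from . import __version__
from .estimators import FittedEstimator, ForestSpec, fit_estimator, predict
from .evaluation import CVReport, CVSpec, nested_cv
from .ingest import (
    DEFAULT_MIN_STUDIES,
    EffectCategory,
    ExposureTable,
    FeatureTable,
    PODDataset,
    SchemaError,
    filter_by_study_count,
    read_feature_table,
    read_pod_table,
)
from .preprocess import PreprocessState, apply_preprocessor, fit_preprocessor
from .screening import (
    DEFAULT_COVERAGE,
    category_counts,
    fold_error,
    gsd_squared,
    prediction_interval,
    screen_chemicals,
)
from .selection import ImportanceResult, SelectionSpec, select_features


class PODRegression:
    """Random-forest regression of log10 POD on predicted properties.

    Parameters
    ----------
    features : FeatureTable
        Per-chemical predicted-property features (domain flagging is
        applied on construction unless ``flag_domain=False``).
    pods : PODDataset
        Labeled log10 PODs for one effect category. Chemicals with
        fewer than ``min_studies`` underlying in vivo studies are
        excluded from training.
    forest_spec, selection_spec : hyperparameter bundles.
    feature_selection : bool
        When False, skip the inner selection loop and use all retained
        features (the no-selection sensitivity variant).
    estimator : str
        Registered estimator name; ``"random_forest"`` is the default
        and the deployed choice.
    """

    def __init__(
        self,
        features: FeatureTable,
        pods: PODDataset,
        *,
        forest_spec: ForestSpec | None = None,
        selection_spec: SelectionSpec | None = None,
        feature_selection: bool = True,
        estimator: str = "random_forest",
        min_studies: int = DEFAULT_MIN_STUDIES,
        flag_domain: bool = True,
    ) -> None:
        self.forest_spec = forest_spec or ForestSpec()
        self.selection_spec = selection_spec or SelectionSpec()
        self.feature_selection = feature_selection
        self.estimator_name = estimator
        self.min_studies = min_studies

        self.pods = filter_by_study_count(pods, min_studies)
        if flag_domain:
            features = features.apply_domain_flags()
        missing = [c for c in self.pods.chemical_ids
                   if c not in features.values.index]
        if missing:
            raise SchemaError(
                f"labeled chemicals missing from feature table: {missing[:10]}"
            )
        self.features = features
        self.labeled_features = features.subset(self.pods.chemical_ids)

    @classmethod
    def from_csv(
        cls,
        features_path,
        pods_path,
        effect_category: EffectCategory | str,
        **kwargs,
    ) -> "PODRegression":
        """Build the model straight from the two training CSVs."""
        features = read_feature_table(features_path)
        pods = read_pod_table(pods_path, effect_category)
        return cls(features, pods, flag_domain=False, **kwargs)

    @property
    def effect_category(self) -> EffectCategory:
        return self.pods.effect_category

    @property
    def nobs(self) -> int:
        return len(self.pods)

    def cross_validate(self, cv_spec: CVSpec | None = None) -> CVReport:
        """Outer repeated k-fold evaluation of the full training recipe."""
        return nested_cv(
            self.labeled_features,
            self.pods,
            forest_spec=self.forest_spec,
            sel_spec=self.selection_spec,
            cv_spec=cv_spec or CVSpec(),
            estimator=self.estimator_name,
            feature_selection=self.feature_selection,
        )

    def fit(self, cv_spec: CVSpec | None = None) -> "PODRegressionResults":
        """Fit the deployable model on the full labeled dataset.

        Runs feature selection on the full labeled data, then fits the
        preprocessor and estimator on all labeled chemicals. When
        ``cv_spec`` is given, the nested cross-validation report is
        computed first and its median RMSE is attached to the results
        for prediction-interval construction.
        """
        cv_report = self.cross_validate(cv_spec) if cv_spec is not None else None

        y = self.pods.log10_pod
        if self.feature_selection:
            importance = select_features(
                self.labeled_features, y,
                self.forest_spec, self.selection_spec,
                estimator=self.estimator_name,
            )
            selected = importance.selected
        else:
            importance = None
            selected = self.labeled_features.feature_names

        state = fit_preprocessor(self.labeled_features)
        selected = [f for f in selected if f in state.retained_features]
        Xtr = apply_preprocessor(state, self.labeled_features).values[selected]
        fitted = fit_estimator(Xtr, y, self.forest_spec,
                               estimator=self.estimator_name)
        cv_rmse = (
            cv_report.summary()["rmse"]["median"] if cv_report is not None
            else None
        )
        return PODRegressionResults(
            model=self,
            preprocess_state=state,
            selected_features=list(selected),
            importance=importance,
            fitted=fitted,
            cv_report=cv_report,
            cv_rmse=cv_rmse,
        )


@dataclasses.dataclass
class PODRegressionResults:
    """Fitted POD model: pipeline state, diagnostics, and risk methods."""

    model: PODRegression | None
    preprocess_state: PreprocessState
    selected_features: list[str]
    importance: ImportanceResult | None
    fitted: FittedEstimator
    cv_report: CVReport | None = None
    cv_rmse: float | None = None
    effect_category: EffectCategory | None = None
    forest_spec: ForestSpec | None = None

    def __post_init__(self) -> None:
        if self.model is not None:
            self.effect_category = self.model.effect_category
            self.forest_spec = self.model.forest_spec
        self._fully_imputed: tuple[str, ...] = ()

    # -- prediction ------------------------------------------------------
    def predict(self, features: FeatureTable | None = None) -> pd.Series:
        """Predicted log10 PODs (mg/(kg-d)) for a feature table.

        Defaults to the training chemicals (fitted values). New tables
        are domain-flagged, imputed with the *training* medians, and
        restricted to the selected features.
        """
        if features is None:
            if self.model is None:
                raise SchemaError("no training features attached; pass a table")
            table = self.model.labeled_features
        else:
            table = features.apply_domain_flags()
        prepped = apply_preprocessor(self.preprocess_state, table)
        self._fully_imputed = prepped.fully_imputed
        X = prepped.values[self.selected_features]
        return pd.Series(predict(self.fitted, X), index=X.index,
                         name="log10_pod_pred")

    def prediction_intervals(
        self,
        features: FeatureTable | None = None,
        coverage: float = DEFAULT_COVERAGE,
    ) -> pd.DataFrame:
        """Central predictions with dose-scale prediction intervals."""
        rmse = self._require_rmse()
        preds = self.predict(features)
        rows = {
            cid: prediction_interval(float(v), rmse, coverage)
            for cid, v in preds.items()
        }
        return pd.DataFrame(
            {
                "log10_pod_central": preds,
                "pod_central": 10.0 ** preds,
                "pi_lower": pd.Series({c: lo for c, (lo, _) in rows.items()}),
                "pi_upper": pd.Series({c: hi for c, (_, hi) in rows.items()}),
            }
        )

    def screen(
        self,
        exposures: ExposureTable,
        features: FeatureTable | None = None,
        coverage: float = DEFAULT_COVERAGE,
    ):
        """Margin-of-exposure screening against an exposure table.

        Returns ``(frame, assessments, missing_exposure_ids)``; see
        :func:`podqsar.screening.screen_chemicals`.
        """
        rmse = self._require_rmse()
        preds = self.predict(features)
        return screen_chemicals(
            {c: float(v) for c, v in preds.items()},
            exposures,
            rmse,
            coverage,
            fully_imputed=self._fully_imputed,
        )

    def _require_rmse(self) -> float:
        if self.cv_rmse is None:
            raise SchemaError(
                "no cross-validated RMSE attached; fit with cv_spec= or set "
                "cv_rmse"
            )
        return float(self.cv_rmse)

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary table of the fitted model."""
        lines = []
        w = 72
        lines.append("POD QSAR Regression Results".center(w))
        lines.append("=" * w)
        cat = self.effect_category.value if self.effect_category else "unknown"
        nobs = self.model.nobs if self.model is not None else "n/a"
        info = [
            ("Effect category:", cat),
            ("No. labeled chemicals:", str(nobs)),
            ("Estimator:", self.fitted.name),
            ("Features retained:",
             str(len(self.preprocess_state.retained_features))),
            ("Features dropped (sparse):",
             str(len(self.preprocess_state.dropped_features))),
            ("Features selected:", str(len(self.selected_features))),
        ]
        for label, value in info:
            lines.append(f"{label:<32}{value:>40}")
        if self.cv_report is not None:
            lines.append("-" * w)
            lines.append("Generalization error (outer CV, median [p5, p95])")
            summ = self.cv_report.summary()
            for metric, label in (("rmse", "RMSE (log10)"),
                                  ("medae", "MedAE (log10)"),
                                  ("r2", "R²")):
                s = summ[metric]
                lines.append(
                    f"  {label:<18}{s['median']:>10.3f}   "
                    f"[{s['p5']:.3f}, {s['p95']:.3f}]"
                )
            rmse = summ["rmse"]["median"]
            lines.append(
                f"  {'GSD fold error':<18}{fold_error(rmse):>10.2f}"
                f"   (GSD² = {gsd_squared(rmse):.1f})"
            )
        lines.append("-" * w)
        lines.append("Selected features (descending importance):")
        for f in self.selected_features:
            agg = (self.importance.aggregate.get(f) if self.importance
                   else None)
            tail = f"  {agg:+.4f}" if agg is not None else ""
            lines.append(f"  {f}{tail}")
        lines.append("=" * w)
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        """Persist as a bundle directory: JSON metadata + joblib estimator."""
        path = pathlib.Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "format": "podqsar-bundle-v1",
            "package_version": __version__,
            "effect_category": (self.effect_category.value
                                if self.effect_category else None),
            "estimator": self.fitted.name,
            "feature_names": list(self.fitted.feature_names),
            "selected_features": list(self.selected_features),
            "cv_rmse": self.cv_rmse,
            "forest_spec": (dataclasses.asdict(self.forest_spec)
                            if self.forest_spec else None),
            "preprocess_state": json.loads(self.preprocess_state.to_json()),
        }
        (path / "metadata.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True)
        )
        joblib.dump(self.fitted.estimator, path / "estimator.joblib")
        if self.importance is not None:
            self.importance.to_frame().to_csv(
                path / "feature_importance.csv", index=False
            )
        if self.cv_report is not None:
            self.cv_report.scores_frame().to_csv(
                path / "cv_replicates.csv", index=False
            )
            (path / "cv_summary.json").write_text(self.cv_report.summary_json())

    @classmethod
    def load(cls, path) -> "PODRegressionResults":
        """Reload a saved bundle for prediction and screening."""
        path = pathlib.Path(path)
        meta = json.loads((path / "metadata.json").read_text())
        if meta.get("format") != "podqsar-bundle-v1":
            raise SchemaError(f"not a model bundle: {path}")
        est = joblib.load(path / "estimator.joblib")
        state = PreprocessState.from_json(
            json.dumps(meta["preprocess_state"])
        )
        forest = (ForestSpec(**meta["forest_spec"])
                  if meta.get("forest_spec") else None)
        res = cls(
            model=None,
            preprocess_state=state,
            selected_features=list(meta["selected_features"]),
            importance=None,
            fitted=FittedEstimator(est, tuple(meta["feature_names"]),
                                   meta["estimator"]),
            cv_rmse=meta.get("cv_rmse"),
            effect_category=(EffectCategory(meta["effect_category"])
                             if meta.get("effect_category") else None),
            forest_spec=forest,
        )
        return res
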