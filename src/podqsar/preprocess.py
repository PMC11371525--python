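"""Leakage-safe feature preprocessing: sparse-feature drop + median imputation.

All transformation parameters are derived from the training split only,
then applied unchanged to held-out data, so no information from test
chemicals can leak into the fitted pipeline. Features needing more than
30% imputation are dropped first (imputing a mostly-missing column would
mostly fabricate it); remaining missing cells are filled with the
training median. Binary features get a median rounded to the nearer of
{0, 1} (ties to 0), equivalent to the training mode. No scaling is
applied: the downstream tree ensemble is invariant to monotone
transforms.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd

from .ingest import FeatureTable, InvalidInputError, SchemaError

DEFAULT_MISSINGNESS_THRESHOLD = 0.30


@dataclasses.dataclass
class PreprocessState:
    """Fitted preprocessing parameters (training data only).

    ``retained_features`` are the features whose training missingness is
    <= ``missingness_threshold``; ``medians`` maps each retained feature
    to its training median; ``dropped_features`` records why each
    excluded feature was removed. ``feature_kind`` is carried through so
    applying the state preserves binary tags.
    """

    retained_features: tuple[str, ...]
    medians: dict[str, float]
    missingness_threshold: float = DEFAULT_MISSINGNESS_THRESHOLD
    dropped_features: dict[str, str] = dataclasses.field(default_factory=dict)
    feature_kind: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.missingness_threshold <= 1.0:
            raise InvalidInputError("missingness threshold must be in [0, 1]")
        if set(self.medians) != set(self.retained_features):
            raise InvalidInputError(
                "medians must be defined exactly for retained features"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "retained_features": list(self.retained_features),
                "medians": self.medians,
                "missingness_threshold": self.missingness_threshold,
                "dropped_features": self.dropped_features,
                "feature_kind": self.feature_kind,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "PreprocessState":
        d = json.loads(text)
        return cls(
            retained_features=tuple(d["retained_features"]),
            medians={k: float(v) for k, v in d["medians"].items()},
            missingness_threshold=float(d["missingness_threshold"]),
            dropped_features=dict(d.get("dropped_features", {})),
            feature_kind=dict(d.get("feature_kind", {})),
        )


def fit_preprocessor(
    train: FeatureTable, threshold: float = DEFAULT_MISSINGNESS_THRESHOLD
) -> PreprocessState:
    """Fit drop-and-impute parameters on a training feature table.

    A feature is retained iff its missing fraction is <= ``threshold``
    (strictly greater triggers exclusion). A feature with zero
    non-missing training values is excluded with a warning and never
    given a median.
    """
    if train.n_chemicals == 0:
        raise InvalidInputError("training feature table is empty")
    if not 0.0 <= threshold <= 1.0:
        raise InvalidInputError("missingness threshold must be in [0, 1]")
    retained: list[str] = []
    medians: dict[str, float] = {}
    dropped: dict[str, str] = {}
    miss_frac = train.values.isna().mean(axis=0)
    for feat in train.feature_names:
        obs = train.values[feat].dropna()
        if len(obs) == 0:
            warnings.warn(
                f"feature {feat!r} has no observed training values; excluded",
                stacklevel=2,
            )
            dropped[feat] = "no observed values"
            continue
        if miss_frac[feat] > threshold:
            dropped[feat] = (
                f"missing fraction {miss_frac[feat]:.3f} > {threshold:g}"
            )
            continue
        med = float(np.median(obs.to_numpy()))
        if train.feature_kind.get(feat) == "binary":
            med = 1.0 if med > 0.5 else 0.0  # ties -> 0
        retained.append(feat)
        medians[feat] = med
    return PreprocessState(
        retained_features=tuple(retained),
        medians=medians,
        missingness_threshold=threshold,
        dropped_features=dropped,
        feature_kind={f: train.feature_kind[f] for f in retained},
    )


def apply_preprocessor(state: PreprocessState, table: FeatureTable) -> FeatureTable:
    """Restrict a table to the retained features and impute with medians.

    Output columns are exactly ``state.retained_features`` with no
    missing values; non-missing cells pass through unchanged. Chemicals
    whose entire (retained) feature row was missing are recorded in the
    output's ``fully_imputed`` field rather than dropped. Idempotent.
    """
    absent = [f for f in state.retained_features if f not in table.values.columns]
    if absent:
        raise SchemaError(f"retained features absent from table: {absent}")
    sub = table.select_features(list(state.retained_features))
    all_missing = sub.values.isna().all(axis=1)
    values = sub.values.fillna(pd.Series(state.medians))
    return FeatureTable(
        values=values,
        domain_global=sub.domain_global,
        domain_local_index=sub.domain_local_index,
        feature_kind={f: state.feature_kind.get(f, sub.feature_kind[f])
                      for f in state.retained_features},
        fully_imputed=tuple(sub.values.index[all_missing]),
    )
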