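"""Input tables: feature matrices, POD labels, and exposure estimates.

Three CSV tables drive the pipeline:

* a per-chemical **feature table** of Stage-1 QSAR-predicted properties
  (one row per chemical, keyed by DTXSID), optionally carrying per-feature
  applicability-domain metadata — a global in/out flag and a local
  applicability-domain index in [0, 1];
* a **POD table** of log10-transformed human-equivalent oral points of
  departure (mg/(kg-d)) per chemical and effect category, with the number
  of underlying in vivo studies;
* an **exposure table** of predicted oral exposures (mg/(kg-d)) per
  chemical at several uncertainty percentiles.

Feature values predicted outside a model's applicability domain are
unreliable; they are flagged missing when *both* the global flag says
"outside" and the local index falls below ``LOCAL_INDEX_THRESHOLD``.
Chemicals whose POD rests on too few in vivo studies are excluded from
training because the surrogate POD is itself unstable.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Local applicability-domain index below which an outside-global-domain
#: prediction is treated as missing.
LOCAL_INDEX_THRESHOLD = 0.4

#: Minimum number of underlying in vivo studies for a surrogate POD to be
#: considered robust enough for training (chemicals with <= 3 are excluded).
DEFAULT_MIN_STUDIES = 4

#: Default chemical-identifier column.
ID_COLUMN = "DTXSID"

#: Default suffixes for the paired applicability-domain columns.
AD_SUFFIX = "_AD"
AD_INDEX_SUFFIX = "_ADindex"

#: CSV missing-value sentinels accepted on read; empty written on write.
NA_SENTINELS = ("", "NA")


class InvalidInputError(ValueError):
    """A value violates an operation's preconditions."""


class SchemaError(ValueError):
    """A table does not match the expected layout."""


class EffectCategory(str, enum.Enum):
    """Health-effect category; each category is modeled independently."""

    GENERAL_NONCANCER = "general_noncancer"
    REPRO_DEVELOPMENTAL = "repro_developmental"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def flag_out_of_domain(value: float, inside_global: bool, local_index: float) -> float:
    """Apply the two-criterion applicability-domain rule to one cell.

    A predicted feature value is replaced by ``nan`` (missing) iff it is
    outside the *global* applicability domain **and** its *local*
    applicability-domain index is below :data:`LOCAL_INDEX_THRESHOLD`.
    Meeting only one criterion keeps the value.

    Parameters
    ----------
    value : float
        The predicted feature value (may already be nan).
    inside_global : bool
        Whether the chemical lies inside the global applicability domain
        of the feature's model.
    local_index : float
        Local applicability-domain index in [0, 1] relative to nearest
        neighbours.

    Returns
    -------
    float
        ``nan`` if both criteria are met, else ``value`` unchanged.
    """
    if not (0.0 <= local_index <= 1.0):
        raise InvalidInputError(
            f"local applicability-domain index must be in [0, 1], got {local_index!r}"
        )
    if (not inside_global) and local_index < LOCAL_INDEX_THRESHOLD:
        return float("nan")
    return value


def _infer_feature_kind(values: pd.DataFrame) -> dict[str, str]:
    kinds: dict[str, str] = {}
    for col in values.columns:
        obs = values[col].dropna()
        if len(obs) > 0 and obs.isin([0, 1]).all():
            kinds[col] = "binary"
        else:
            kinds[col] = "continuous"
    return kinds


@dataclasses.dataclass
class FeatureTable:
    """A chemicals x features grid with applicability-domain metadata.

    Attributes
    ----------
    values : pandas.DataFrame
        Numeric feature values indexed by chemical ID; ``NaN`` = missing.
    domain_global : pandas.DataFrame
        Per-cell boolean, True where the prediction is inside the global
        applicability domain. Defaults to all-True when not supplied.
    domain_local_index : pandas.DataFrame
        Per-cell local applicability-domain index in [0, 1]. Defaults to 1.
    feature_kind : dict
        Per-feature tag, ``"continuous"`` or ``"binary"``. Inferred from
        the observed values when not supplied (a feature whose non-missing
        values are all 0/1 is tagged binary).
    fully_imputed : tuple of str
        Chemical IDs whose entire feature row was missing before
        imputation; populated by the preprocessor, carried as a warning.
    """

    values: pd.DataFrame
    domain_global: pd.DataFrame | None = None
    domain_local_index: pd.DataFrame | None = None
    feature_kind: dict[str, str] | None = None
    fully_imputed: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate chemical IDs: {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate feature names: {dups}")
        if self.domain_global is None:
            self.domain_global = pd.DataFrame(
                True, index=v.index, columns=v.columns, dtype=bool
            )
        else:
            self.domain_global = self.domain_global.reindex(
                index=v.index, columns=v.columns
            ).fillna(True).astype(bool)
        if self.domain_local_index is None:
            self.domain_local_index = pd.DataFrame(
                1.0, index=v.index, columns=v.columns, dtype=float
            )
        else:
            self.domain_local_index = (
                self.domain_local_index.reindex(index=v.index, columns=v.columns)
                .fillna(1.0)
                .astype(float)
            )
        idx = self.domain_local_index.to_numpy()
        if ((idx < 0) | (idx > 1)).any():
            raise InvalidInputError(
                "local applicability-domain index outside [0, 1]"
            )
        if self.feature_kind is None:
            self.feature_kind = _infer_feature_kind(v)
        else:
            missing = set(v.columns) - set(self.feature_kind)
            if missing:
                inferred = _infer_feature_kind(v[sorted(missing)])
                self.feature_kind = {**self.feature_kind, **inferred}
        for col, kind in self.feature_kind.items():
            if kind == "binary" and col in v.columns:
                obs = v[col].dropna()
                if not obs.isin([0, 1]).all():
                    raise InvalidInputError(
                        f"binary feature {col!r} has values outside {{0, 1}}"
                    )

    # -- basic views -----------------------------------------------------
    @property
    def chemical_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_chemicals(self) -> int:
        return len(self.values.index)

    @property
    def n_features(self) -> int:
        return len(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def subset(self, chemical_ids: Sequence[str]) -> "FeatureTable":
        """Row subset preserving the given order."""
        ids = list(chemical_ids)
        missing = [c for c in ids if c not in self.values.index]
        if missing:
            raise SchemaError(f"chemicals not in feature table: {missing}")
        return FeatureTable(
            values=self.values.loc[ids].copy(),
            domain_global=self.domain_global.loc[ids].copy(),
            domain_local_index=self.domain_local_index.loc[ids].copy(),
            feature_kind=dict(self.feature_kind),
        )

    def select_features(self, features: Sequence[str]) -> "FeatureTable":
        """Column subset preserving the given order."""
        feats = list(features)
        missing = [f for f in feats if f not in self.values.columns]
        if missing:
            raise SchemaError(f"features not in table: {missing}")
        return FeatureTable(
            values=self.values[feats].copy(),
            domain_global=self.domain_global[feats].copy(),
            domain_local_index=self.domain_local_index[feats].copy(),
            feature_kind={f: self.feature_kind[f] for f in feats},
            fully_imputed=self.fully_imputed,
        )

    def apply_domain_flags(self) -> "FeatureTable":
        """Mask cells outside the applicability domain (vectorised rule).

        Idempotent: flagged cells stay missing, everything else is kept.
        """
        mask = (~self.domain_global) & (
            self.domain_local_index < LOCAL_INDEX_THRESHOLD
        )
        return FeatureTable(
            values=self.values.mask(mask),
            domain_global=self.domain_global.copy(),
            domain_local_index=self.domain_local_index.copy(),
            feature_kind=dict(self.feature_kind),
            fully_imputed=self.fully_imputed,
        )

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.values.equals(other.values)
            and self.domain_global.equals(other.domain_global)
            and self.domain_local_index.equals(other.domain_local_index)
            and self.feature_kind == other.feature_kind
        )


@dataclasses.dataclass
class PODDataset:
    """Per-chemical log10 POD labels for one effect category.

    ``data`` is indexed by chemical ID with columns ``log10_pod``
    (log10 mg/(kg-d), the surrogate human-equivalent benchmark dose) and
    ``study_count`` (number of underlying in vivo studies).
    """

    effect_category: EffectCategory
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.effect_category = EffectCategory(self.effect_category)
        required = {"log10_pod", "study_count"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"POD table missing columns: {sorted(missing)}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise SchemaError(
                f"duplicate chemicals for effect category "
                f"{self.effect_category.value}: {dups}"
            )
        pod = self.data["log10_pod"].to_numpy(dtype=float)
        if not np.isfinite(pod).all():
            raise InvalidInputError("log10_pod must be finite")
        counts = self.data["study_count"]
        if (counts < 0).any():
            raise InvalidInputError("study_count must be >= 0")

    @property
    def chemical_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def log10_pod(self) -> pd.Series:
        return self.data["log10_pod"]

    @property
    def study_count(self) -> pd.Series:
        return self.data["study_count"]

    def __len__(self) -> int:
        return len(self.data)


def filter_by_study_count(
    dataset: PODDataset, min_studies: int = DEFAULT_MIN_STUDIES
) -> PODDataset:
    """Drop chemicals whose surrogate POD rests on too few in vivo studies.

    Retains exactly the chemicals with ``study_count >= min_studies``
    (the default 4 excludes chemicals with <= 3 studies), preserving
    order. ``min_studies=0`` is the identity.
    """
    keep = dataset.data["study_count"] >= min_studies
    return PODDataset(dataset.effect_category, dataset.data.loc[keep].copy())


@dataclasses.dataclass
class ExposureTable:
    """Predicted oral exposure per chemical at uncertainty percentiles.

    ``data`` is indexed by chemical ID; columns are numeric percentiles
    (e.g. 5, 50, 95) and values are doses in mg/(kg-d). Doses must be
    positive and nondecreasing across percentiles within a chemical.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise SchemaError("duplicate chemical IDs in exposure table")
        cols = sorted(float(c) for c in self.data.columns)
        self.data = self.data[[c for _, c in sorted(
            zip([float(c) for c in self.data.columns], self.data.columns)
        )]]
        self.data.columns = [float(c) for c in self.data.columns]
        arr = self.data.to_numpy(dtype=float)
        if (arr <= 0).any() or not np.isfinite(arr).all():
            raise InvalidInputError("exposure doses must be positive and finite")
        if (np.diff(arr, axis=1) < 0).any():
            raise InvalidInputError(
                "exposure doses must be nondecreasing in percentile"
            )

    @property
    def percentiles(self) -> list[float]:
        return [float(c) for c in self.data.columns]

    @property
    def chemical_ids(self) -> list[str]:
        return list(self.data.index)

    def percentile_doses(self, chemical_id: str) -> dict[float, float]:
        """Mapping percentile -> dose for one chemical."""
        if chemical_id not in self.data.index:
            raise SchemaError(f"no exposure row for {chemical_id!r}")
        return {float(p): float(v) for p, v in self.data.loc[chemical_id].items()}

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _parse_numeric(raw: pd.Series, column: str) -> pd.Series:
    cleaned = raw.str.strip().replace(list(NA_SENTINELS), np.nan)
    out = pd.to_numeric(cleaned, errors="coerce")
    bad = cleaned.notna() & out.isna()
    if bad.any():
        rows = list(raw.index[bad][:5])
        raise SchemaError(
            f"non-numeric values in column {column!r} at rows {rows}: "
            f"{cleaned[bad].head().tolist()}"
        )
    return out.astype(float)


def read_feature_table(
    path,
    id_column: str = ID_COLUMN,
    ad_suffix: str = AD_SUFFIX,
    ad_index_suffix: str = AD_INDEX_SUFFIX,
    flag_domain: bool = True,
    feature_kind: Mapping[str, str] | None = None,
) -> FeatureTable:
    """Read a feature CSV into a validated :class:`FeatureTable`.

    The file has a chemical-ID column, one column per feature, and
    (optionally) paired applicability-domain columns ``<feature>_AD``
    (0/1, inside global domain) and ``<feature>_ADindex`` (local index in
    [0, 1]). Absent domain columns default to inside-global with local
    index 1, i.e. never flagged. Empty cells and ``NA`` are missing.

    With ``flag_domain=True`` (default) the two-criterion
    applicability-domain rule is applied on read.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if id_column not in raw.columns:
        raise SchemaError(f"missing chemical-ID column {id_column!r}")
    ids = raw[id_column].str.strip()
    if ids.duplicated().any():
        raise SchemaError(
            f"duplicate chemical IDs: {ids[ids.duplicated()].unique().tolist()}"
        )
    other = [c for c in raw.columns if c != id_column]
    feature_cols = [
        c for c in other
        if not (c.endswith(ad_suffix) or c.endswith(ad_index_suffix))
    ]
    feature_set = set(feature_cols)
    for c in other:
        if c.endswith(ad_index_suffix):
            base = c[: -len(ad_index_suffix)]
        elif c.endswith(ad_suffix):
            base = c[: -len(ad_suffix)]
        else:
            continue
        if base not in feature_set:
            raise SchemaError(
                f"applicability-domain column {c!r} has no matching feature "
                f"column {base!r}"
            )

    values = pd.DataFrame(index=pd.Index(ids, name=id_column))
    domain_global = pd.DataFrame(index=values.index)
    domain_local = pd.DataFrame(index=values.index)
    for c in feature_cols:
        values[c] = _parse_numeric(raw[c], c).to_numpy()
        ad_col = c + ad_suffix
        idx_col = c + ad_index_suffix
        if ad_col in raw.columns:
            parsed = _parse_numeric(raw[ad_col], ad_col)
            if not parsed.dropna().isin([0, 1]).all():
                raise SchemaError(f"column {ad_col!r} must contain only 0/1")
            domain_global[c] = parsed.fillna(1).astype(bool).to_numpy()
        else:
            domain_global[c] = True
        if idx_col in raw.columns:
            parsed = _parse_numeric(raw[idx_col], idx_col)
            domain_local[c] = parsed.fillna(1.0).to_numpy()
        else:
            domain_local[c] = 1.0

    table = FeatureTable(
        values=values,
        domain_global=domain_global,
        domain_local_index=domain_local,
        feature_kind=dict(feature_kind) if feature_kind else None,
    )
    return table.apply_domain_flags() if flag_domain else table


def write_feature_table(
    table: FeatureTable,
    path,
    id_column: str = ID_COLUMN,
    ad_suffix: str = AD_SUFFIX,
    ad_index_suffix: str = AD_INDEX_SUFFIX,
) -> None:
    """Write a :class:`FeatureTable` with its domain columns; NaN -> empty."""
    out = pd.DataFrame(index=table.values.index)
    for c in table.feature_names:
        out[c] = table.values[c]
        out[c + ad_suffix] = table.domain_global[c].astype(int)
        out[c + ad_index_suffix] = table.domain_local_index[c]
    out.index.name = id_column
    out.to_csv(path, na_rep="")


def read_pod_table(
    path,
    effect_category: EffectCategory | str,
    id_column: str = ID_COLUMN,
) -> PODDataset:
    """Read a labeled POD CSV and return the rows for one effect category.

    Expected columns: the chemical ID, ``effect_category``, ``log10_pod``
    (log10 mg/(kg-d)) and ``study_count``.
    """
    effect_category = EffectCategory(effect_category)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {id_column, "effect_category", "log10_pod", "study_count"}
    missing = required - set(raw.columns)
    if missing:
        raise SchemaError(f"POD table missing columns: {sorted(missing)}")
    sel = raw[raw["effect_category"].str.strip() == effect_category.value]
    data = pd.DataFrame(
        {
            "log10_pod": _parse_numeric(sel["log10_pod"], "log10_pod").to_numpy(),
            "study_count": _parse_numeric(
                sel["study_count"], "study_count"
            ).astype(int).to_numpy(),
        },
        index=pd.Index(sel[id_column].str.strip(), name=id_column),
    )
    return PODDataset(effect_category, data)


def write_pod_table(
    datasets: Iterable[PODDataset], path, id_column: str = ID_COLUMN
) -> None:
    frames = []
    for ds in datasets:
        df = ds.data.copy()
        df.insert(0, "effect_category", ds.effect_category.value)
        df.index.name = id_column
        frames.append(df.reset_index())
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_exposure_table(path, id_column: str = ID_COLUMN) -> ExposureTable:
    """Read an exposure CSV with percentile columns named ``p<percentile>``."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if id_column not in raw.columns:
        raise SchemaError(f"missing chemical-ID column {id_column!r}")
    pct_cols = {}
    for c in raw.columns:
        if c == id_column:
            continue
        name = c[1:] if c.startswith("p") else c
        try:
            pct_cols[c] = float(name)
        except ValueError:
            raise SchemaError(f"unrecognised exposure column {c!r}") from None
    data = pd.DataFrame(index=pd.Index(raw[id_column].str.strip(), name=id_column))
    for c, p in pct_cols.items():
        data[p] = _parse_numeric(raw[c], c).to_numpy()
    return ExposureTable(data)


def write_exposure_table(
    table: ExposureTable, path, id_column: str = ID_COLUMN
) -> None:
    out = table.data.copy()
    out.columns = [f"p{int(p) if float(p).is_integer() else p}" for p in out.columns]
    out.index.name = id_column
    out.to_csv(path)
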