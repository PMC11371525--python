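"""Synthetic data with known structure for end-to-end testing.

The generator emulates the statistical shape of the real inputs: a
chemicals x 39 feature table of mixed continuous (unit-normal) and
binary (Bernoulli(0.5)) predicted properties with feature-wise
missingness, a log10-scale POD target that is a sparse linear
combination of a few informative features plus Gaussian noise, and a
lognormal exposure table with multiplicative credible-interval
percentiles. Missingness is encoded through applicability-domain
metadata (outside the global domain with a low local index), so the
domain-flagging path is exercised end to end rather than bypassed with
bare gaps.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .ingest import (
    EffectCategory,
    ExposureTable,
    FeatureTable,
    InvalidInputError,
    PODDataset,
)

#: Number of Stage-1 predicted-property features emulated.
DEFAULT_N_FEATURES = 39

#: z-score of the 95th percentile, used for credible-interval construction.
_Z95 = 1.645


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults mirror the scale of the real problem: ~2,000 labeled
    chemicals, 39 features of which the last 8 are binary, three
    informative features with log10-scale effect sizes >= 1, residual
    noise of 0.5 log10 units, low missingness on most features with
    three heavily-missing features (>30%) that the preprocessor should
    drop, and exposure percentiles spanning ~4 orders of magnitude
    between p5 and p95 (GSD ~16).
    """

    n_chemicals: int = 2000
    n_features: int = DEFAULT_N_FEATURES
    informative_features: tuple[tuple[int, float], ...] = (
        (0, 1.2),
        (1, 1.0),
        (2, 1.0),
    )
    noise_sd: float = 0.5
    missingness: float | tuple[float, ...] | None = None
    binary_features: tuple[int, ...] = tuple(range(31, 39))
    exposure_gsd: float = 16.0
    intercept: float = 0.5
    effect_category: EffectCategory = EffectCategory.GENERAL_NONCANCER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chemicals < 1 or self.n_features < 1:
            raise InvalidInputError("n_chemicals and n_features must be >= 1")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if any(i >= self.n_features or i < 0 for i, _ in self.informative_features):
            raise InvalidInputError("informative feature index out of range")
        if any(i >= self.n_features or i < 0 for i in self.binary_features):
            # out-of-range binary indices are ignored rather than fatal:
            # the default tail indices only exist at full width
            object.__setattr__(
                self,
                "binary_features",
                tuple(i for i in self.binary_features if i < self.n_features),
            )
        for m in self._missingness_vector():
            if not 0.0 <= m < 1.0:
                raise InvalidInputError("missingness must be in [0, 1)")

    def _missingness_vector(self) -> np.ndarray:
        """Per-feature missing fractions.

        Default: 5% on every feature except the last three non-binary
        features, which get 35% (above the 30% drop threshold),
        emulating a feature table where a few models place many
        chemicals outside their applicability domain.
        """
        if self.missingness is None:
            vec = np.full(self.n_features, 0.05)
            informative = {i for i, _ in self.informative_features}
            heavy = [
                i
                for i in range(self.n_features - 1, -1, -1)
                if i not in self.binary_features and i not in informative
            ][:3]
            vec[heavy] = 0.35
            return vec
        if np.isscalar(self.missingness):
            return np.full(self.n_features, float(self.missingness))
        vec = np.asarray(self.missingness, dtype=float)
        if vec.shape != (self.n_features,):
            raise InvalidInputError(
                "missingness must be scalar or one value per feature"
            )
        return vec

    def replace(self, **kwargs) -> "SyntheticSpec":
        return dataclasses.replace(self, **kwargs)


def _feature_names(n: int) -> list[str]:
    return [f"F{i + 1:02d}" for i in range(n)]


def _chemical_ids(n: int) -> list[str]:
    return [f"DTXSID{i + 1:07d}" for i in range(n)]


def generate_labeled_data(spec: SyntheticSpec) -> tuple[FeatureTable, PODDataset]:
    """Draw a feature table and matching POD labels.

    Continuous features are unit normal, binary features
    Bernoulli(0.5); the target is
    ``log10_pod = intercept + Σ effect·feature + ε`` with
    ``ε ~ N(0, noise_sd)``. Missing cells are encoded as
    outside-global-domain with a local index below the flagging
    threshold; all other cells carry a local index >= 0.4. Study counts
    are uniform on 1..20. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, f = spec.n_chemicals, spec.n_features
    names = _feature_names(f)
    ids = _chemical_ids(n)

    X = rng.standard_normal((n, f))
    for j in spec.binary_features:
        X[:, j] = rng.integers(0, 2, size=n).astype(float)

    y = np.full(n, float(spec.intercept))
    for j, effect in spec.informative_features:
        y = y + effect * X[:, j]
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=n)

    miss = spec._missingness_vector()
    missing_mask = rng.random((n, f)) < miss[None, :]
    domain_global = ~missing_mask
    local_index = np.where(
        missing_mask,
        rng.uniform(0.0, 0.39, size=(n, f)),
        rng.uniform(0.4, 1.0, size=(n, f)),
    )

    values = pd.DataFrame(X, index=pd.Index(ids, name="DTXSID"), columns=names)
    kinds = {
        name: ("binary" if j in spec.binary_features else "continuous")
        for j, name in enumerate(names)
    }
    table = FeatureTable(
        values=values,
        domain_global=pd.DataFrame(domain_global, index=values.index,
                                   columns=names),
        domain_local_index=pd.DataFrame(local_index, index=values.index,
                                        columns=names),
        feature_kind=kinds,
    )

    pods = PODDataset(
        spec.effect_category,
        pd.DataFrame(
            {
                "log10_pod": y,
                "study_count": rng.integers(1, 21, size=n),
            },
            index=values.index.copy(),
        ),
    )
    return table, pods


def generate_exposure_table(
    chemical_ids: Sequence[str],
    exposure_gsd: float = 16.0,
    seed: int = 0,
    median_log10_mean: float = -6.0,
    median_log10_sd: float = 1.5,
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0),
) -> ExposureTable:
    """Draw per-chemical exposure percentiles, mg/(kg-d).

    The median (p50) exposure is lognormal across chemicals; the p5 and
    p95 are the median divided/multiplied by ``exposure_gsd**1.645``, so
    the p95/p5 ratio is ``exposure_gsd**(2*1.645)``. ``exposure_gsd=1``
    collapses the interval.
    """
    if exposure_gsd < 1:
        raise InvalidInputError("exposure_gsd must be >= 1")
    rng = np.random.default_rng(seed)
    ids = list(chemical_ids)
    median = 10.0 ** rng.normal(median_log10_mean, median_log10_sd, size=len(ids))
    data = pd.DataFrame(index=pd.Index(ids, name="DTXSID"))
    for p in sorted(percentiles):
        z = (p - 50.0) / 45.0 * _Z95  # linear in z between p5/p50/p95 anchors
        data[float(p)] = median * exposure_gsd ** z
    return ExposureTable(data)
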