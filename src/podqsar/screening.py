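"""Risk layer: prediction intervals, margins of exposure, reference doses.

A predicted POD carries model uncertainty summarised by the
cross-validated RMSE in log10 units. Treating prediction errors as
log10-normal, a two-sided interval at coverage c is
``10**(log10_pod ± z·RMSE)`` with ``z`` the standard-normal quantile at
``(1+c)/2`` (1.645 for 90%). The same RMSE converts to a fold-scale
geometric-standard-deviation error ``10**RMSE`` and a squared GSD
``10**(2·RMSE)``.

The margin of exposure (MOE) is POD divided by estimated exposure, both
in mg/(kg-d); screening concern categories at the median population
exposure are: low (MOE > 100), moderate (1 < MOE <= 100), high
(0 < MOE <= 1). A reference dose divides a POD by the product of
uncertainty factors for animal-to-human extrapolation (UF_A), human
variability (UF_H) and database inadequacy (UF_D).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
from scipy import stats

from .ingest import ExposureTable, InvalidInputError

#: MOE above which a chemical is of low concern at the median exposure.
MOE_LOW_THRESHOLD = 100.0
#: MOE at or below which a chemical is of high concern.
MOE_HIGH_THRESHOLD = 1.0

DEFAULT_COVERAGE = 0.90


def round_sigfigs(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (display helper)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def _z(coverage: float) -> float:
    if not 0.0 < coverage < 1.0:
        raise InvalidInputError("coverage must be in (0, 1)")
    return float(stats.norm.ppf((1.0 + coverage) / 2.0))


def prediction_interval(
    log10_pod_central: float, rmse: float, coverage: float = DEFAULT_COVERAGE
) -> tuple[float, float]:
    """Two-sided prediction interval for a POD, on the dose scale.

    Bounds are ``10**(log10_pod_central ∓ z·rmse)`` in mg/(kg-d), with
    ``z`` the standard-normal quantile at ``(1+coverage)/2`` — symmetric
    about the central value on the log10 scale.
    """
    if rmse < 0:
        raise InvalidInputError("rmse must be >= 0")
    z = _z(coverage)
    return (
        10.0 ** (log10_pod_central - z * rmse),
        10.0 ** (log10_pod_central + z * rmse),
    )


def fold_error(rmse: float) -> float:
    """Fold-scale geometric-standard-deviation error, ``10**rmse``."""
    if rmse < 0:
        raise InvalidInputError("rmse must be >= 0")
    return 10.0 ** rmse


def gsd_squared(rmse: float) -> float:
    """Squared geometric standard deviation, ``10**(2·rmse)``."""
    if rmse < 0:
        raise InvalidInputError("rmse must be >= 0")
    return 10.0 ** (2.0 * rmse)


def fold_interval_halfwidth(rmse: float, coverage: float = 0.95) -> float:
    """Fold half-width of a two-sided interval: ``10**(z·rmse)``.

    E.g. at 95% coverage an RMSE of 0.54 corresponds to an interval
    spanning ~11-fold in each direction.
    """
    if rmse < 0:
        raise InvalidInputError("rmse must be >= 0")
    return 10.0 ** (_z(coverage) * rmse)


@dataclasses.dataclass
class PODPrediction:
    """A central predicted POD with its RMSE-derived prediction interval.

    ``log10_pod_central`` is the model prediction in log10 mg/(kg-d);
    ``rmse`` the model-level cross-validated RMSE attached for interval
    construction; ``pi_lower``/``pi_upper`` the dose-scale bounds.
    """

    chemical_id: str
    log10_pod_central: float
    rmse: float
    coverage: float = DEFAULT_COVERAGE
    pi_lower: float = dataclasses.field(init=False)
    pi_upper: float = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        self.pi_lower, self.pi_upper = prediction_interval(
            self.log10_pod_central, self.rmse, self.coverage
        )

    @property
    def pod_central(self) -> float:
        """Central POD on the dose scale, mg/(kg-d)."""
        return 10.0 ** self.log10_pod_central


def margin_of_exposure(pod: float, exposure: float) -> float:
    """MOE = POD / exposure, both in mg/(kg-d); larger is safer."""
    if pod <= 0 or exposure <= 0:
        raise InvalidInputError("pod and exposure must be positive")
    return pod / exposure


def categorize_moe(moe: float) -> str:
    """Concern category at the median population exposure.

    ``low`` iff MOE > 100, ``moderate`` iff 1 < MOE <= 100, ``high`` iff
    0 < MOE <= 1; both boundaries belong to the more concerning side.
    """
    if moe <= 0:
        raise InvalidInputError("moe must be positive")
    if moe > MOE_LOW_THRESHOLD:
        return "low"
    if moe > MOE_HIGH_THRESHOLD:
        return "moderate"
    return "high"


def moe_uncertainty_grid(
    pred: PODPrediction, percentile_doses: Mapping[float, float]
) -> dict[tuple[float, str], float]:
    """MOE at every exposure percentile x POD bound (lower/central/upper).

    The most conservative cell is the lower POD bound divided by the
    highest exposure percentile. MOE is antitone in exposure percentile
    for a fixed POD bound.
    """
    if not percentile_doses:
        raise InvalidInputError("exposure percentiles must be nonempty")
    bounds = {
        "lower": pred.pi_lower,
        "central": pred.pod_central,
        "upper": pred.pi_upper,
    }
    return {
        (float(p), name): margin_of_exposure(pod, dose)
        for p, dose in percentile_doses.items()
        for name, pod in bounds.items()
    }


@dataclasses.dataclass
class MOEAssessment:
    """Margin-of-exposure assessment for one chemical.

    ``moe_central`` divides the central POD by the median (50th
    percentile, or closest available) exposure; ``category`` applies the
    concern rule to it; ``moe_grid`` spans exposure percentiles x POD
    prediction-interval bounds.
    """

    chemical_id: str
    moe_central: float
    category: str
    moe_grid: dict[tuple[float, str], float]

    @classmethod
    def from_prediction(
        cls, pred: PODPrediction, percentile_doses: Mapping[float, float]
    ) -> "MOEAssessment":
        grid = moe_uncertainty_grid(pred, percentile_doses)
        pcts = sorted(float(p) for p in percentile_doses)
        median_p = min(pcts, key=lambda p: abs(p - 50.0))
        moe_central = margin_of_exposure(
            pred.pod_central, percentile_doses[median_p]
        )
        return cls(
            chemical_id=pred.chemical_id,
            moe_central=moe_central,
            category=categorize_moe(moe_central),
            moe_grid=grid,
        )

    @property
    def conservative_moe(self) -> float:
        """Lower POD bound over the highest exposure percentile."""
        top = max(p for p, _ in self.moe_grid)
        return self.moe_grid[(top, "lower")]


@dataclasses.dataclass
class RfDDerivation:
    """A reference dose derived from a POD and uncertainty factors.

    ``rfd = pod / (uf_a * uf_h * uf_d)`` exactly; ``display`` rounds to
    one significant figure as toxicity values are conventionally
    reported.
    """

    pod: float
    uf_a: float
    uf_h: float
    uf_d: float
    rfd: float = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        for name in ("pod", "uf_a", "uf_h", "uf_d"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        self.rfd = self.pod / (self.uf_a * self.uf_h * self.uf_d)

    @property
    def display(self) -> float:
        return round_sigfigs(self.rfd, 1)


def derive_rfd(pod: float, uf_a: float, uf_h: float, uf_d: float) -> RfDDerivation:
    """Reference dose = POD / (UF_A · UF_H · UF_D), all in mg/(kg-d)."""
    return RfDDerivation(pod=pod, uf_a=uf_a, uf_h=uf_h, uf_d=uf_d)


def screen_chemicals(
    log10_pods: Mapping[str, float],
    exposures: ExposureTable,
    rmse: float,
    coverage: float = DEFAULT_COVERAGE,
    fully_imputed: tuple[str, ...] = (),
):
    """Assemble the per-chemical screening table.

    Returns ``(frame, assessments, missing_exposure_ids)``: a pandas
    DataFrame (one row per screened chemical: POD, interval bounds, MOE
    grid cells, category), the :class:`MOEAssessment` objects, and the
    IDs lacking an exposure row (reported, never silently dropped).
    """
    import pandas as pd

    if len(exposures) == 0:
        raise InvalidInputError("exposure table is empty")
    rows = []
    assessments: list[MOEAssessment] = []
    missing: list[str] = []
    for cid, log10_pod in log10_pods.items():
        if cid not in exposures.data.index:
            missing.append(cid)
            continue
        pred = PODPrediction(cid, float(log10_pod), rmse, coverage)
        doses = exposures.percentile_doses(cid)
        assess = MOEAssessment.from_prediction(pred, doses)
        assessments.append(assess)
        row = {
            "chemical_id": cid,
            "log10_pod_central": pred.log10_pod_central,
            "pod_central": pred.pod_central,
            "pi_lower": pred.pi_lower,
            "pi_upper": pred.pi_upper,
            "moe_central": assess.moe_central,
            "conservative_moe": assess.conservative_moe,
            "category": assess.category,
            "all_features_imputed": cid in fully_imputed,
        }
        for p in sorted(doses):
            row[f"exposure_p{p:g}"] = doses[p]
        for (p, bound), moe in sorted(assess.moe_grid.items()):
            row[f"moe_p{p:g}_{bound}"] = moe
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame, assessments, missing


def category_counts(assessments) -> dict[str, int]:
    """Count screened chemicals per concern category."""
    counts = {"low": 0, "moderate": 0, "high": 0}
    for a in assessments:
        counts[a.category] += 1
    return counts
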