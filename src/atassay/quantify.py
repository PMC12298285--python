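"""Calibration, inverse prediction of antithrombin activity, and
method-validation statistics.

The chromogenic anti-Xa assay leaves residual factor Xa in inverse
proportion to antithrombin (AT) activity, so the color-formation rate
dA/min falls linearly as activity rises.  A calibration line

    rate = intercept + slope * activity_fraction        (slope < 0)

is fitted by ordinary least squares on calibrator levels (activity as a
fraction, 1.0 = 100% of normal), and unknowns are quantified by classical
calibration — algebraic inversion of the fitted line, not inverse
regression.

Validation statistics mirror standard clinical method-verification
practice: repeatability as CV% with a <=10% acceptance bound, linearity
as R^2 against a 0.985 bound, agreement with a reference instrument as
per-sample relative differences, and distributional consistency between
clinical results and calibrators as a two-sample Kolmogorov–Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DomainError,
    IllConditionedCalibrationError,
    InsufficientDataError,
    InvalidConfigError,
    RankDeficiencyError,
    UndefinedCVError,
)

#: Default linearity acceptance bound on R^2.
R2_ACCEPTANCE = 0.985
#: Default repeatability acceptance bound on CV, percent.
CV_ACCEPTANCE_PERCENT = 10.0
#: Minimum |slope| for a usable inverse prediction, AU/min per fraction.
MIN_ABS_SLOPE = 1e-12


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (display convention for percents)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line rate = intercept + slope * activity_fraction.

    ``passes_linearity`` records whether R^2 met the acceptance bound at
    fit time; the bound itself is stored so serialized curves are
    self-describing.
    """

    intercept: float
    slope: float
    r_squared: float
    pearson_r: float
    n_points: int
    passes_linearity: bool
    sample_type: str = "plasma"
    r2_bound: float = R2_ACCEPTANCE
    slope_se: float = float("nan")
    intercept_se: float = float("nan")
    calibration_id: str = ""

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise InvalidConfigError("r_squared must lie in [0, 1]")
        if not -1 - 1e-9 <= self.pearson_r <= 1 + 1e-9:
            raise InvalidConfigError("pearson_r must lie in [-1, 1]")
        if self.n_points < 2:
            raise InvalidConfigError("n_points must be >= 2")

    def predict(self, activity_fraction: float) -> float:
        """Forward model: expected dA/min at a given activity fraction."""
        return self.intercept + self.slope * activity_fraction


@dataclass(frozen=True)
class ActivityResult:
    """An inverse-predicted activity with its provenance."""

    rate_per_min: float
    activity_fraction: float
    dilution_factor: float = 1.0
    calibration_id: str = ""

    @property
    def activity_percent(self) -> float:
        return 100.0 * self.activity_fraction


@dataclass(frozen=True)
class RepeatabilityReport:
    """Replicate-set repeatability: CV% against the acceptance bound."""

    mean: float
    sd: float
    cv_percent: float
    cv_bound_percent: float
    passes: bool
    n: int


@dataclass(frozen=True)
class SampleComparison:
    """One sample's reference-vs-test record."""

    sample_id: str
    reference_percent: float
    test_percent: float
    relative_difference_percent: float
    relative_difference_rounded: float


@dataclass(frozen=True)
class ComparisonReport:
    """Per-sample relative differences plus a KS consistency test."""

    samples: tuple[SampleComparison, ...]
    ks_statistic: float
    ks_p_value: float


@dataclass(frozen=True)
class DilutionPlan:
    """Prescribed sample preparation for one sample type."""

    sample_type: str
    sample_parts: float
    diluent_parts: float
    on_chip: bool
    dilution_factor: float
    note: str = ""


def fit_calibration(
    activities: Sequence[float],
    rates: Sequence[float],
    sample_type: str = "plasma",
    r2_bound: float = R2_ACCEPTANCE,
    calibration_id: str = "",
) -> CalibrationCurve:
    """OLS fit of dA/min on activity fraction.

    Activities are fractions of the 100% calibrator.  Raises
    :class:`RankDeficiencyError` when all activities coincide.
    """
    x = np.asarray(activities, dtype=float)
    y = np.asarray(rates, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise InvalidConfigError("activities and rates must be equal-length 1-D")
    if len(x) < 2:
        raise InsufficientDataError("need at least 2 calibration points")
    if np.ptp(x) == 0:
        raise RankDeficiencyError("all activities identical; line not identifiable")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue) ** 2
    return CalibrationCurve(
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        r_squared=r2,
        pearson_r=float(fit.rvalue),
        n_points=len(x),
        passes_linearity=r2 >= r2_bound,
        sample_type=sample_type,
        r2_bound=r2_bound,
        slope_se=float(fit.stderr),
        intercept_se=float(fit.intercept_stderr),
        calibration_id=calibration_id,
    )


def invert_calibration(
    curve: CalibrationCurve,
    rate_per_min: float,
    dilution_factor: float = 1.0,
) -> ActivityResult:
    """Classical-calibration inverse: activity = (rate - intercept)/slope.

    Activity is a quantity *relative to the calibrator measured under the
    same preparation*, so no dilution back-correction is applied; the
    dilution factor is carried along for provenance only.
    """
    if abs(curve.slope) < MIN_ABS_SLOPE:
        raise IllConditionedCalibrationError(
            f"|slope| = {abs(curve.slope):g} too small for inverse prediction"
        )
    a = (rate_per_min - curve.intercept) / curve.slope
    return ActivityResult(
        rate_per_min=rate_per_min,
        activity_fraction=float(a),
        dilution_factor=dilution_factor,
        calibration_id=curve.calibration_id,
    )


def repeatability(
    values: Sequence[float], cv_bound_percent: float = CV_ACCEPTANCE_PERCENT
) -> RepeatabilityReport:
    """CV (%) = 100 * SD / mean over a replicate set; passes iff <= bound."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise InsufficientDataError("need at least 2 replicates for a CV")
    mean = float(np.mean(v))
    if mean == 0:
        raise UndefinedCVError("CV undefined for zero mean")
    sd = float(np.std(v, ddof=1))
    cv = 100.0 * sd / abs(mean)
    return RepeatabilityReport(
        mean=mean,
        sd=sd,
        cv_percent=cv,
        cv_bound_percent=cv_bound_percent,
        passes=cv <= cv_bound_percent,
        n=len(v),
    )


def relative_difference(
    reference_percent: float, test_percent: float
) -> tuple[float, float]:
    """Percent relative difference versus the reference instrument.

    Returns ``(raw, rounded)`` where raw = 100*|ref - test|/ref and
    rounded is the half-up one-decimal display value.
    """
    if reference_percent <= 0:
        raise DomainError("reference value must be positive")
    raw = 100.0 * abs(reference_percent - test_percent) / reference_percent
    return raw, round_half_up(raw, 1)


def ks_consistency(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov statistic and asymptotic p-value.

    D = sup_x |ECDF_a(x) - ECDF_b(x)|; a large p indicates the two result
    sets (e.g. clinical samples vs calibrators) are distributionally
    consistent.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InsufficientDataError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def compare_results(
    sample_ids: Sequence[str],
    reference_percent: Sequence[float],
    test_percent: Sequence[float],
) -> ComparisonReport:
    """Bundle per-sample relative differences with the KS consistency test."""
    if not (len(sample_ids) == len(reference_percent) == len(test_percent)):
        raise InvalidConfigError("comparison columns must have equal length")
    records = []
    for sid, ref, test in zip(sample_ids, reference_percent, test_percent):
        raw, rounded = relative_difference(float(ref), float(test))
        records.append(
            SampleComparison(
                sample_id=str(sid),
                reference_percent=float(ref),
                test_percent=float(test),
                relative_difference_percent=raw,
                relative_difference_rounded=rounded,
            )
        )
    d, p = ks_consistency(reference_percent, test_percent)
    return ComparisonReport(samples=tuple(records), ks_statistic=d, ks_p_value=p)


def apply_dilution_plan(
    sample_type: str, dilution_factor: Optional[float] = None
) -> DilutionPlan:
    """Prescribed preparation per sample type.

    Plasma and reconstituted calibrators are pre-diluted off-chip (8 uL
    supernatant into 320 uL factor diluent); whole venous and capillary
    blood are diluted on-chip 1 part sample + 9 parts diluent (factor 10)
    to suppress hemoglobin background.  Activity is always read against a
    calibration built under the same preparation, so no post-hoc
    back-correction of the dilution is recorded.
    """
    if sample_type in ("plasma", "calibrator"):
        plan = DilutionPlan(
            sample_type=sample_type,
            sample_parts=8.0,
            diluent_parts=320.0,
            on_chip=False,
            dilution_factor=(8.0 + 320.0) / 8.0,
            note="off-chip pre-dilution: 8 uL sample + 320 uL factor diluent",
        )
    elif sample_type in ("venous_whole_blood", "capillary"):
        factor = 10.0 if dilution_factor is None else float(dilution_factor)
        if factor < 1:
            raise DomainError("dilution_factor must be >= 1")
        plan = DilutionPlan(
            sample_type=sample_type,
            sample_parts=1.0,
            diluent_parts=factor - 1.0,
            on_chip=True,
            dilution_factor=factor,
            note="on-chip dilution: 1 part blood + "
            f"{factor - 1:g} parts factor diluent",
        )
    else:
        raise InvalidConfigError(f"no dilution plan for sample type {sample_type!r}")
    return plan
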