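"""Observed LDL-C response and the achieved percentage of expected reduction.

Given pre- and post-treatment LDL-C the observed percent reduction is

    delta% = 100 * (pre - post) / pre

and the primary response variable normalises it by the regimen-specific
expected reduction E (see :mod:`fhresponse.regimen`):

    P = 100 * delta% / E

P may exceed 100 (the regimen out-performed expectation) or be negative
(LDL-C rose); neither is clipped.  Target attainment is the strict
threshold LDL-C < 70 mg/dL.  All computation is full precision; rounding
(half away from zero, one decimal for percentages) happens only at report
boundaries via :func:`round_half_away`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .errors import InvalidBaselineError, InvalidExpectationError
from .regimen import ExpectedReductionTable

TARGET_LDL_MG_DL = 70.0


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (e.g. 76.55 -> 76.6, -0.25 -> -0.3).

    Python's built-in ``round`` uses banker's rounding; clinical tables round
    half away from zero, so reported percentages go through this helper.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LipidPanel:
    """Pre/post LDL-C pair in mg/dL; pre must be positive and both finite."""

    pre_ldl: float
    post_ldl: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.pre_ldl) and math.isfinite(self.post_ldl)):
            raise InvalidBaselineError("LDL-C values must be finite")
        if self.pre_ldl <= 0:
            raise InvalidBaselineError(f"pre-treatment LDL-C must be > 0, got {self.pre_ldl}")
        if self.post_ldl < 0:
            raise InvalidBaselineError(f"post-treatment LDL-C must be >= 0, got {self.post_ldl}")


@dataclass(frozen=True)
class ResponseRecord:
    """Per-patient response: observed reduction, achieved % of expected, target flag."""

    delta_pct: float
    achieved_pct: float
    target_met: bool
    expected_pct: float


def percent_reduction(panel: LipidPanel) -> float:
    """Observed percent LDL-C reduction, 100*(pre-post)/pre, full precision."""
    return 100.0 * (panel.pre_ldl - panel.post_ldl) / panel.pre_ldl


def achieved_pct_of_expected(delta_pct: float, expected: float) -> float:
    """Primary variable P = 100 * delta% / E; E must be a positive percent."""
    if not expected > 0:
        raise InvalidExpectationError(f"expected reduction must be > 0, got {expected}")
    return 100.0 * delta_pct / expected


def target_attainment(post_ldl: float) -> bool:
    """True iff post-treatment LDL-C is strictly below 70 mg/dL."""
    return post_ldl < TARGET_LDL_MG_DL


def response_record(panel: LipidPanel, expected: float) -> ResponseRecord:
    """Full response record against a known expected reduction E."""
    delta = percent_reduction(panel)
    return ResponseRecord(
        delta_pct=delta,
        achieved_pct=achieved_pct_of_expected(delta, expected),
        target_met=target_attainment(panel.post_ldl),
        expected_pct=float(expected),
    )


def evolocumab_response(
    pre_evolocumab: LipidPanel, table: ExpectedReductionTable | None = None
) -> ResponseRecord:
    """Response to the evolocumab add-on, normalised by the add-on expectation.

    The baseline here is the LDL-C on the background statin/ezetimibe
    regimen immediately before evolocumab was started; the default add-on
    expectation is 54%.
    """
    table = table or ExpectedReductionTable()
    return response_record(pre_evolocumab, table.expected_reduction_addon(True))
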