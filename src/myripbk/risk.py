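"""Margin-of-exposure arithmetic and cross-model comparison ratios.

The margin of exposure (MOE) is a benchmark dose lower bound (BMDL10)
divided by the estimated daily intake; values below 10,000 flag the
compound as a priority for risk management.  For the read-across the
comparison API is deliberately generic: any two simulation results (any
species or compound parameterization) can be compared on the same
metric at the same dose.  A reference model for the structural analogue
used in the published read-across is not bundled; its parameter file
can be supplied like any other species/compound configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import UndefinedQuantityError

__all__ = [
    "ExposureScenario",
    "MOEResult",
    "margin_of_exposure",
    "ComparisonSpec",
    "fold_ratio",
    "MOE_PRIORITY_THRESHOLD",
]

MOE_PRIORITY_THRESHOLD = 10_000


@dataclass(frozen=True)
class ExposureScenario:
    """BMDL10 range and estimated daily intake, both in mg/kg bw/day."""

    compound: str
    bmdl10_low: float
    bmdl10_high: float
    daily_intake: float

    def __post_init__(self):
        if self.bmdl10_low <= 0 or self.bmdl10_high <= 0 or self.daily_intake < 0:
            raise ValueError("BMDL10 values must be positive, intake non-negative")
        if self.bmdl10_low > self.bmdl10_high:
            raise ValueError("BMDL10 lower bound exceeds upper bound")


@dataclass(frozen=True)
class MOEResult:
    compound: str
    low: int
    high: int
    priority_for_risk_management: bool

    def __str__(self):
        flag = " (priority for risk management)" if self.priority_for_risk_management else ""
        return f"MOE for {self.compound}: {self.low}-{self.high}{flag}"


def margin_of_exposure(scenario: ExposureScenario) -> MOEResult:
    """MOE range = BMDL10 / intake, floored to integers for reporting.

    Flooring matches the convention of reporting e.g. 5.1/0.0019 as 2684.
    """
    if scenario.daily_intake == 0:
        raise UndefinedQuantityError("daily intake is zero; MOE undefined")
    # tiny epsilon so that exact ratios (1.9/0.001 = 1900) are not pushed
    # below the integer by floating-point rounding
    low = math.floor(scenario.bmdl10_low / scenario.daily_intake + 1e-9)
    high = math.floor(scenario.bmdl10_high / scenario.daily_intake + 1e-9)
    return MOEResult(
        compound=scenario.compound,
        low=low,
        high=high,
        priority_for_risk_management=low < MOE_PRIORITY_THRESHOLD,
    )


@dataclass
class ComparisonSpec:
    """Two simulation results compared on one metabolite and metric."""

    result_a: object
    result_b: object
    metabolite_id: str
    metric: str = "nmol_per_g_liver"  # or "percent_of_dose"
    at_time_h: float = 720.0

    def __post_init__(self):
        if self.metric not in ("nmol_per_g_liver", "percent_of_dose"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.result_a.dose_mg_per_kg != self.result_b.dose_mg_per_kg:
            raise ValueError("comparison requires the same dose on both sides")

    def _value(self, result) -> float:
        if self.metric == "percent_of_dose":
            return result.percent_of_dose(self.metabolite_id, self.at_time_h)
        return result.amount_per_g_liver(self.metabolite_id, self.at_time_h)


def fold_ratio(comparison: ComparisonSpec) -> float:
    """metric(A) / metric(B) for the shared metabolite, dose and time."""
    denom = comparison._value(comparison.result_b)
    if denom == 0:
        raise UndefinedQuantityError("comparison denominator is zero")
    return comparison._value(comparison.result_a) / denom
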