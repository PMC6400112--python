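"""Per-scan cost model, screening demand, scanner fleets, radiation risk.

Capacity planning for a population screening programme: how much one
PET/MRI examination costs when capital is depreciated over a scanner's
throughput, how many people must be screened each year (annual incidence,
halved to the lifestyle-attributable fraction, times ``1/p`` scans per
future case), how many scanners that requires, the radiation detriment of
screening under the linear no-threshold model, and the vendor-side revenue
case for a dedicated brain PET insert.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from ._util import round_half_up, truncate

__all__ = [
    "ScanCostParams",
    "ScanCostBreakdown",
    "DemandParams",
    "RadiationParams",
    "BusinessCase",
    "BusinessCaseResult",
    "scan_cost_per_procedure",
    "buffer_infrastructure_value",
    "screening_demand",
    "scanner_fleet",
    "radiation_risk",
    "business_case",
    "capacity_table",
]


@dataclass(frozen=True)
class ScanCostParams:
    """Cost components of one screening examination (CAD).

    Defaults: $500 probe per session, $4.3M capital (a $1.3M brain PET
    insert in a $3M 3T MRI) depreciated straight-line over 10 years with a
    10%/yr service contract, $100 operating and $250 interpretation per
    exam, 3,000 exams per scanner-year.  ``buffer`` is an optional per-exam
    allowance for unspecified infrastructure costs.
    """

    probe_cost_per_session: float = 500.0
    equipment_capital: float = 4_300_000.0
    depreciation_years: float = 10.0
    service_fraction: float = 0.10
    operating_cost: float = 100.0
    interpretation_cost: float = 250.0
    throughput: float = 3_000.0
    buffer: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "probe_cost_per_session",
            "equipment_capital",
            "depreciation_years",
            "service_fraction",
            "operating_cost",
            "interpretation_cost",
            "buffer",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.throughput <= 0:
            raise ValueError(f"throughput must be positive, got {self.throughput}")


@dataclass(frozen=True)
class ScanCostBreakdown:
    probe: float
    depreciation: float
    service: float
    operating: float
    interpretation: float
    buffer: float

    @property
    def total(self) -> float:
        return (
            self.probe
            + self.depreciation
            + self.service
            + self.operating
            + self.interpretation
            + self.buffer
        )

    @property
    def printed(self) -> int:
        """Whole-CAD figure, truncated as the reference breakdown prints it."""
        return int(truncate(self.total))


def scan_cost_per_procedure(params: ScanCostParams) -> ScanCostBreakdown:
    """Per-exam cost: probe + depreciation + service + operating + reading.

    Annual depreciation (capital / depreciation_years) and the annual
    service contract (capital x service_fraction) are each spread over the
    scanner-year throughput.
    """
    per_exam_depreciation = (
        params.equipment_capital / params.depreciation_years / params.throughput
    )
    per_exam_service = (
        params.equipment_capital * params.service_fraction / params.throughput
    )
    return ScanCostBreakdown(
        probe=params.probe_cost_per_session,
        depreciation=per_exam_depreciation,
        service=per_exam_service,
        operating=params.operating_cost,
        interpretation=params.interpretation_cost,
        buffer=params.buffer,
    )


def buffer_infrastructure_value(
    buffer_per_exam: float, throughput: float, years: float
) -> tuple[float, float]:
    """Capitalised value of a per-exam buffer over a scanner's life.

    Returns ``(exact, rounded_to_nearest_million)``.
    """
    if buffer_per_exam < 0 or throughput < 0 or years < 0:
        raise ValueError("all inputs must be non-negative")
    exact = buffer_per_exam * throughput * years
    return exact, round_half_up(exact / 1e6) * 1e6


@dataclass(frozen=True)
class DemandParams:
    """Annual screening demand assumptions.

    ``incidence_per_year`` is the annual incident dementia cases in the
    target age range; half are taken to be lifestyle-attributable
    (``lifestyle_fraction``), and each future case requires ``1/p = 10``
    scans to find (``screening_multiplier``).  ``rescreen_interval_years``
    spreads the screens when negatives are not rescanned annually.
    """

    incidence_per_year: float = 0.0
    lifestyle_fraction: float = 0.5
    screening_multiplier: float = 10.0
    throughput: float = 3_000.0
    rescreen_interval_years: float = 1.0

    def __post_init__(self) -> None:
        if self.incidence_per_year < 0:
            raise ValueError("incidence_per_year must be non-negative")
        if not 0.0 <= self.lifestyle_fraction <= 1.0:
            raise ValueError("lifestyle_fraction must be in [0, 1]")
        if self.screening_multiplier < 1:
            raise ValueError("screening_multiplier must be >= 1")
        if self.throughput <= 0:
            raise ValueError("throughput must be positive")
        if self.rescreen_interval_years < 1:
            raise ValueError("rescreen_interval_years must be >= 1")


def screening_demand(d: DemandParams) -> float:
    """Persons to screen per year under the demand assumptions."""
    return (
        d.incidence_per_year
        * d.lifestyle_fraction
        * d.screening_multiplier
        / d.rescreen_interval_years
    )


def scanner_fleet(screened_per_year: float, throughput: float = 3_000.0) -> int:
    """Scanners needed: screened / throughput, rounded half-up to an integer."""
    if throughput <= 0:
        raise ValueError("throughput must be positive")
    if screened_per_year < 0:
        raise ValueError("screened_per_year must be non-negative")
    return int(round_half_up(screened_per_year / throughput))


@dataclass(frozen=True)
class RadiationParams:
    """Effective dose per exam (Sv) and the LNT risk coefficient (per Sv)."""

    effective_dose: float
    risk_coefficient: float = 6e-2

    def __post_init__(self) -> None:
        if self.effective_dose < 0 or self.risk_coefficient < 0:
            raise ValueError("dose and risk coefficient must be non-negative")


def radiation_risk(r: RadiationParams, per: float = 1_000_000.0) -> float:
    """Induced cancers per ``per`` subjects screened (linear no-threshold)."""
    if per < 0:
        raise ValueError("population size must be non-negative")
    return r.effective_dose * r.risk_coefficient * per


@dataclass(frozen=True)
class BusinessCase:
    """Vendor revenue model for a target scanner fleet."""

    fleet_target: float
    ramp_years: float = 10.0
    product_life_years: float = 10.0
    unit_price: float = 1_000_000.0
    service_fraction: float = 0.10

    def __post_init__(self) -> None:
        for name in ("ramp_years", "product_life_years", "unit_price"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fleet_target < 0 or self.service_fraction < 0:
            raise ValueError("fleet_target and service_fraction must be non-negative")


@dataclass(frozen=True)
class BusinessCaseResult:
    """Exact and presentation-rounded revenue figures.

    ``units_per_year`` is the headline figure (exact units rounded to the
    nearest hundred); the ``*_exact`` fields carry the unrounded
    arithmetic.  Service revenue at maturity assumes every unit in the
    installed base (units/yr x product life) pays the annual service
    fraction of its sale price.
    """

    units_per_year_exact: float
    units_per_year: float
    gross_sales: float
    service_revenue_at_maturity: float
    total_revenue_at_maturity: float
    gross_sales_exact: float
    service_revenue_exact: float
    total_revenue_exact: float


def business_case(b: BusinessCase) -> BusinessCaseResult:
    exact_units = b.fleet_target / b.ramp_years
    presented_units = round_half_up(exact_units / 100.0) * 100.0

    def revenues(units: float) -> tuple[float, float, float]:
        gross = units * b.unit_price
        service = units * b.product_life_years * b.unit_price * b.service_fraction
        return gross, service, gross + service

    gross_p, service_p, total_p = revenues(presented_units)
    gross_e, service_e, total_e = revenues(exact_units)
    return BusinessCaseResult(
        units_per_year_exact=exact_units,
        units_per_year=presented_units,
        gross_sales=gross_p,
        service_revenue_at_maturity=service_p,
        total_revenue_at_maturity=total_p,
        gross_sales_exact=gross_e,
        service_revenue_exact=service_e,
        total_revenue_exact=total_e,
    )


def capacity_table(
    incidence: pd.DataFrame | Sequence[Mapping],
    params: DemandParams = DemandParams(),
) -> pd.DataFrame:
    """Screening-demand and fleet table from regional incidence figures.

    ``incidence`` needs columns ``region``, ``age_range``, ``incidence``
    (annual incident cases, persons).  Returns those columns plus
    ``lifestyle_pool`` (incidence x lifestyle fraction), ``screened``
    (persons/yr) and ``scanners``.
    """
    df = pd.DataFrame(incidence).copy()
    required = {"region", "age_range", "incidence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"incidence table missing columns {sorted(missing)}")
    rows = []
    for _, row in df.iterrows():
        d = replace(params, incidence_per_year=float(row["incidence"]))
        screened = screening_demand(d)
        rows.append(
            {
                "region": row["region"],
                "age_range": row["age_range"],
                "incidence": float(row["incidence"]),
                "lifestyle_pool": float(row["incidence"]) * d.lifestyle_fraction,
                "screened": screened,
                "scanners": scanner_fleet(screened, d.throughput),
            }
        )
    return pd.DataFrame(rows)
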