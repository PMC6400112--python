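"""Reference defaults and headline values in one place.

Every default parameter of the reference screening analysis lives here (or
as the dataclass defaults that mirror these values), together with the
headline results the ``reproduce`` command recomputes and checks.  Keeping
them in a single module avoids literals scattering through the code.

All currency values are CAD unless a name says otherwise.
"""

from __future__ import annotations

from .cost_capacity import BusinessCase, DemandParams, RadiationParams, ScanCostParams
from .decision_model import EconomicParams, TestCharacteristics

__all__ = [
    "default_test",
    "default_economic",
    "default_scan_cost",
    "default_demand",
    "default_business",
    "RADIATION_CURRENT",
    "RADIATION_HEAD_INSERT",
    "HEADLINE",
]


def default_test() -> TestCharacteristics:
    """Se = Sp = 0.9, screened-population prevalence 0.1."""
    return TestCharacteristics(se=0.9, sp=0.9, p=0.1)


def default_economic() -> EconomicParams:
    """WTP $80,000 USD (2011) x1.10 x1.3 CAD/USD; QALY weight 0.348;
    $27,000/yr care savings, $4,800/yr therapy, $2,000 scan, 5-year delay."""
    return EconomicParams()


def default_scan_cost() -> ScanCostParams:
    return ScanCostParams()


def default_demand(incidence_per_year: float = 0.0) -> DemandParams:
    return DemandParams(incidence_per_year=incidence_per_year)


def default_business(fleet_target: float = 5_902.0) -> BusinessCase:
    return BusinessCase(fleet_target=fleet_target)


#: 7 mSv/exam at the LNT coefficient 6e-2 per Sv (whole-body-era dose).
RADIATION_CURRENT = RadiationParams(effective_dose=7e-3)
#: 1 mSv/exam for a high-sensitivity head-only insert.
RADIATION_HEAD_INSERT = RadiationParams(effective_dose=1e-3)


#: Headline values of the reference analysis, on the scale they are quoted.
HEADLINE: dict[str, float] = {
    "expected_value_cad": 23_745.0,  # per screened subject, whole CAD
    "qaly_annual_value_cad": 39_811.2,
    "u_tp_cad": 308_056.0,
    "u_fp_cad": -26_000.0,
    "u_tn_cad": -2_000.0,
    "u_fn_cad": -2_000.0,
    "scan_cost_printed_cad": 1_136.0,  # truncated whole-CAD breakdown
    "buffer_value_cad": 26_000_000.0,  # $864 x 3,000/yr x 10 yr, to $1M
    "net_savings_per_detection_cad": 115_000.0,
    "screened_60_79_three_countries": 11_405_000.0,
    "scanners_total_60_79": 3_801.0,
    "scanners_total_60_plus": 5_902.0,
    "business_units_per_year": 600.0,
    "business_total_revenue_usd": 1.2e9,
    "radiation_cases_per_million_7msv": 420.0,
    "radiation_cases_per_million_1msv": 60.0,
    "world_60plus_growth_pct": 82.8,
    "canada_2020_incidence_prevalence_pct": 20.5,
}

#: Scanner counts per (region, age_range) in the reference capacity table.
SCANNER_CELLS: dict[tuple[str, str], int] = {
    ("Canada", "60-79"): 103,
    ("Canada", "60+"): 218,
    ("USA", "60-79"): 850,
    ("USA", "60+"): 1_742,
    ("China", "60-79"): 2_848,
    ("China", "60+"): 3_942,
}
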