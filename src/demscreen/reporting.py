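"""End-to-end reproduction of the reference analysis' headline numbers.

``reproduce`` recomputes every headline figure from the packaged inputs —
expected value, QALY valuation, utility matrix, per-scan cost, the full
capacity table, radiation risk, net savings, vendor revenue, and the
demographic ratios — and compares each against its reference value at the
printed rounding.  The report is a plain list of checks that serialises to
JSON and a DataFrame, and is fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from typing import Mapping

import pandas as pd

from . import defaults
from ._util import round_half_up
from .cost_capacity import (
    RadiationParams,
    buffer_infrastructure_value,
    business_case,
    capacity_table,
    radiation_risk,
    scan_cost_per_procedure,
)
from .decision_model import (
    build_utility_matrix,
    expected_value,
    net_savings_per_detection,
    qaly_annual_value,
)
from .demographics import incidence_prevalence_ratio, percent_increase
from .io import load_reference_tables, validate_config

__all__ = ["Check", "reproduce", "report_frame", "report_json"]


@dataclass(frozen=True)
class Check:
    name: str
    expected: float
    computed: float
    comparator: str  # e.g. "== (printed rounding)"
    passed: bool


def _eq(name: str, expected: float, computed: float, tol: float = 1e-9) -> Check:
    expected, computed = float(expected), float(computed)
    return Check(
        name=name,
        expected=expected,
        computed=computed,
        comparator="== (printed rounding)",
        passed=bool(abs(computed - expected) <= tol),
    )


def reproduce(config: Mapping | None = None) -> list[Check]:
    """Recompute and check every headline number; see module docstring.

    ``config`` may override any block accepted by
    :func:`demscreen.io.validate_config`; unspecified values keep the
    reference defaults.
    """
    cfg = validate_config(config or {})
    test = replace(defaults.default_test(), **cfg.get("test", {}))
    econ = replace(defaults.default_economic(), **cfg.get("economic", {}))
    scan = replace(defaults.default_scan_cost(), **cfg.get("cost", {}))
    H = defaults.HEADLINE

    checks: list[Check] = []

    # decision model
    checks.append(
        _eq("qaly_annual_value_cad", H["qaly_annual_value_cad"],
            round(qaly_annual_value(econ), 1))
    )
    u = build_utility_matrix(econ)
    checks.append(_eq("u_tp_cad", H["u_tp_cad"], round(u.u_tp, 2)))
    checks.append(_eq("u_fp_cad", H["u_fp_cad"], round(u.u_fp, 2)))
    checks.append(_eq("u_tn_cad", H["u_tn_cad"], round(u.u_tn, 2)))
    checks.append(_eq("u_fn_cad", H["u_fn_cad"], round(u.u_fn, 2)))
    checks.append(
        _eq("expected_value_cad", H["expected_value_cad"],
            round_half_up(expected_value(test, u)))
    )
    checks.append(
        _eq("net_savings_per_detection_cad", H["net_savings_per_detection_cad"],
            net_savings_per_detection(
                annual_care_savings=econ.annual_care_savings,
                delay_years=econ.delay_years,
                scan_cost=econ.scan_cost,
                screens_per_detection=1.0 / test.p,
            ))
    )

    # scan cost + buffer
    breakdown = scan_cost_per_procedure(scan)
    checks.append(
        _eq("scan_cost_printed_cad", H["scan_cost_printed_cad"], breakdown.printed)
    )
    assumed_price = econ.scan_cost
    buffer_per_exam = assumed_price - breakdown.printed
    _, buffer_millions = buffer_infrastructure_value(
        buffer_per_exam, scan.throughput, scan.depreciation_years
    )
    checks.append(_eq("buffer_value_cad", H["buffer_value_cad"], buffer_millions))

    # capacity table from the packaged incidence projections
    tables = load_reference_tables()
    inc2020 = tables["incidence"].query(
        "year == 2020 and region in ('Canada', 'USA', 'China')"
    )
    demand = replace(defaults.default_demand(), **cfg.get("demand", {}))
    cap = capacity_table(inc2020, demand)
    for (region, age_range), expected_cells in defaults.SCANNER_CELLS.items():
        row = cap.query("region == @region and age_range == @age_range").iloc[0]
        checks.append(
            _eq(f"scanners_{region}_{age_range}", expected_cells, row["scanners"])
        )
    totals = cap.groupby("age_range")["scanners"].sum()
    checks.append(
        _eq("scanners_total_60_79", H["scanners_total_60_79"], totals["60-79"])
    )
    checks.append(
        _eq("scanners_total_60_plus", H["scanners_total_60_plus"], totals["60+"])
    )
    screened_60_79 = cap.query("age_range == '60-79'")["screened"].sum()
    checks.append(
        _eq("screened_60_79_three_countries",
            H["screened_60_79_three_countries"], screened_60_79)
    )

    # radiation risk
    rad_hi = replace(defaults.RADIATION_CURRENT, **cfg.get("radiation", {}))
    rad_lo = RadiationParams(
        effective_dose=1e-3, risk_coefficient=rad_hi.risk_coefficient
    )
    checks.append(
        _eq("radiation_cases_per_million_7msv",
            H["radiation_cases_per_million_7msv"], radiation_risk(rad_hi))
    )
    checks.append(
        _eq("radiation_cases_per_million_1msv",
            H["radiation_cases_per_million_1msv"], radiation_risk(rad_lo))
    )

    # business case
    biz_cfg = cfg.get("business", {})
    biz = replace(defaults.default_business(), **biz_cfg) if biz_cfg else (
        defaults.default_business(float(totals["60+"]))
    )
    result = business_case(biz)
    checks.append(
        _eq("business_units_per_year", H["business_units_per_year"],
            result.units_per_year)
    )
    checks.append(
        _eq("business_total_revenue_usd", H["business_total_revenue_usd"],
            result.total_revenue_at_maturity)
    )

    # demographic ratios
    pop = tables["population"]

    def pop_at(region: str, year: int, age_range: str) -> float:
        q = pop.query(
            "region == @region and year == @year and age_range == @age_range"
        )
        return float(q["population"].iloc[0])

    checks.append(
        _eq("world_60plus_growth_pct", H["world_60plus_growth_pct"],
            percent_increase(pop_at("World", 2010, "60+"),
                             pop_at("World", 2030, "60+")))
    )
    prev_ca = tables["prevalence"].query("region == 'Canada' and year == 2020")
    inc_ca = tables["incidence"].query(
        "region == 'Canada' and year == 2020 and age_range == '60+'"
    )
    checks.append(
        _eq("canada_2020_incidence_prevalence_pct",
            H["canada_2020_incidence_prevalence_pct"],
            incidence_prevalence_ratio(float(inc_ca["incidence"].iloc[0]),
                                       float(prev_ca["prevalence"].iloc[0])))
    )
    return checks


def report_frame(checks: list[Check]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(c) for c in checks])
    df["delta"] = df["computed"] - df["expected"]
    return df


def report_json(checks: list[Check]) -> str:
    return json.dumps([asdict(c) for c in checks], indent=2)
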