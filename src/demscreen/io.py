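"""Reading and writing the package's delimited-text formats.

Demographic tables travel as UTF-8 CSV.  Banded populations and rate
schedules use the columns ``region, year, age_lo, age_hi, sex, count`` /
``kind, age_lo, age_hi, sex, rate`` with the literal string ``inf`` as the
open-ended top-band sentinel.  Cohort trajectories are written long-form
(``year, age, sex, non_demented, demented, in_care``).  Configs are YAML
(JSON being a YAML subset is accepted too) with unknown keys rejected.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .delay_scenario import CohortState
from .demographics import AgeBandPopulation, Band, RateSchedule

__all__ = [
    "ConfigError",
    "read_population",
    "write_population",
    "read_schedule",
    "write_schedule",
    "trajectory_to_frame",
    "write_trajectory",
    "load_config",
    "validate_config",
    "load_reference_tables",
]


class ConfigError(ValueError):
    """A configuration file contains unknown or invalid keys."""


def _age_hi_to_text(age_hi: float) -> str:
    return "inf" if math.isinf(age_hi) else str(age_hi)


def write_population(pop: AgeBandPopulation, path: str | Path) -> None:
    rows = [
        {
            "region": pop.region,
            "year": pop.year,
            "age_lo": b.age_lo,
            "age_hi": _age_hi_to_text(b.age_hi),
            "sex": b.sex,
            "count": b.value,
        }
        for b in pop.bands
    ]
    # %.17g guarantees float round-trip through the text format
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_population(path: str | Path) -> AgeBandPopulation:
    df = pd.read_csv(path, float_precision="round_trip")
    regions = df["region"].unique()
    years = df["year"].unique()
    if len(regions) != 1 or len(years) != 1:
        raise ValueError("population CSV must hold one region-year")
    bands = tuple(
        Band(float(r.age_lo), float(r.age_hi), str(r.sex), float(r.count))
        for r in df.itertuples()
    )
    return AgeBandPopulation(str(regions[0]), int(years[0]), bands)


def write_schedule(schedule: RateSchedule, path: str | Path) -> None:
    rows = [
        {
            "kind": schedule.kind,
            "age_lo": e.age_lo,
            "age_hi": _age_hi_to_text(e.age_hi),
            "sex": e.sex,
            "rate": e.value,
        }
        for e in schedule.entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_schedule(path: str | Path) -> RateSchedule:
    df = pd.read_csv(path, float_precision="round_trip")
    kinds = df["kind"].unique()
    if len(kinds) != 1:
        raise ValueError("schedule CSV must hold one kind")
    entries = tuple(
        Band(float(r.age_lo), float(r.age_hi), str(r.sex), float(r.rate))
        for r in df.itertuples()
    )
    return RateSchedule(str(kinds[0]), entries)


def trajectory_to_frame(states: Sequence[CohortState]) -> pd.DataFrame:
    return pd.concat([s.to_frame() for s in states], ignore_index=True)


def write_trajectory(states: Sequence[CohortState], path: str | Path) -> None:
    trajectory_to_frame(states).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration

#: Allowed keys per config block; block names mirror the module surfaces.
CONFIG_SCHEMA: dict[str, set[str]] = {
    "test": {"se", "sp", "p"},
    "economic": {
        "wtp_base",
        "inflation_factor",
        "fx_rate",
        "qaly_weight",
        "delay_years",
        "annual_care_savings",
        "therapy_cost_annual",
        "scan_cost",
        "discount_rate",
        "fn_penalty",
    },
    "cost": {
        "probe_cost_per_session",
        "equipment_capital",
        "depreciation_years",
        "service_fraction",
        "operating_cost",
        "interpretation_cost",
        "throughput",
        "buffer",
    },
    "demand": {
        "incidence_per_year",
        "lifestyle_fraction",
        "screening_multiplier",
        "throughput",
        "rescreen_interval_years",
    },
    "radiation": {"effective_dose", "risk_coefficient"},
    "business": {
        "fleet_target",
        "ramp_years",
        "product_life_years",
        "unit_price",
        "service_fraction",
    },
    "scenario": {
        "delay_years",
        "start_year",
        "end_year",
        "care_fraction",
        "annual_cost_per_case",
    },
    "synthetic": {
        "age_lo",
        "age_hi",
        "band_width",
        "population_shape",
        "pyramid_decline",
        "total_population",
        "incidence_anchor",
        "incidence_doubling_years",
        "incidence_scale",
        "sex_ratio_old_age",
        "crossover_age",
        "mortality_anchor",
        "mortality_doubling_years",
        "dementia_hazard_ratio",
        "start_year",
        "seed",
    },
}


def validate_config(config: Mapping) -> dict:
    """Reject unknown blocks/keys; return the config as a plain dict."""
    out: dict = {}
    for block, values in config.items():
        if block not in CONFIG_SCHEMA:
            raise ConfigError(
                f"unknown config block {block!r}; known: {sorted(CONFIG_SCHEMA)}"
            )
        if not isinstance(values, Mapping):
            raise ConfigError(f"config block {block!r} must be a mapping")
        unknown = set(values) - CONFIG_SCHEMA[block]
        if unknown:
            raise ConfigError(
                f"unknown keys {sorted(unknown)} in config block {block!r}"
            )
        out[block] = dict(values)
    return out


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError("config file must contain a mapping of blocks")
    return validate_config(raw)


# ---------------------------------------------------------------------------
# packaged reference tables


def load_reference_tables() -> dict[str, pd.DataFrame]:
    """Packaged demographic reference tables, counts scaled to persons.

    Keys: ``population`` (region, year, age_range, population),
    ``prevalence`` (region, year, prevalence), ``incidence`` (region, year,
    age_range, incidence).
    """
    out = {}
    pkg = resources.files("demscreen.data")
    spec = {
        "population": ("table1_population.csv", "population_thousands"),
        "prevalence": ("table2_prevalence.csv", "prevalence_thousands"),
        "incidence": ("table3_incidence.csv", "incidence_thousands"),
    }
    for key, (fname, col) in spec.items():
        with resources.as_file(pkg / fname) as p:
            df = pd.read_csv(p)
        df[col.replace("_thousands", "")] = df.pop(col) * 1000.0
        out[key] = df
    return out
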