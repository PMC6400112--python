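"""Age-banded demographic arithmetic for dementia projection.

This module implements the macro-simulation building blocks used throughout
the package: populations held in age bands (optionally by sex), banded rate
schedules (prevalence proportions or incidence per 1,000 person-years), and
the standard operations on them —

* growth factors between two population counts,
* applying a rate schedule to a banded population ("macro-simulation"),
* the at-risk incidence procedure (population minus prevalent cases, times
  the age-specific incidence rate),
* incidence/prevalence ratios,
* exponential ("doubling") incidence schedules, reflecting the empirical
  regularity that dementia incidence roughly doubles with every ~6.3 years
  of age.

Conventions
-----------
Age bands are labelled inclusively on both ends ("60-64" covers ages 60
through 64); internally every band is the half-open interval
``[age_lo, age_hi + 1)``.  Open-ended top bands ("90+") carry
``age_hi = inf`` and are closed at :data:`demscreen._util.AGE_CAP` for any
width-weighted arithmetic.  Counts are stored as plain persons; published
tables quoted in thousands are scaled on load (see :mod:`demscreen.io`).
Rates are assumed uniform within a band, and band intersections are
apportioned linearly in overlap width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._util import AGE_CAP, round_half_up

__all__ = [
    "Band",
    "AgeBandPopulation",
    "RateSchedule",
    "CountTable",
    "CoverageError",
    "growth_factor",
    "percent_increase",
    "apply_rates",
    "apply_rates_by_band",
    "adi_incidence",
    "incidence_prevalence_ratio",
    "doubling_rate",
    "doubling_schedule",
    "parse_age_range",
]

SEXES = ("f", "m", "all")


class CoverageError(ValueError):
    """A rate schedule does not cover a requested population band."""


@dataclass(frozen=True)
class Band:
    """One age band: inclusive ``[age_lo, age_hi]``, a sex label, a value.

    ``value`` is a person count for populations and a rate (per 1,000
    person-years, or a proportion) for schedules.  ``age_hi = inf`` marks an
    open-ended top band.
    """

    age_lo: float
    age_hi: float
    sex: str = "all"
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_lo < 0 or self.age_hi < self.age_lo:
            raise ValueError(f"invalid age band [{self.age_lo}, {self.age_hi}]")
        if self.value < 0:
            raise ValueError(f"negative value {self.value} in band {self}")

    @property
    def open_ended(self) -> bool:
        return math.isinf(self.age_hi)

    def half_open(self) -> tuple[float, float]:
        """Internal half-open interval ``[lo, hi)``; open bands close at AGE_CAP."""
        hi = AGE_CAP if self.open_ended else self.age_hi + 1.0
        return (self.age_lo, hi)

    def width(self) -> float:
        lo, hi = self.half_open()
        return hi - lo

    def contains(self, age: float) -> bool:
        lo, hi = self.half_open()
        return lo <= age < hi


def _sexes_match(schedule_sex: str, lookup_sex: str) -> bool:
    return schedule_sex == lookup_sex or schedule_sex == "all" or lookup_sex == "all"


def _check_band_structure(bands: Sequence[Band], what: str) -> None:
    """Bands with conflicting sex labels must be ascending, non-overlapping.

    Two bands conflict when their sexes match (identical, or one is the
    'all' wildcard); distinct concrete sexes may share age ranges freely.
    """
    for i, b1 in enumerate(bands):
        for b2 in bands[i + 1 :]:
            if not _sexes_match(b1.sex, b2.sex):
                continue
            lo1, hi1 = b1.half_open()
            lo2, hi2 = b2.half_open()
            if min(hi1, hi2) > max(lo1, lo2) + 1e-12:
                raise ValueError(
                    f"{what}: overlapping bands {b1.age_lo}-{b1.age_hi} "
                    f"(sex {b1.sex!r}) and {b2.age_lo}-{b2.age_hi} "
                    f"(sex {b2.sex!r})"
                )


@dataclass(frozen=True)
class AgeBandPopulation:
    """A region-year population held in ordered, non-overlapping age bands."""

    region: str
    year: int
    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        _check_band_structure(self.bands, f"population {self.region}/{self.year}")

    def total(self) -> float:
        return sum(b.value for b in self.bands)

    def sexes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(b.sex for b in self.bands))


@dataclass(frozen=True)
class RateSchedule:
    """Banded rates: prevalence proportions or incidence per 1,000 person-years."""

    kind: str  # "prevalence_proportion" | "incidence_per_1000py"
    entries: tuple[Band, ...]

    KINDS = ("prevalence_proportion", "incidence_per_1000py")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}, got {self.kind!r}")
        object.__setattr__(self, "entries", tuple(self.entries))
        if self.kind == "prevalence_proportion":
            for e in self.entries:
                if e.value > 1.0:
                    raise ValueError(f"prevalence proportion {e.value} > 1 in {e}")
        _check_band_structure(self.entries, f"{self.kind} schedule")

    def age_floor(self, sex: str = "all") -> float:
        ages = [e.age_lo for e in self.entries if _sexes_match(e.sex, sex)]
        if not ages:
            raise CoverageError(f"schedule has no entries for sex {sex!r}")
        return min(ages)

    def _candidates(self, sex: str) -> list[Band]:
        # a sex-'all' lookup must not mix sex-specific entries (they would
        # double-count); sex-specific lookups may fall through to 'all'
        # entries, which construction guarantees do not overlap them
        if sex == "all":
            return [e for e in self.entries if e.sex == "all"]
        return [e for e in self.entries if e.sex in (sex, "all")]

    def rate_at(self, age: float, sex: str = "all") -> float:
        """Rate for a single age; exact-sex entries shadow 'all' entries."""
        hits = [e for e in self._candidates(sex) if e.contains(age)]
        if hits:
            exact = [e for e in hits if e.sex == sex]
            return (exact or hits)[0].value
        raise CoverageError(f"no rate for age {age} (sex {sex!r})")

    def mean_rate(self, age_lo: float, age_hi_excl: float, sex: str = "all") -> float:
        """Width-weighted mean rate over the half-open range ``[lo, hi)``.

        Raises :class:`CoverageError` naming the gap if the range is not
        fully covered for the requested sex.
        """
        if age_hi_excl <= age_lo:
            raise ValueError("empty age range")
        pieces: list[tuple[float, float, float]] = []
        for e in self._candidates(sex):
            lo, hi = e.half_open()
            lo, hi = max(lo, age_lo), min(hi, age_hi_excl)
            if hi > lo:
                pieces.append((lo, hi, e.value))
        pieces.sort()
        covered = 0.0
        cursor = age_lo
        acc = 0.0
        for lo, hi, rate in pieces:
            if lo > cursor + 1e-9:
                raise CoverageError(
                    f"schedule gap over ages [{cursor}, {lo}) for sex {sex!r}"
                )
            take_lo = max(lo, cursor)
            acc += (hi - take_lo) * rate
            covered += hi - take_lo
            cursor = max(cursor, hi)
        if cursor < age_hi_excl - 1e-9:
            raise CoverageError(
                f"schedule gap over ages [{cursor}, {age_hi_excl}) for sex {sex!r}"
            )
        return acc / (age_hi_excl - age_lo)


@dataclass
class CountTable:
    """Expected counts by (year, age-range label) for one region and quantity."""

    region: str
    quantity: str  # "prevalence" | "incidence"
    values: dict = field(default_factory=dict)

    def get(self, year: int, age_range: str = "all") -> float:
        return self.values[(year, age_range)]


def parse_age_range(label: str) -> tuple[float, float]:
    """Map a printed age-range label to a half-open interval.

    ``"60-79"`` -> (60, 80); ``"60+"`` -> (60, AGE_CAP); ``"all"`` -> (0, AGE_CAP).
    """
    label = label.strip()
    if label == "all":
        return (0.0, float(AGE_CAP))
    if label.endswith("+"):
        return (float(label[:-1]), float(AGE_CAP))
    lo, _, hi = label.partition("-")
    if not hi:
        raise ValueError(f"unrecognised age range label {label!r}")
    return (float(lo), float(hi) + 1.0)


# ---------------------------------------------------------------------------
# operations


def growth_factor(start: float, end: float) -> float:
    """Ratio ``end / start`` between two population counts."""
    if start <= 0:
        raise ValueError(f"start population must be positive, got {start}")
    if end < 0:
        raise ValueError(f"end population must be non-negative, got {end}")
    return end / start


def percent_increase(start: float, end: float) -> float:
    """Percent increase, rounded half-up to one decimal (printed convention)."""
    return round_half_up((growth_factor(start, end) - 1.0) * 100.0, 1)


def _rate_scale(kind: str) -> float:
    # prevalence proportions multiply counts directly; incidence rates are
    # per 1,000 person-years over a one-year horizon
    return 1.0 if kind == "prevalence_proportion" else 1e-3


def apply_rates_by_band(
    pop: AgeBandPopulation, rates: RateSchedule
) -> list[tuple[Band, float]]:
    """Per-band expected counts ``count x mean rate`` (incidence: /1,000)."""
    scale = _rate_scale(rates.kind)
    out = []
    for b in pop.bands:
        lo, hi = b.half_open()
        out.append((b, b.value * rates.mean_rate(lo, hi, b.sex) * scale))
    return out


def _aggregate(
    per_band: Iterable[tuple[Band, float]],
    age_ranges: Sequence[str],
) -> dict[str, float]:
    totals = {label: 0.0 for label in age_ranges}
    for band, expected in per_band:
        lo, hi = band.half_open()
        for label in age_ranges:
            rlo, rhi = parse_age_range(label)
            overlap = max(0.0, min(hi, rhi) - max(lo, rlo))
            totals[label] += expected * overlap / (hi - lo)
    return totals


def apply_rates(
    pop: AgeBandPopulation,
    rates: RateSchedule,
    age_ranges: Sequence[str] = ("all",),
) -> CountTable:
    """Apply a rate schedule to a banded population (macro-simulation step).

    Returns expected prevalent cases (prevalence schedules) or expected
    incident cases per year (incidence schedules), aggregated over the
    requested age-range labels.
    """
    quantity = "prevalence" if rates.kind == "prevalence_proportion" else "incidence"
    per_band = apply_rates_by_band(pop, rates)
    totals = _aggregate(per_band, age_ranges)
    return CountTable(
        region=pop.region,
        quantity=quantity,
        values={(pop.year, label): v for label, v in totals.items()},
    )


def adi_incidence(
    pop: AgeBandPopulation,
    prevalent: AgeBandPopulation,
    inc_rates: RateSchedule,
    age_ranges: Sequence[str] = ("all",),
) -> CountTable:
    """At-risk incidence: ``(population - prevalent cases) x incidence rate``.

    ``prevalent`` must carry the same band structure as ``pop`` (matched on
    age bounds and sex) with counts of prevalent cases per band.
    """
    if inc_rates.kind != "incidence_per_1000py":
        raise ValueError("adi_incidence needs an incidence schedule")
    prev_by_key = {(b.age_lo, b.age_hi, b.sex): b.value for b in prevalent.bands}
    at_risk = []
    for b in pop.bands:
        key = (b.age_lo, b.age_hi, b.sex)
        if key not in prev_by_key:
            raise ValueError(f"prevalent counts missing for band {key}")
        p = prev_by_key[key]
        if p > b.value * (1 + 1e-12):
            raise ValueError(
                f"prevalent cases ({p}) exceed population ({b.value}) in band {key}"
            )
        at_risk.append(Band(b.age_lo, b.age_hi, b.sex, max(b.value - p, 0.0)))
    pool = AgeBandPopulation(pop.region, pop.year, tuple(at_risk))
    table = apply_rates(pool, inc_rates, age_ranges)
    table.quantity = "incidence"
    return table


def incidence_prevalence_ratio(incidence: float, prevalence: float) -> float:
    """Annual incidence as a percent of prevalence, half-up to one decimal."""
    if prevalence <= 0:
        raise ValueError(f"prevalence must be positive, got {prevalence}")
    if incidence < 0:
        raise ValueError(f"incidence must be non-negative, got {incidence}")
    return round_half_up(100.0 * incidence / prevalence, 1)


def doubling_rate(
    age: float,
    base_rate: float,
    anchor_age: float,
    doubling_years: float = 6.3,
) -> float:
    """Closed-form exponential rate: doubles every ``doubling_years`` of age."""
    if base_rate <= 0 or doubling_years <= 0:
        raise ValueError("base_rate and doubling_years must be positive")
    return base_rate * 2.0 ** ((age - anchor_age) / doubling_years)


def doubling_schedule(
    base_rate: float,
    anchor_age: float,
    age_lo: float,
    age_hi: float,
    doubling_years: float = 6.3,
    band_width: float = 5.0,
    sex: str = "all",
    open_top: bool = True,
    scale: float = 1.0,
) -> RateSchedule:
    """Banded incidence schedule from the exponential doubling law.

    Each band ``[lo, lo + band_width - 1]`` carries the closed-form rate at
    its midpoint.  With ``open_top`` the last band is open-ended but still
    rated at the midpoint it would have had if closed, so the generated
    schedule is exactly log-linear across band midpoints.
    """
    entries = []
    lo = age_lo
    while lo <= age_hi:
        hi = lo + band_width - 1.0
        last = hi >= age_hi
        mid = lo + (band_width - 1.0) / 2.0
        rate = scale * doubling_rate(mid, base_rate, anchor_age, doubling_years)
        entries.append(Band(lo, math.inf if (last and open_top) else hi, sex, rate))
        lo += band_width
    return RateSchedule("incidence_per_1000py", tuple(entries))


def table_ratios(table: Mapping[str, tuple[float, float]]) -> dict[str, float]:
    """Growth factors (3 decimals, half-up) for ``{row: (start, end)}`` pairs."""
    return {
        row: round_half_up(growth_factor(start, end), 3)
        for row, (start, end) in table.items()
    }
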