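"""Synthetic demographic scenarios for testing the projection machinery.

Generates age-structured populations, age/sex-specific incidence and
mortality schedules, and initial cohort states with the statistical
structure the analysis assumes:

* incidence follows the exponential doubling law through a printed anchor
  (3.9 per 1,000 person-years at ages 60-64, doubling every 6.3 years),
* above a crossover age female incidence exceeds male by a fixed ratio,
  as administrative-data incidence shows at ages over 75,
* all-cause mortality is Gompertz-like (its own doubling time), with an
  elevated hazard for the demented.

A separate preset reproduces the printed sex-specific administrative
incidence anchors exactly (0.110/0.226 per 1,000 F/M at 40-44,
5.547/5.921 at 70-74, 48.040/43.578 at 95+), interpolating log-linearly
between anchor band midpoints.

The default population pyramid declines geometrically with age.  The
default steepness (30% per 5-year band) is deliberately steeper than a
stationary age structure: with entry cohorts closed off and mortality held
constant, the pyramid alone must carry the strong cohort-bulge aging that
drives observed prevalence roughly to double over 20 years.  See the
methods note for what this does and does not emulate.

``calibrate_to_anchors`` tunes only the overall incidence scale and the
dementia hazard ratio so the projected prevalence passes through stated
(year, prevalence) anchors — a deterministic grid + golden-section search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar

from .delay_scenario import (
    DEFAULT_CARE_FRACTION,
    CohortState,
    DelayScenario,
    MortalitySchedule,
    prevalence_series,
    project,
)
from .demographics import AgeBandPopulation, Band, RateSchedule, doubling_schedule

__all__ = [
    "ScenarioSpec",
    "Scenario",
    "CalibrationResult",
    "CalibrationError",
    "generate_scenario",
    "calibrate_to_anchors",
    "sex_specific_incidence_preset",
]

#: Highest single age simulated; the top age is absorbing in the projector.
MAX_AGE = 110


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a synthetic demographic scenario.

    Ages are organised in ``band_width``-year bands from ``age_lo`` through
    ``age_hi`` (the top band open-ended).  ``incidence_scale`` multiplies
    the whole incidence schedule and is one of the two calibration knobs;
    ``dementia_hazard_ratio`` is the other.
    """

    age_lo: int = 40
    age_hi: int = 99
    band_width: int = 5
    population_shape: str = "pyramid"  # "pyramid" | "uniform"
    pyramid_decline: float = 0.30  # per-band decline of the pyramid
    total_population: float = 16_000_000.0  # persons aged 40+, Canada-like
    incidence_anchor: tuple[float, float] = (62.0, 3.9)  # (age, per-1000py)
    incidence_doubling_years: float = 6.3
    incidence_scale: float = 1.0
    sex_ratio_old_age: float = 1.10  # female/male incidence above crossover
    crossover_age: float = 75.0
    mortality_anchor: tuple[float, float] = (60.0, 8.0)
    mortality_doubling_years: float = 8.0
    dementia_hazard_ratio: float = 2.5
    start_year: int = 2011
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_shape not in ("pyramid", "uniform"):
            raise ValueError("population_shape must be 'pyramid' or 'uniform'")
        if not 0.0 <= self.pyramid_decline < 1.0:
            raise ValueError("pyramid_decline must be in [0, 1)")
        if (self.age_hi - self.age_lo + 1) % self.band_width:
            raise ValueError(
                f"ages [{self.age_lo}, {self.age_hi}] do not partition into "
                f"{self.band_width}-year bands"
            )
        for name in ("total_population", "incidence_scale", "sex_ratio_old_age"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.incidence_anchor[1] <= 0 or self.mortality_anchor[1] <= 0:
            raise ValueError("anchor rates must be positive")
        if self.dementia_hazard_ratio < 1.0:
            raise ValueError("dementia_hazard_ratio must be >= 1")

    @property
    def n_bands(self) -> int:
        return (self.age_hi - self.age_lo + 1) // self.band_width


@dataclass(frozen=True)
class Scenario:
    population: AgeBandPopulation
    incidence: RateSchedule
    mortality: MortalitySchedule
    initial: CohortState


def _band_counts(spec: ScenarioSpec) -> np.ndarray:
    if spec.population_shape == "uniform":
        weights = np.ones(spec.n_bands)
    else:
        weights = (1.0 - spec.pyramid_decline) ** np.arange(spec.n_bands)
    return spec.total_population * weights / weights.sum()


def _incidence_schedule(spec: ScenarioSpec) -> RateSchedule:
    """Sex-specific doubling schedule; female rates lifted above crossover."""
    anchor_age, base = spec.incidence_anchor
    entries = []
    for k in range(spec.n_bands):
        lo = spec.age_lo + k * spec.band_width
        hi = math.inf if k == spec.n_bands - 1 else lo + spec.band_width - 1
        mid = lo + (spec.band_width - 1) / 2.0
        rate = (
            spec.incidence_scale
            * base
            * 2.0 ** ((mid - anchor_age) / spec.incidence_doubling_years)
        )
        ratio = spec.sex_ratio_old_age if mid >= spec.crossover_age else 1.0
        entries.append(Band(lo, hi, "f", rate * ratio))
        entries.append(Band(lo, hi, "m", rate))
    return RateSchedule("incidence_per_1000py", tuple(entries))


def _mortality_schedule(spec: ScenarioSpec) -> MortalitySchedule:
    anchor_age, base = spec.mortality_anchor
    sched = doubling_schedule(
        base_rate=base,
        anchor_age=anchor_age,
        age_lo=spec.age_lo,
        age_hi=spec.age_hi,
        doubling_years=spec.mortality_doubling_years,
        band_width=spec.band_width,
    )
    return MortalitySchedule(
        all_cause=sched, dementia_hazard_ratio=spec.dementia_hazard_ratio
    )


def _equilibrium_fraction(
    incidence: RateSchedule,
    mortality: MortalitySchedule,
    ages: np.ndarray,
    sex: str,
) -> np.ndarray:
    """Demented fraction by age from cohort integration of the dynamics.

    Follows one cohort up from the schedule floor with the same
    incidence-then-mortality difference equations the projector uses; the
    result is the stationary-entries (long burn-in) limit of the baseline
    dynamics.
    """
    frac = np.zeros(len(ages))
    nd, dem = 1.0, 0.0
    floor = incidence.age_floor(sex)
    for j, age in enumerate(ages):
        total = nd + dem
        frac[j] = dem / total if total > 0 else 0.0
        q_inc = 0.0 if age < floor else min(incidence.rate_at(age, sex) / 1000.0, 1.0)
        new = nd * q_inc
        nd, dem = nd - new, dem + new
        nd *= 1.0 - mortality.annual_prob(age, sex, demented=False)
        dem *= 1.0 - mortality.annual_prob(age, sex, demented=True)
    return frac


def generate_scenario(spec: ScenarioSpec) -> Scenario:
    """Build population, schedules, and the initial cohort state.

    Fully deterministic given the spec (the seed only matters for
    downstream stochastic projections).  The initial demented counts are
    the quasi-equilibrium of the baseline dynamics; band counts are spread
    uniformly across the single ages of each band and split evenly between
    the sexes.
    """
    counts = _band_counts(spec)
    sexes = ("f", "m")
    bands = []
    for k, c in enumerate(counts):
        lo = spec.age_lo + k * spec.band_width
        hi = math.inf if k == spec.n_bands - 1 else lo + spec.band_width - 1
        for sex in sexes:
            bands.append(Band(lo, hi, sex, c / 2.0))
    population = AgeBandPopulation("synthetic", spec.start_year, tuple(bands))

    incidence = _incidence_schedule(spec)
    mortality = _mortality_schedule(spec)

    ages = np.arange(spec.age_lo, MAX_AGE + 1)
    per_age = np.zeros((len(sexes), len(ages)))
    for k, c in enumerate(counts):
        lo = spec.age_lo + k * spec.band_width
        idx = slice(lo - spec.age_lo, lo - spec.age_lo + spec.band_width)
        per_age[:, idx] = c / 2.0 / spec.band_width

    nd = np.zeros_like(per_age)
    dem = np.zeros_like(per_age)
    for i, sex in enumerate(sexes):
        frac = _equilibrium_fraction(incidence, mortality, ages, sex)
        dem[i] = per_age[i] * frac
        nd[i] = per_age[i] - dem[i]
    initial = CohortState(
        year=spec.start_year,
        ages=ages,
        sexes=sexes,
        non_demented=nd,
        demented=dem,
        in_care=DEFAULT_CARE_FRACTION * dem,
    )
    return Scenario(population, incidence, mortality, initial)


def sex_specific_incidence_preset(
    age_lo: int = 40, age_hi: int = 99, band_width: int = 5
) -> RateSchedule:
    """Sex-specific incidence reproducing printed administrative anchors.

    Exact at the anchor bands (40-44, 70-74, 95+); other band midpoints are
    log-linear interpolations/extrapolations between neighbouring anchors,
    matching the exponential-doubling structure of dementia incidence.
    """
    anchors = {  # band midpoint -> (female, male) per 1,000 person-years
        42.0: (0.110, 0.226),
        72.0: (5.547, 5.921),
        97.0: (48.040, 43.578),
    }
    xs = sorted(anchors)

    def interp(mid: float, sex_idx: int) -> float:
        ys = [math.log(anchors[x][sex_idx]) for x in xs]
        if mid <= xs[0]:
            lo, hi = 0, 1
        elif mid >= xs[-1]:
            lo, hi = len(xs) - 2, len(xs) - 1
        else:
            hi = next(i for i, x in enumerate(xs) if x >= mid)
            lo = hi - 1
        slope = (ys[hi] - ys[lo]) / (xs[hi] - xs[lo])
        return math.exp(ys[lo] + slope * (mid - xs[lo]))

    entries = []
    n_bands = (age_hi - age_lo + 1) // band_width
    for k in range(n_bands):
        lo = age_lo + k * band_width
        hi = math.inf if k == n_bands - 1 else lo + band_width - 1
        mid = lo + (band_width - 1) / 2.0
        entries.append(Band(lo, hi, "f", interp(mid, 0)))
        entries.append(Band(lo, hi, "m", interp(mid, 1)))
    return RateSchedule("incidence_per_1000py", tuple(entries))


# ---------------------------------------------------------------------------
# calibration


class CalibrationError(RuntimeError):
    """Anchors unreachable within the knob bounds; carries the best attempt."""

    def __init__(self, message: str, result: "CalibrationResult"):
        super().__init__(message)
        self.result = result


@dataclass(frozen=True)
class CalibrationResult:
    spec: ScenarioSpec
    residual: float  # max relative anchor error
    achieved: tuple[tuple[int, float], ...]  # (year, projected prevalence)


def _anchor_trajectory(
    spec: ScenarioSpec, anchors: tuple[tuple[int, float], ...]
) -> dict[int, float]:
    end_year = max(y for y, _ in anchors)
    scenario = DelayScenario(
        delay_years=0.0, start_year=spec.start_year, end_year=end_year
    )
    scn = generate_scenario(spec)
    series = prevalence_series(project(scn.initial, scn.incidence, scn.mortality, scenario))
    return {y: float(series.loc[y]) for y, _ in anchors}


def _fit_scale(
    spec: ScenarioSpec,
    anchors: tuple[tuple[int, float], ...],
    max_iter: int = 25,
) -> tuple[ScenarioSpec, float]:
    """Fixed-point fit of the incidence scale (prevalence is ~linear in it)."""
    current = spec
    for _ in range(max_iter):
        achieved = _anchor_trajectory(current, anchors)
        ratios = [target / achieved[y] for y, target in anchors if achieved[y] > 0]
        if not ratios:
            break
        adjust = float(np.exp(np.mean(np.log(ratios))))  # geometric mean
        if abs(adjust - 1.0) < 1e-6:
            break
        current = replace(
            current, incidence_scale=current.incidence_scale * adjust
        )
    achieved = _anchor_trajectory(current, anchors)
    residual = max(abs(achieved[y] - t) / t for y, t in anchors)
    return current, residual


def calibrate_to_anchors(
    spec: ScenarioSpec,
    anchors,
    tol: float = 0.05,
    hr_bounds: tuple[float, float] = (1.0, 8.0),
    hr_grid_points: int = 15,
) -> CalibrationResult:
    """Tune incidence scale and dementia hazard ratio to prevalence anchors.

    ``anchors`` is a sequence of ``(year, prevalence)`` pairs (at least
    two).  The incidence scale sets the overall level; the hazard ratio
    governs case turnover and hence the growth between anchors.  The search
    is deterministic: if the spec already meets the anchors it is returned
    unchanged; otherwise a coarse hazard-ratio grid is refined by
    golden-section, with the scale re-fit at every step.  Raises
    :class:`CalibrationError` (carrying the best attempt) if the residual
    exceeds ``tol``.
    """
    anchors = tuple((int(y), float(v)) for y, v in anchors)
    if len(anchors) < 2:
        raise ValueError("need at least two (year, prevalence) anchors")
    if any(v <= 0 for _, v in anchors):
        raise ValueError("anchor prevalences must be positive")
    if any(y < spec.start_year for y, _ in anchors):
        raise ValueError("anchor years precede the scenario start year")

    # fixed point: the spec's own output needs no calibration
    achieved0 = _anchor_trajectory(spec, anchors)
    res0 = max(abs(achieved0[y] - t) / t for y, t in anchors)
    if res0 < 1e-9:
        return CalibrationResult(spec, res0, tuple(achieved0.items()))

    cache: dict[float, tuple[ScenarioSpec, float]] = {}

    def eval_hr(hr: float) -> float:
        hr = float(np.clip(hr, *hr_bounds))
        key = round(hr, 6)
        if key not in cache:
            cache[key] = _fit_scale(replace(spec, dementia_hazard_ratio=hr), anchors)
        return cache[key][1]

    grid = np.linspace(hr_bounds[0], hr_bounds[1], hr_grid_points)
    residuals = [eval_hr(h) for h in grid]
    i_best = int(np.argmin(residuals))
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, len(grid) - 1)]
    if hi > lo:
        minimize_scalar(
            eval_hr, bounds=(lo, hi), method="bounded", options={"xatol": 1e-3}
        )
    best_key = min(cache, key=lambda k: cache[k][1])
    best_spec, best_res = cache[best_key]
    achieved = tuple(_anchor_trajectory(best_spec, anchors).items())
    result = CalibrationResult(best_spec, best_res, achieved)
    if best_res > tol:
        raise CalibrationError(
            f"best calibration residual {best_res:.3f} exceeds tolerance {tol}",
            result,
        )
    return result
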