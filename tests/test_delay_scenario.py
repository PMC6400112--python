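"""Cohort projection under onset delay: oracle equivalence and invariants."""

from dataclasses import replace

import numpy as np
import pytest

from demscreen.delay_scenario import (
    CohortState,
    DelayScenario,
    MortalitySchedule,
    cost_delta,
    estimate_delay,
    per_person_from_aggregate,
    prevalence_reduction,
    prevalence_series,
    project,
)
from demscreen.demographics import Band, RateSchedule


def make_toy(n_ages=3, age_lo=70, inc_rates=(10.0, 20.0, 40.0),
             mort_rates=(20.0, 40.0, 80.0), hr=2.0, nd0=(1000.0, 800.0, 600.0),
             d0=(50.0, 80.0, 120.0)):
    """Small single-sex cohort with per-age rates, for hand-checkable runs."""
    ages = np.arange(age_lo, age_lo + n_ages)
    inc = RateSchedule(
        "incidence_per_1000py",
        tuple(Band(a, a if i < n_ages - 1 else np.inf, "all", r)
              for i, (a, r) in enumerate(zip(ages, inc_rates))),
    )
    mort = MortalitySchedule(
        RateSchedule(
            "incidence_per_1000py",
            tuple(Band(a, a if i < n_ages - 1 else np.inf, "all", r)
                  for i, (a, r) in enumerate(zip(ages, mort_rates))),
        ),
        dementia_hazard_ratio=hr,
    )
    state = CohortState(
        year=2020, ages=ages, sexes=("all",),
        non_demented=np.array([list(nd0)]), demented=np.array([list(d0)]),
        in_care=np.zeros((1, n_ages)),
    )
    return state, inc, mort


def brute_force_project(state, inc_rates, mort_rates, hr, years, delay=0.0,
                        age_lo=70, care_fraction=261 / 340):
    """Independent difference-equation oracle using plain Python loops.

    Rates are per-age lists indexed from ``age_lo``; the top age is
    absorbing and carries the last listed rate; onset ages shifted below
    the first listed age get rate zero.
    """
    nd = list(state.non_demented[0])
    dem = list(state.demented[0])
    n = len(nd)
    out = [(sum(nd), sum(dem))]
    for _ in range(years):
        new_nd, new_dem = [0.0] * n, [0.0] * n
        for j in range(n):
            age = age_lo + j
            shifted = age - delay
            if shifted < age_lo:
                q_inc = 0.0
            else:
                idx = min(int(shifted) - age_lo, n - 1)
                q_inc = inc_rates[idx] / 1000.0
            q = mort_rates[j] / 1000.0
            onset = nd[j] * q_inc
            nd_j = (nd[j] - onset) * (1 - q)
            dem_j = (dem[j] + onset) * (1 - min(q * hr, 1.0))
            tgt = min(j + 1, n - 1)
            new_nd[tgt] += nd_j
            new_dem[tgt] += dem_j
        nd, dem = new_nd, new_dem
        out.append((sum(nd), sum(dem)))
    return out


def test_zero_delay_identical_to_baseline():
    state, inc, mort = make_toy()
    base = project(state, inc, mort, DelayScenario(0.0, 2020, 2025))
    also = project(state, inc, mort, DelayScenario(0.0, 2020, 2025))
    for a, b in zip(base, also):
        np.testing.assert_array_equal(a.demented, b.demented)
        np.testing.assert_array_equal(a.non_demented, b.non_demented)


@pytest.mark.parametrize("delay", [0.0, 1.0, 2.0])
def test_projection_matches_brute_force_oracle(delay):
    """Expected-count propagation equals an independently coded
    difference-equation evaluation on a 3-age, 5-year toy to 1e-9 relative."""
    inc_rates, mort_rates, hr = (10.0, 20.0, 40.0), (20.0, 40.0, 80.0), 2.0
    state, inc, mort = make_toy(inc_rates=inc_rates, mort_rates=mort_rates, hr=hr)
    states = project(state, inc, mort, DelayScenario(delay, 2020, 2025))
    oracle = brute_force_project(state, inc_rates, mort_rates, hr, 5, delay=delay)
    for s, (nd_tot, dem_tot) in zip(states, oracle):
        assert s.non_demented.sum() == pytest.approx(nd_tot, rel=1e-9)
        assert s.total_prevalence() == pytest.approx(dem_tot, rel=1e-9)


def test_population_conserved_without_mortality():
    state, inc, _ = make_toy()
    no_mort = MortalitySchedule(
        RateSchedule("incidence_per_1000py", (Band(0, np.inf, "all", 0.0),)),
        dementia_hazard_ratio=1.0,
    )
    states = project(state, inc, no_mort, DelayScenario(0.0, 2020, 2030))
    totals = [s.total_population() for s in states]
    assert np.allclose(totals, totals[0], rtol=1e-12)


def test_delayed_prevalence_below_baseline_every_year():
    state, inc, mort = make_toy()
    base = project(state, inc, mort, DelayScenario(0.0, 2020, 2030))
    prev_prev = None
    for d in (0.0, 1.0, 3.0, 5.0):
        traj = project(state, inc, mort, DelayScenario(d, 2020, 2030))
        for b, t in zip(base, traj):
            assert t.total_prevalence() <= b.total_prevalence() + 1e-9
        # larger delays give weakly lower prevalence
        series = prevalence_series(traj)
        if prev_prev is not None:
            assert (series <= prev_prev + 1e-9).all()
        prev_prev = series


def test_demented_never_revert():
    """With no mortality the demented stock is non-decreasing."""
    state, inc, _ = make_toy()
    no_mort = MortalitySchedule(
        RateSchedule("incidence_per_1000py", (Band(0, np.inf, "all", 0.0),)),
        dementia_hazard_ratio=1.0,
    )
    series = prevalence_series(project(state, inc, no_mort,
                                       DelayScenario(0.0, 2020, 2030)))
    assert (series.diff().dropna() >= -1e-9).all()


def test_project_rejects_mismatched_year_and_negative_delay():
    state, inc, mort = make_toy()
    with pytest.raises(ValueError):
        project(state, inc, mort, DelayScenario(0.0, 2019, 2025))
    with pytest.raises(ValueError):
        DelayScenario(-1.0, 2020, 2025)


def test_stochastic_mode_reproducible_and_near_deterministic():
    state, inc, mort = make_toy(nd0=(100_000.0, 80_000.0, 60_000.0),
                                d0=(5_000.0, 8_000.0, 12_000.0))
    sc = DelayScenario(0.0, 2020, 2030)
    a = project(state, inc, mort, sc, stochastic=True, seed=11)
    b = project(state, inc, mort, sc, stochastic=True, seed=11)
    det = project(state, inc, mort, sc)
    for s1, s2 in zip(a, b):
        np.testing.assert_array_equal(s1.demented, s2.demented)
    # with ~10^5 persons the draws track the expectation within a few percent
    assert a[-1].total_prevalence() == pytest.approx(
        det[-1].total_prevalence(), rel=0.05
    )
    with pytest.raises(ValueError, match="seed"):
        project(state, inc, mort, sc, stochastic=True)


# ---------------------------------------------------------------------------
# summary operations


def test_prevalence_reduction_on_printed_counts():
    """674,000 vs 374,000 prevalent gives a 44.5% reduction; the printed
    '45%' figure is the in-care version (522,000 vs 291,000 -> 44.25%)."""
    assert 100 * (674_000 - 374_000) / 674_000 == pytest.approx(44.51, abs=0.01)
    assert 100 * (522_000 - 291_000) / 522_000 == pytest.approx(44.25, abs=0.01)


def test_prevalence_reduction_trajectories():
    state, inc, mort = make_toy()
    base = project(state, inc, mort, DelayScenario(0.0, 2020, 2025))
    same = project(state, inc, mort, DelayScenario(0.0, 2020, 2025))
    assert prevalence_reduction(base, same, 2025) == pytest.approx(0.0)
    delayed = project(state, inc, mort, DelayScenario(5.0, 2020, 2025))
    red = prevalence_reduction(base, delayed, 2025)
    assert 0.0 < red < 100.0
    care_red = prevalence_reduction(base, delayed, 2025, quantity="in_care")
    assert care_red == pytest.approx(red)  # care is proportional to prevalence


def test_prevalence_reduction_total_elimination():
    state, inc, mort = make_toy()
    base = project(state, inc, mort, DelayScenario(0.0, 2020, 2025))
    zero = [s.copy() for s in base]
    for s in zero:
        s.demented = np.zeros_like(s.demented)
        s.in_care = np.zeros_like(s.in_care)
    assert prevalence_reduction(base, zero, 2025) == pytest.approx(100.0)


def test_cost_delta_per_person_and_aggregate_entry():
    state, inc, mort = make_toy()
    base = project(state, inc, mort, DelayScenario(0.0, 2020, 2025))
    delayed = project(state, inc, mort, DelayScenario(5.0, 2020, 2025))
    total, per_person = cost_delta(base, delayed, 27_000.0)
    delta = base[-1].total_prevalence() - delayed[-1].total_prevalence()
    assert total == pytest.approx(delta * 27_000.0)
    assert per_person == 27_000.0
    # printed aggregate arithmetic
    assert per_person_from_aggregate(8e9, 0.0, 300_000.0) == pytest.approx(
        26_666.67, abs=0.01
    )
    assert per_person_from_aggregate(18.2e9, 10.25e9, 300_000.0) == pytest.approx(
        26_500.0
    )


def test_cost_delta_zero_difference_warns():
    state, inc, mort = make_toy()
    base = project(state, inc, mort, DelayScenario(0.0, 2020, 2025))
    with pytest.warns(UserWarning):
        total, per_person = cost_delta(base, base, 27_000.0)
    assert (total, per_person) == (0.0, 0.0)


def test_estimate_delay_recovers_injected_delay_on_toy():
    state, inc, mort = make_toy(nd0=(10_000.0, 8_000.0, 6_000.0),
                                d0=(500.0, 800.0, 1_200.0))
    sc = DelayScenario(0.0, 2020, 2030)
    for true_d in (0, 1, 2):
        observed = project(state, inc, mort, replace(sc, delay_years=true_d))
        assert estimate_delay(observed, state, inc, mort, sc) == true_d
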