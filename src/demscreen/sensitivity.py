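"""Sensitivity analyses over the screening decision model.

One-way sweeps, break-even (threshold) analysis, probabilistic sensitivity
analysis (PSA), and tornado tables, all over the parameter namespace of
:class:`~demscreen.decision_model.EconomicParams` and
:class:`~demscreen.decision_model.TestCharacteristics`.

With zero discounting the expected value E is affine in every cost and
value parameter and in the delay, so thresholds have closed-form roots;
the bisection solver here must (and is tested to) agree with them.  PSA
uses a single seeded random stream with parameter draws consumed in sorted
parameter-name order, so summaries are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .decision_model import (
    EconomicParams,
    TestCharacteristics,
    expected_value_from_params,
)

__all__ = [
    "SweepSpec",
    "DistributionSpec",
    "PSAResult",
    "ThresholdError",
    "PARAMETER_BOUNDS",
    "evaluate",
    "one_way_sweep",
    "threshold",
    "probabilistic_sa",
    "tornado",
]

_TEST_FIELDS = {f.name for f in fields(TestCharacteristics)}
_ECON_FIELDS = {f.name for f in fields(EconomicParams)}

#: Domain bounds per parameter; these double as bisection brackets.
PARAMETER_BOUNDS: dict[str, tuple[float, float]] = {
    "se": (1e-9, 1.0),
    "sp": (1e-9, 1.0),
    "p": (0.0, 1.0),
    "qaly_weight": (0.0, 1.0),
    "wtp_base": (0.0, 1e7),
    "inflation_factor": (0.0, 10.0),
    "fx_rate": (0.0, 10.0),
    "delay_years": (0.0, 10.0),
    "annual_care_savings": (0.0, 1e6),
    "therapy_cost_annual": (0.0, 1e6),
    "scan_cost": (0.0, 1e5),
    "discount_rate": (0.0, 0.5),
    "fn_penalty": (0.0, 1e7),
}

_PROBABILITY_PARAMS = {"se", "sp", "p", "qaly_weight"}


class ThresholdError(RuntimeError):
    """E is not monotone in the requested parameter over its domain."""


def _check_parameter(name: str) -> None:
    if name not in _TEST_FIELDS | _ECON_FIELDS:
        raise ValueError(f"unknown parameter {name!r}")


def _check_in_bounds(name: str, value: float) -> None:
    lo, hi = PARAMETER_BOUNDS[name]
    if not lo <= value <= hi:
        raise ValueError(f"{name}={value} outside its domain [{lo}, {hi}]")


def evaluate(
    econ: EconomicParams,
    test: TestCharacteristics,
    overrides: Mapping[str, float] | None = None,
) -> float:
    """Expected value with any subset of parameters overridden."""
    overrides = dict(overrides or {})
    for name, value in overrides.items():
        _check_parameter(name)
        _check_in_bounds(name, value)
    test_over = {k: v for k, v in overrides.items() if k in _TEST_FIELDS}
    econ_over = {k: v for k, v in overrides.items() if k in _ECON_FIELDS}
    return expected_value_from_params(
        replace(test, **test_over), replace(econ, **econ_over)
    )


@dataclass(frozen=True)
class SweepSpec:
    """A parameter name and the ordered grid of values to sweep."""

    parameter: str
    grid: tuple[float, ...]

    def __post_init__(self) -> None:
        _check_parameter(self.parameter)
        if not self.grid:
            raise ValueError("sweep grid must be non-empty")
        object.__setattr__(self, "grid", tuple(float(g) for g in self.grid))
        for g in self.grid:
            _check_in_bounds(self.parameter, g)


def one_way_sweep(
    spec: SweepSpec,
    econ: EconomicParams = EconomicParams(),
    test: TestCharacteristics = TestCharacteristics(),
) -> pd.DataFrame:
    """E at each grid value, all else held at base; sorted by grid value."""
    rows = [
        {"value": g, "expected_value": evaluate(econ, test, {spec.parameter: g})}
        for g in sorted(spec.grid)
    ]
    return pd.DataFrame(rows)


def _is_monotone(values: Sequence[float], tol: float = 1e-9) -> bool:
    diffs = np.diff(np.asarray(values, dtype=float))
    return bool((diffs >= -tol).all() or (diffs <= tol).all())


def threshold(
    parameter: str,
    econ: EconomicParams = EconomicParams(),
    test: TestCharacteristics = TestCharacteristics(),
    target: float = 0.0,
    rtol: float = 1e-6,
    max_iter: int = 200,
) -> float | None:
    """Break-even value of one parameter: the root of ``E - target``.

    Monotonicity of E over the parameter's domain is checked on a coarse
    grid first (:class:`ThresholdError` if violated).  Returns ``None``
    when E never crosses the target in the domain; otherwise the bisection
    root, converged to relative width ``rtol``.
    """
    _check_parameter(parameter)
    lo, hi = PARAMETER_BOUNDS[parameter]

    def f(x: float) -> float:
        return evaluate(econ, test, {parameter: x}) - target

    grid = np.linspace(lo, hi, 41)
    values = [f(x) for x in grid]
    if not _is_monotone(values):
        raise ThresholdError(
            f"E is not monotone in {parameter!r} over [{lo}, {hi}]; "
            "threshold analysis is not well defined"
        )
    signs = np.sign(values)
    crossings = np.nonzero(np.diff(signs) != 0)[0]
    if len(crossings) == 0:
        return None
    a, b = float(grid[crossings[0]]), float(grid[crossings[0] + 1])
    fa = f(a)
    if fa == 0.0:
        return a
    for _ in range(max_iter):
        m = 0.5 * (a + b)
        fm = f(m)
        if fm == 0.0 or (b - a) <= rtol * max(abs(m), 1e-12):
            return m
        if (fa < 0) == (fm < 0):
            a, fa = m, fm
        else:
            b = m
    return 0.5 * (a + b)


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution for one parameter.

    Families: ``point`` (value), ``uniform`` (low, high), ``beta`` (mean,
    sd; method-of-moments, probabilities only), ``normal`` (mean, sd) and
    ``lognormal`` (mean, sd of the variable itself).  Probability-type
    parameters accept only point/uniform/beta; normal draws for
    non-negative parameters are clipped at zero.
    """

    parameter: str
    family: str
    hyperparameters: Mapping[str, float]

    FAMILIES = ("point", "uniform", "beta", "normal", "lognormal")

    def __post_init__(self) -> None:
        _check_parameter(self.parameter)
        if self.family not in self.FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "hyperparameters", dict(self.hyperparameters))
        h = self.hyperparameters
        if self.family == "point":
            _check_in_bounds(self.parameter, h["value"])
        elif self.family == "uniform":
            if h["low"] > h["high"]:
                raise ValueError("uniform requires low <= high")
            _check_in_bounds(self.parameter, h["low"])
            _check_in_bounds(self.parameter, h["high"])
        elif self.family == "beta":
            if self.parameter not in _PROBABILITY_PARAMS:
                raise ValueError("beta is only valid for probability parameters")
            m, s = h["mean"], h["sd"]
            if not 0 < m < 1 or s <= 0 or s * s >= m * (1 - m):
                raise ValueError("beta needs 0<mean<1 and sd^2 < mean(1-mean)")
        elif self.family in ("normal", "lognormal"):
            if self.parameter in _PROBABILITY_PARAMS:
                raise ValueError(
                    f"{self.family} is not valid for probability parameters"
                )
            if h["sd"] <= 0 or (self.family == "lognormal" and h["mean"] <= 0):
                raise ValueError(f"invalid {self.family} hyperparameters")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        h = self.hyperparameters
        lo, hi = PARAMETER_BOUNDS[self.parameter]
        if self.family == "point":
            return np.full(n, float(h["value"]))
        if self.family == "uniform":
            return rng.uniform(h["low"], h["high"], n)
        if self.family == "beta":
            m, s = h["mean"], h["sd"]
            nu = m * (1 - m) / (s * s) - 1.0
            draws = rng.beta(m * nu, (1 - m) * nu, n)
            return np.clip(draws, lo, hi)
        if self.family == "normal":
            return np.clip(rng.normal(h["mean"], h["sd"], n), max(lo, 0.0), hi)
        # lognormal parameterised by the variable's own mean and sd
        m, s = h["mean"], h["sd"]
        sigma2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        return np.clip(rng.lognormal(mu, np.sqrt(sigma2), n), lo, hi)


@dataclass(frozen=True)
class PSAResult:
    mean: float
    sd: float
    prob_positive: float
    quantiles: Mapping[float, float]
    draws: np.ndarray


def probabilistic_sa(
    specs: Sequence[DistributionSpec],
    econ: EconomicParams = EconomicParams(),
    test: TestCharacteristics = TestCharacteristics(),
    n_draws: int = 10_000,
    seed: int = 0,
    quantile_levels: Sequence[float] = (0.025, 0.25, 0.5, 0.75, 0.975),
) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty through E.

    One seeded stream; parameter draws are consumed in sorted-name order,
    so results are reproducible regardless of spec ordering.  Point-mass
    specs reproduce the deterministic E exactly.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    by_name = {}
    for spec in specs:
        if spec.parameter in by_name:
            raise ValueError(f"duplicate distribution for {spec.parameter!r}")
        by_name[spec.parameter] = spec
    rng = np.random.default_rng(seed)
    samples = {
        name: by_name[name].sample(rng, n_draws) for name in sorted(by_name)
    }
    draws = np.empty(n_draws)
    names = list(samples)
    for i in range(n_draws):
        draws[i] = evaluate(econ, test, {n: float(samples[n][i]) for n in names})
    return PSAResult(
        mean=float(draws.mean()),
        sd=float(draws.std(ddof=1)) if n_draws > 1 else 0.0,
        prob_positive=float((draws > 0).mean()),
        quantiles={q: float(np.quantile(draws, q)) for q in quantile_levels},
        draws=draws,
    )


def tornado(
    ranges: Mapping[str, tuple[float, float]],
    econ: EconomicParams = EconomicParams(),
    test: TestCharacteristics = TestCharacteristics(),
) -> pd.DataFrame:
    """One-way low/high spans per parameter, widest span first.

    ``span = E(high) - E(low)``; rows are sorted by |span| descending with
    ties broken by parameter name.
    """
    rows = []
    for name, (low, high) in ranges.items():
        e_low = evaluate(econ, test, {name: low})
        e_high = evaluate(econ, test, {name: high})
        rows.append(
            {
                "parameter": name,
                "low": low,
                "high": high,
                "e_low": e_low,
                "e_high": e_high,
                "span": e_high - e_low,
            }
        )
    df = pd.DataFrame(rows)
    df["_abs"] = df["span"].abs()
    df = (
        df.sort_values(["_abs", "parameter"], ascending=[False, True])
        .drop(columns="_abs")
        .reset_index(drop=True)
    )
    return df
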