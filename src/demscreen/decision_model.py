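"""Expected-value model of a presymptomatic dementia screening test.

The economic core of the package.  A screened subject falls into one of the
four diagnostic outcomes — true positive (TP), false positive (FP), true
negative (TN), false negative (FN) — with probabilities induced by the
test's sensitivity (Se), specificity (Sp), and the prevalence ``p`` of
future dementia in the screened population:

    TPF = Se,  FNF = 1 - Se,  TNF = Sp,  FPF = 1 - Sp.

Each outcome is assigned a currency-valued utility ``U``, and the expected
value per screened subject is

    E = U(TP)*Se*p + U(FP)*(1-Sp)*(1-p) + U(TN)*Sp*(1-p) + U(FN)*(1-Se)*p.

Utilities follow the delayed-onset construction: a true positive who adopts
lifestyle change/therapy gains ``d`` years of delayed onset, valued as the
annual care-cost savings plus the monetised quality-of-life (QALY)
difference between the non-demented and demented states, both summed over
the ``d`` delay years, minus therapy and scan costs.  A false positive pays
therapy and scan; negatives pay only the scan.

Default parameter values are the reference analysis' Canadian figures
(CAD): $27,000/yr care savings, a 0.348 QALY-weight applied to a
willingness-to-pay of $80,000 USD (2011) inflated by 1.10 and converted at
1.3 CAD/USD, $4,800/yr therapy, $2,000 per scan, five-year delay.  Streams
are summed undiscounted by default; a discount rate is available and
applies an ordinary annuity factor to all annual streams.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "TestCharacteristics",
    "EconomicParams",
    "UtilityMatrix",
    "qaly_annual_value",
    "annuity_factor",
    "build_utility_matrix",
    "expected_value",
    "expected_value_from_params",
    "expected_value_vs_delay",
    "net_savings_per_detection",
]


@dataclass(frozen=True)
class TestCharacteristics:
    """Sensitivity, specificity, and screened-population prevalence."""

    se: float = 0.9
    sp: float = 0.9
    p: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.se <= 1.0:
            raise ValueError(f"sensitivity must be in (0, 1], got {self.se}")
        if not 0.0 < self.sp <= 1.0:
            raise ValueError(f"specificity must be in (0, 1], got {self.sp}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"prevalence must be in [0, 1], got {self.p}")

    @property
    def tpf(self) -> float:
        return self.se

    @property
    def fnf(self) -> float:
        return 1.0 - self.se

    @property
    def tnf(self) -> float:
        return self.sp

    @property
    def fpf(self) -> float:
        return 1.0 - self.sp


@dataclass(frozen=True)
class EconomicParams:
    """Economic inputs of the screening decision model (currency: CAD).

    ``wtp_base`` is quoted in base-year USD and converted to CAD via
    ``inflation_factor`` and ``fx_rate``.  ``therapy_cost_annual`` is the
    yearly therapy cost; the total over the delay period is derived
    (``therapy_cost_total``), so therapy scales with ``delay_years`` as the
    delayed-onset construction requires.  ``fn_penalty`` is an optional
    extra cost attached to a missed case (the reference construction uses
    none — a false negative pays only the scan).
    """

    wtp_base: float = 80_000.0
    inflation_factor: float = 1.10
    fx_rate: float = 1.3
    qaly_weight: float = 0.348
    delay_years: float = 5.0
    annual_care_savings: float = 27_000.0
    therapy_cost_annual: float = 4_800.0
    scan_cost: float = 2_000.0
    discount_rate: float = 0.0
    fn_penalty: float = 0.0

    def __post_init__(self) -> None:
        for name in (
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
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.qaly_weight > 1.0:
            raise ValueError("qaly_weight must be <= 1")

    @property
    def wtp_cad(self) -> float:
        """Willingness to pay per QALY in current CAD."""
        return self.wtp_base * self.inflation_factor * self.fx_rate

    @property
    def therapy_cost_total(self) -> float:
        """Therapy cost accumulated over the delay period (undiscounted)."""
        return self.therapy_cost_annual * self.delay_years


@dataclass(frozen=True)
class UtilityMatrix:
    """Currency utilities of the four screening outcomes, per subject."""

    u_tp: float
    u_fp: float
    u_tn: float
    u_fn: float


def qaly_annual_value(params: EconomicParams) -> float:
    """Monetised annual QALY difference between non-demented and demented.

    ``WTP_base x inflation x FX x qaly_weight`` — $39,811.2 CAD/yr at the
    reference defaults.
    """
    return params.wtp_cad * params.qaly_weight


def annuity_factor(years: float, rate: float) -> float:
    """Present value of a $1/yr stream over ``years`` at ``rate`` (0 -> years)."""
    if years < 0 or rate < 0:
        raise ValueError("years and rate must be non-negative")
    if rate == 0.0:
        return years
    return (1.0 - (1.0 + rate) ** (-years)) / rate


def build_utility_matrix(params: EconomicParams) -> UtilityMatrix:
    """Utility matrix of the delayed-onset screening construction.

    With zero discounting this reduces to

        U(TP) = savings*d + qaly*d - therapy_annual*d - scan
        U(FP) = -therapy_annual*d - scan
        U(TN) = U(FN) = -scan
    """
    a = annuity_factor(params.delay_years, params.discount_rate)
    gain = (params.annual_care_savings + qaly_annual_value(params)) * a
    therapy = params.therapy_cost_annual * a
    return UtilityMatrix(
        u_tp=gain - therapy - params.scan_cost,
        u_fp=-therapy - params.scan_cost,
        u_tn=-params.scan_cost,
        u_fn=-params.scan_cost - params.fn_penalty,
    )


def expected_value(test: TestCharacteristics, u: UtilityMatrix) -> float:
    """Probability-weighted utility per screened subject (full precision)."""
    return (
        u.u_tp * test.tpf * test.p
        + u.u_fp * test.fpf * (1.0 - test.p)
        + u.u_tn * test.tnf * (1.0 - test.p)
        + u.u_fn * test.fnf * test.p
    )


def expected_value_from_params(
    test: TestCharacteristics, params: EconomicParams
) -> float:
    return expected_value(test, build_utility_matrix(params))


def expected_value_vs_delay(
    test: TestCharacteristics, params: EconomicParams, delay_years: float
) -> float:
    """E evaluated at an alternative onset delay ``d``.

    Savings, QALY value and therapy all scale with ``d``, so with zero
    discounting E is affine in the delay; at ``d = 0`` only scan costs
    remain.
    """
    return expected_value_from_params(test, replace(params, delay_years=delay_years))


def net_savings_per_detection(
    annual_care_savings: float = 27_000.0,
    delay_years: float = 5.0,
    scan_cost: float = 2_000.0,
    screens_per_detection: float = 10.0,
) -> float:
    """Gross delay savings minus the imaging cost of finding one case.

    ``screens_per_detection`` is 1/p — the number of scans needed per
    detected future case at screened-population prevalence ``p``.
    """
    if screens_per_detection < 1:
        raise ValueError("screens_per_detection must be >= 1")
    return annual_care_savings * delay_years - scan_cost * screens_per_detection
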