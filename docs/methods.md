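# Methods

This note documents the models implemented in `demscreen`, the defaults
they ship with, the numerical conventions, and what the synthetic-data
machinery does and does not emulate.

## The screening decision model

A screened subject has future dementia with probability `p` (the
prevalence in the *screened* population, not the general population; risk
enrichment through lifestyle factors is what raises it to the default
0.1).  Conditional on disease status the test is positive with probability
`Se` (diseased) or `1 − Sp` (healthy).  The four outcomes carry currency
utilities per subject:

- `U(TP) = (annual_care_savings + qaly_annual_value)·A(d, r) − therapy_annual·A(d, r) − scan_cost`
- `U(FP) = −therapy_annual·A(d, r) − scan_cost`
- `U(TN) = U(FN) = −scan_cost`

where `d` is the onset delay achieved for detected cases,
`A(d, r)` the annuity factor (`A = d` at discount rate `r = 0`, the
default — the reference construction sums the five-year streams
undiscounted), and `qaly_annual_value = WTP_USD × inflation × FX ×
qaly_weight`.  The expected value is the probability-weighted sum.  E is
affine in every cost/value parameter and, at `r = 0`, affine in `d`, which
gives closed-form break-even points used to validate the threshold solver.

Two modelling choices deserve flagging:

- **A missed case costs only the scan.**  The reference utility matrix
  assigns the false negative no disease penalty; an optional `fn_penalty`
  parameter (default 0) lets users price the missed detection.
- **The quoted CAD willingness-to-pay.**  `80,000 × 1.10 × 1.3 = 114,400`
  CAD; the source analysis quotes "$114,000".  The package computes
  114,400 and never uses the rounded figure.

Defaults (all CAD unless noted): WTP $80,000 USD (2011) × 1.10 inflation ×
1.3 CAD/USD; QALY weight 0.348 (the non-demented/demented utility
difference); delay 5 years; care savings $27,000/yr; therapy $4,800/yr
(stored annually so therapy scales with the delay, matching the
construction's what-if behaviour at other delays); scan $2,000.
At the defaults, `E = 5,149.008·d − 2,000`, so screening breaks even at a
delay of ≈ 0.39 years.

Therapy cost is stored as an **annual** figure with the period total
derived as `annual × delay_years`.  The reference total ($24,000 over five
years) is recovered exactly; the annual form is primary because the
delay-sensitivity analysis scales therapy with `d`.

## Demographic arithmetic

Populations live in inclusive age bands (`60–64`), internally treated as
half-open `[lo, hi+1)`; open-ended top bands (`90+`) are closed at age 120
for any width-weighted arithmetic.  Rates are uniform within a band; when
population and schedule bands intersect, rates are apportioned linearly in
overlap width (the only defensible choice given banded inputs).  Counts
are plain persons internally; the packaged tables quoted in thousands are
scaled on load.

The at-risk incidence procedure computes `(population − prevalent cases) ×
incidence rate` per band.  Incidence schedules can be generated from the
exponential doubling law (rate doubling every 6.3 years of age, anchored
at 3.9/1,000 person-years at ages 60–64, rated at band midpoints).  Note
the printed anchors themselves are not exactly consistent with the law:
pure doubling from the 60–64 anchor gives ≈ 85/1,000 at 90+, not the
quoted 104.8; the generator is therefore offered as a generator, not as a
reproduction of the 90+ figure.

Printed-number conventions: growth factors and percentages round half-up
(82.75 → 82.8), matching the published tables; the per-scan cost is
*truncated* to whole dollars (1,136.67 → 1,136), because that is the only
convention consistent with the printed figure; scanner counts round
half-up (5,225,000/3,000 = 1,741.67 → 1,742), the only convention
consistent with all six printed fleet cells.  One printed cell is
internally inconsistent: the Canada 80+ growth ratio prints 1.937 while
its own counts give 1.93755 → 1.938; the test suite holds that cell to ±1
in the last printed digit.

## The cohort delay model

The projector is a deterministic expected-count model over strata of
non-demented and demented persons by single year of age and sex.  The
underlying administrative micro-simulation this emulates is
individual-level; expected-count propagation reproduces its aggregate
anchors exactly as means and is testable to machine precision, which is
why it is the default (a seeded binomial mode is available for variance
exploration).  Within each projected year the order of operations is
fixed: incidence → mortality → aging.  The order is a convention (the
sources are silent); it is applied identically in the projector, the
equilibrium initialiser, and the test oracles.  The top modelled age (110)
is absorbing; entry cohorts at the youngest age default to zero, so the
modelled population closes over the 20-year horizon and calibration
absorbs the missing immigration/birth inflow.

Onset delay `d` is an age-shift of the incidence schedule,
`rate_d(a) = rate(a − d)`; ages shifted below the schedule floor get rate
zero.  Because incidence rises steeply with age this bounds delayed
prevalence above by baseline at every year, and larger delays give weakly
lower prevalence — both enforced as tests.

Care counts are `care_fraction × demented`, with the default fraction
261/340 ≈ 0.768 inferred from the reference 2011 pair (261,000 receiving
care of 340,000 prevalent).  On the reference printed counts the
"prevalence reduction of ~45%" is actually the care-count version
((522 − 291)/522 = 44.25%); the prevalence-proper version is
(674 − 374)/674 = 44.51%.  `prevalence_reduction` exposes both via its
`quantity` argument.

## Synthetic scenarios and calibration

`synthetic_data` generates the inputs the projector needs with the
statistical structure the analysis assumes: doubling-law incidence through
the 60–64 anchor, female rates exceeding male above a crossover age
(default 75, ratio 1.10), Gompertz-like all-cause mortality (default
8/1,000 person-years at 60, doubling every 8 years — **invented**: the
sources quote no mortality rates at all), and a dementia hazard ratio
(default 2.5) multiplying all-cause mortality for the demented.  A
separate preset reproduces the printed sex-specific administrative
incidence anchors exactly (0.110/0.226 per 1,000 F/M at 40–44,
5.547/5.921 at 70–74, 48.040/43.578 at 95+) with log-linear interpolation
between anchor-band midpoints; because the anchors are sparse, the
female/male crossover of the interpolated curve lands near age 82 rather
than exactly at 75.

Initial demented counts are the quasi-equilibrium of the baseline
dynamics, computed by integrating the projector's own difference equations
along a cohort's age — the exact stationary-entries limit of a long
burn-in, without the burn-in.  A test verifies that projecting the
equilibrium state preserves age-specific demented fractions to 1e-9.

The default population pyramid declines geometrically by 30% per 5-year
band over ages 40–99 with a Canada-like 16M total.  That is deliberately
steeper than a stationary age structure: with entry cohorts closed off and
mortality held constant, the pyramid alone must carry the cohort-bulge
aging, mortality improvement, and immigration that drive the observed
near-doubling of prevalence over 20 years.  The synthetic population is
therefore a *dynamical* stand-in — its prevalence trajectory has the right
shape and calibrated level — not a demographic portrait; passing tests say
the projection and calibration machinery is correct, not that the pyramid
matches any census.

`calibrate_to_anchors` tunes exactly two knobs — the overall incidence
scale (sets the level; prevalence is nearly linear in it, fit by a
deterministic multiplicative fixed point) and the dementia hazard ratio
(sets case turnover and hence growth between anchors; coarse grid over
[1, 8] refined by bounded golden-section) — until the projected prevalence
passes within 5% (default) of the stated `(year, prevalence)` anchors.
Infeasible anchors raise a `CalibrationError` carrying the best-achieved
spec and residual.  Calibrated to (2011, 340k) and (2031, 674k) the
defaults land at scale ≈ 1.64, hazard ratio ≈ 7.1, residual ≈ 1e-6; a
five-year delay then gives a 2031 growth factor of 1.21 and a 39%
prevalence reduction (reference: 1.10 and ~45%; external estimates range
44–50%).  The calibrated hazard ratio is high relative to epidemiological
estimates (~2–3) because it also absorbs the narrower diagnosed-case
definition and time-varying mortality the model omits.

## Capacity, cost, and radiation

Screening demand is `annual incidence × lifestyle fraction (0.5) ×
screens per detected case (1/p = 10) ÷ rescreen interval (1 yr)`; fleets
divide by throughput (3,000 exams/scanner/yr) and round half-up.  The
demand model is steady-state: it ignores depletion of the screening pool
by prior positive screens.  Per-scan cost components: $500 probe (the
quoted probe arithmetic is itself inconsistent — $3,000 per production run
over 10 patients is $300, yet $500 is quoted — so the probe cost is a
direct parameter defaulting to the quoted $500), capital $4.3M
straight-line over 10 years and 10%/yr service each spread over
throughput, $100 operating, $250 interpretation.  Radiation detriment is
linear no-threshold: `dose × 6×10⁻² Sv⁻¹ × population`.  The vendor case
divides the fleet target by the ramp-up years, presents units rounded to
the nearest hundred, and adds a mature service stream of
`units/yr × product life × price × service fraction`; both presented and
exact figures are returned.

## Sensitivity analysis

Sweeps and tornado tables re-evaluate E with one parameter overridden,
validated against per-parameter domain bounds (the same bounds bracket the
threshold bisection; delay is bounded at [0, 10] years).  The threshold
solver checks monotonicity on a 41-point grid first, returns "none in
domain" when E never crosses the target, and otherwise bisects to 1e-6
relative width (200-iteration cap); it is tested against the closed-form
affine roots.  PSA families follow standard health-economics practice
(the sources specify no distributions): beta for probabilities
(method-of-moments from mean and sd), lognormal for costs and WTP, uniform
for the delay.  One seeded stream is consumed in sorted parameter-name
order, so results are independent of spec ordering and bit-reproducible.

## Problem sizes and runtime

Everything is desk-scale: the decision model is closed-form; cohort
projections run 71 ages × 2 sexes × 20 years; calibration evaluates a few
hundred such projections; the Monte-Carlo cross-check of E uses 10⁶
Bernoulli subjects and PSA defaults to 10⁴ draws.  The full test suite
runs in well under a minute on one CPU.

## Known limitations

- No jurisdiction calibration: parameter defaults mix Canadian costs,
  Swedish/Finnish QALY valuation, and US screening-trial prevalence; the
  expected value is a starting point, not a jurisdictional estimate.
- The cohort model omits immigration, time trends in mortality and
  incidence, and risk-factor dynamics (diabetes, hypertension, obesity);
  the pyramid steepness and calibration knobs absorb these in aggregate.
- Undiscounted five-year streams by default; enabling discounting changes
  E and all break-even points.
- The screened-pool model assumes annual rescreening of negatives without
  pool depletion; longer rescreen intervals are supported but prevalence
  enrichment from repeated negative screens is not modelled.
- Se/Sp of a future combined PET/MRI test are assumptions (0.9/0.9), not
  estimates from imaging data.
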