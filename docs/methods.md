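# Methods

`retailcea` evaluates a population-level policy that restricts the placement
of discretionary (HFSS) food and drink — chocolate and confectionery,
puddings and biscuits, savoury snacks, and sugary beverages — in prominent
supermarket locations, against a status quo with no restrictions. It is a
cost-utility analysis: benefits are health-adjusted life years (HALYs) and
healthcare cost offsets produced by a proportional multi-state life table
(PMSLT); costs are bottom-up estimates of government and industry
implementation effort. This note records the model, its assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Intervention-effect pathway

There is no direct evidence linking placement restrictions to BMI, so the
effect is propagated along a logic pathway:

1. **Purchase reduction.** Two retail studies provide proportional
   reductions in purchases of restricted products: a sustained 15.5%
   checkout-restriction effect, and an arm contrast of seasonal increases
   (31% control − 12% intervention = 19%). The combined effect is their
   unweighted mean, 17.25%. The arm contrast is operationalised as an
   arithmetic difference; a ratio form, 1 − 1.12/1.31, is available by
   configuration. The same effect applies to all four categories, including
   beverages, where the direct evidence is weakest.
2. **Energy.** Per (age, sex) stratum, the daily energy reduction is
   `ΔE = −Σ_cat intake × market_share × supermarket_share × effect`,
   with market share 0.824 (the chains the policy binds) and supermarket
   purchase share 0.76. The 0.76 figure is evidenced for chocolate only and
   is applied uniformly to all categories as a deliberate simplification
   (overridable per category in configuration). No compensatory consumption
   of non-restricted products is assumed.
3. **Weight.** A sustained energy change maps to an *equilibrium* body-weight
   change using steady-state energy-balance constants: 94 kJ/day per kg for
   adults (18+) — the familiar ~10 kcal/day-per-pound rule — and 100 kJ/day
   per kg for children, both configurable. No dynamic trajectory is
   modelled; the weight change is treated as attained and then maintained
   for the remainder of each cohort's lifetime.
4. **BMI.** `ΔBMI = Δweight / height²` with stratum mean height. The shift
   moves the stratum's mean BMI; the standard deviation is unchanged.

The pathway is linear in the effect size and monotone in intake and each
coverage factor; a zero effect produces an identically zero impact table.
Because the population mean weight change blends child and adult
coefficients, an adult-only conversion of the population-mean energy change
slightly overstates the blended mean — this is expected, not an error.

## Proportional multi-state life table

The model follows single-year (age, sex) cohorts aged 2–100 through annual
cycles to age 100 (the lifetime horizon) or a configured shorter horizon.
Each cohort carries a main life table and nine parallel disease sub-models:
ischaemic heart disease, hypertensive heart disease, ischaemic stroke,
diabetes, colorectal and kidney cancer, breast and endometrial cancer
(female only), and knee/hip osteoarthritis.

**Risk.** BMI within a stratum is lognormal (configurable to normal) with
the stratum mean/SD. Relative risk per disease is
`RR(x) = rr^max(0, x − TMRED)` with a theoretical-minimum-risk threshold of
21 kg/m² by default. The potential impact fraction

    PIF = (∫RR f − ∫RR f') / ∫RR f

is integrated on a fixed bounded BMI grid (10–60 kg/m², step 0.5, trapezoid
rule, renormalised over the grid). The bounded support is essential, not
cosmetic: an exponential risk function has no finite expectation under an
unbounded lognormal, so truncation to the physiologically meaningful range
defines the estimand. The grid places the default threshold exactly on a
node; against adaptive quadrature on the same support the grid integral
agrees to ~1e-4 relative. The PIF is exactly zero for a null shift or a
flat risk, and the intervention enters the model solely as
`incidence × (1 − PIF)` from each disease's minimum age (default 20).

**Disease dynamics.** Each sub-model has four states — healthy, diseased,
dead from the disease, dead from other causes — advanced by annual
difference equations with incidence i, remission r and case fatality f:

    S' = S − Si + Cr − Sm      C' = C + Si − Cr − Cf − Cm
    Dd' = Dd + Cf              Do' = Do + (S + C)m

where m is all-cause mortality net of the disease's own mortality
(f × input prevalence), avoiding double counting. Occupancies are checked
to sum to one at every cycle (they do to ~1e-15; the engine aborts above
1e-6). There is no half-cycle correction, and the incidence response to the
BMI change is immediate — no lag is applied.

**Main table.** Baseline-arm mortality is the input all-cause rate;
intervention-arm mortality adds `Σ_d f_d (p_d − p_d^baseline)`, the change
in disease-attributable deaths. Morbidity is background pYLD plus
`Σ_d dw_d p_d` with GBD-style disability weights, capped below 1 (the run
aborts otherwise). Per cycle the cohort accrues life years, HALYs
`l × (1 − morbidity)` and healthcare costs `l × Σ_d p_d × cost_d`,
discounted at `(1 + ρ)^−t` with t = 0 undiscounted and ρ = 3% by default.
Children carry their BMI shift with them as they age; disease risk activates
at each disease's minimum age.

Incremental results are count-weighted sums over cohorts. The status-quo arm
depends only on the epidemiological inputs, so it is computed once and
cached; probabilistic draws rerun only the intervention arm.

**ICER.** Net cost is defined as intervention cost plus incremental
healthcare cost (signed; savings negative). With positive health gain and
net savings the result is reported as "Dominant" with no ratio; the reverse
is "Dominated"; zero health gain is labelled undefined. Note that published
cost-utility tables sometimes report a net figure equal to savings plus
intervention cost with both taken as magnitudes; this package always uses
the signed definition above.

## Bottom-up costing

All amounts are A$ 2024; a CPI helper adjusts older figures. A working day
is 7.6 h. Hourly labour is `base × 1.13 × (1 + 0.175 × 4/52)`: 13% on-costs
on all hours, 17.5% leave loading prorated over four annual-leave weeks
(full-year application is a configuration flag).

Industry transition costs (year 0, undiscounted): 12 h of a general manager
at each of 4 head offices; 3 h each for a retail manager and two stock
clerks at each of 4,105 stores; product assessment of 79% of the range
(default 25,000 products per chain) at 5–10 minutes per product (midpoint
7.5 deterministic, uniform in the PSA); and layout changes of one day each
for a manager and clerk plus 4 assistants × 1.5 days per store. Ongoing
assessment of new products (default 1,000 per chain-year × 79%) runs from
year 1 to the horizon. Government bears legislation (A$1.56 M), a media
campaign (A$0.96 M), complaints handling (A$57 k/yr), and monitoring of 7%
of stores in years 1–3 only. Non-compliant stores among those checked
(30/20/10% in years 1–3) pay a A$5,500 penalty, modelled as an industry
cost — not netted off government costs as revenue. Store counts stay
fractional (expected-value costing). Discounted sector totals sum exactly
to the grand total, and with defaults the lifetime total lands around
A$19 M, in the intended tens-of-millions range.

## Synthetic inputs

The generator emulates the study conditions for a high-income population of
about 26 million: a smooth age pyramid (2–100, both sexes), BMI means rising
from childhood (~16 kg/m²) to a mid-adult plateau (~27–28 kg/m², SD ~5),
heights following a growth curve to 1.78 m (males) / 1.645 m (females),
Gompertz-like all-cause mortality (monotone above age 40) and a logistic
background-morbidity curve. Disease rates follow smooth logistic age curves
with sex offsets; magnitudes loosely echo published high-income burden
patterns without claiming accuracy. Category intake is shaped by age and
calibrated so the population-weighted mean restricted-category totals are
772 kJ/day (males) and 521 kJ/day (females) — the levels at which the
pathway yields mean reductions of ≈83 and ≈56 kJ/day. One master seed feeds
independent sub-streams per data domain, so regenerating one domain never
perturbs another; generation is byte-reproducible.

The "small" scale collapses the population to 5-year-band representative
ages (20 per sex) for fast tests and the PSA; rate tables stay at
single-year resolution because cohorts age through every year. What passing
tests on these inputs show is that the machinery is correct — calibration,
conservation, monotonicity, dominance logic, reproducibility. They do not
show that the headline health gains of any real population are reproduced:
real intake surveys, epidemiology and costs would be needed for that, and
the synthetic HALY and cost magnitudes should be read only as plausible
orders of magnitude.

## Uncertainty analysis

The PSA samples every uncertain parameter independently and reruns the
pipeline per draw (default 2,000 draws): effect size ~ normal(0.1725,
0.0215) truncated to [0, 1] (the SD reproduces a ±12–13% relative 95%
interval); per-disease RR multipliers ~ lognormal(σ = 0.03) truncated so
RR stays ≥ 1, reflecting the consistent direction of the evidence;
healthcare and fixed-cost multipliers ~ gamma (legislation degenerate);
assessment minutes ~ uniform(5, 10). Summaries are means with empirical
2.5/97.5 percentile intervals plus cost-effectiveness-plane quadrant counts.
One master seed spawns per-draw substreams, so scenario contrasts share
common random numbers and repeat runs are bit-identical. With all
distributions degenerate the PSA reproduces the deterministic run exactly.

Five deterministic scenarios rerun the pipeline with documented overrides:
7% and 10% discount rates, store-layout time tripled to 3 days, restriction
to chocolate/confectionery only, and a 10-year horizon.

## Numerical choices and degenerate inputs

- Annual cycles; additive difference equations; no half-cycle correction.
- PIF grid (10, 60, 101); identical distributions and RR = 1 short-circuit
  to exact zero, making the null-intervention identity exact to the bit.
- Empty strata (e.g. a sex with no cohorts in a toy population) are carried
  as inert; a cohort older than 100 contributes nothing.
- Anthropometry for collapsed populations is linearly interpolated to
  single-year ages for the PIF.
- Validation rejects out-of-range cells with row identifiers and incomplete
  age coverage per sex before any computation runs.

## Problem sizes

Default runs use the full 198-cohort population for deterministic results
and scenarios, and the 40-cohort collapsed population with 2,000 draws for
the PSA; the engine-versus-oracle equivalence uses a 3-disease, 10-start-age
toy at 1e-9.

## Known limitations

- Proportional purchase→consumption transfer with no substitution; the
  steady-state weight model ignores adaptation dynamics.
- Independent parameter sampling (no correlation structure).
- Healthcare cost offsets accrue only through the nine modelled diseases.
- The RR functional form (exponential above a threshold) and the bounded
  integration range are modelling conventions; results are conditional on
  them.
- Synthetic epidemiology is illustrative; no equity, productivity or
  industry-revenue effects are modelled.
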