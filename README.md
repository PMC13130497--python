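# retailcea

Cost-utility analysis of a policy restricting the placement of unhealthy
(HFSS) food and drink — chocolate and confectionery, puddings and biscuits,
savoury snacks, and sugary beverages — in prominent supermarket locations
(checkouts, end-of-aisles, entrances), compared with a no-policy status quo.
The package is written for health economists and epidemiological modellers
who want a tested, reusable implementation of the whole evaluation chain,
runnable end-to-end on internally consistent synthetic inputs.

## What it computes

The analysis runs in four stages:

1. **Effect pathway.** Trial evidence on purchase reductions is combined
   (unweighted mean of 15.5% and 31% − 12% = 19%, giving 17.25%) and scaled
   by market coverage to a daily energy reduction per (age, sex) stratum,
   ΔE = −Σ_cat intake × 0.824 × 0.76 × 0.1725, then converted to an
   equilibrium weight change (Δw = ΔE / 94 kJ·day⁻¹·kg⁻¹ for adults,
   /100 for children) and a BMI shift Δw/h².
2. **Bottom-up costing.** Government (legislation, media, complaints,
   3-year monitoring) and industry (head-office work, per-store
   familiarisation and layout change across 4,105 stores, product
   assessment, ongoing new-product assessment, non-compliance penalties)
   cost streams in A$ 2024, discounted at 3%.
3. **Proportional multi-state life table (PMSLT).** The BMI shift lowers
   disease incidence through potential impact fractions,
   PIF = (∫RR f − ∫RR f′)/∫RR f with RR(x) = rr^max(0, x − 21), for nine
   obesity-related diseases, each a four-state Markov sub-model (healthy /
   diseased / dead-of-disease / dead-other) feeding mortality and morbidity
   adjustments into cohort life tables for ages 2–100, both sexes. Outputs
   are incremental health-adjusted life years (HALYs) and healthcare cost
   offsets over the lifetime horizon.
4. **ICER and uncertainty.** Net cost = intervention cost + incremental
   healthcare cost; more health at net savings reports "Dominant" instead
   of a ratio. A 2,000-draw Monte Carlo PSA propagates parameter
   uncertainty (95% percentile intervals, cost-effectiveness-plane
   quadrants), and five deterministic scenarios vary discount rate (7%,
   10%), layout effort (3 days), category scope (chocolate only) and
   horizon (10 years).

See `docs/methods.md` for the model equations, assumptions, parameter
defaults and known limitations.

## Worked example

```sh
retailcea run --scale small --seed 1 --out demo_out
```

prints (small scale collapses the population to 5-year-band cohorts):

```
HALYs gained: 617,543
intervention cost: A$18.87 M
healthcare cost: A$-10,190.91 M
net cost: A$-10,172.04 M
ICER: Dominant
outputs written to demo_out
```

and writes the tables under `demo_out/`, e.g. the effectiveness table

```
                          males  females
mean_change_kj_per_day -85.1199 -56.6190
mean_change_weight_kg   -0.8872  -0.5903
mean_change_bmi_kg_m2   -0.3283  -0.2515
```

Reading: the policy removes ~85 kJ/day (males) and ~57 kJ/day (females)
from mean intake, which at steady state is ~0.89/0.59 kg of body weight and
0.33/0.25 BMI units. Over the population's lifetime the model converts that
into 0.62 M HALYs gained and ~A$10.2 bn of healthcare savings against a
A$18.9 M implementation cost, so the intervention dominates the status quo
(better health, lower cost). The magnitudes are properties of the synthetic
inputs — plausible, deliberately calibrated in their intake means, but not
estimates for any real population.

The same run from the library:

```python
from retailcea import RunConfig, generate_all, deterministic_run

cfg = RunConfig(seed=1, scale="small")
bundle = generate_all(cfg.seed, scale=cfg.scale)
res = deterministic_run(bundle, cfg)
print(res["outputs"].halys, res["icer"])   # 617543.25..., 'Dominant'
```

Other entry points: `retailcea generate-data` writes the synthetic CSV/YAML
input bundle, `retailcea psa` runs the Monte Carlo analysis, and
`retailcea scenarios` produces the scenario table. Every CLI flag overrides
the corresponding key of a YAML config passed with `--config`.

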