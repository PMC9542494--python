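# invasionlab

Analysis toolkit for **pulse-disturbance invasion experiments in microbial
microcosms**: serial-transfer communities of *Pseudomonas fluorescens*-style
morphotypes (smooth SM, wrinkly spreader WS, fuzzy spreader FS) that are
periodically diluted into fresh medium (1% transfer, 99% mortality) and
invaded by a marked strain at fixed time points. The package is for
microbial ecologists who count colonies and want the full chain from tidy
plate-count tables to publishable inference — plus a mechanistic simulator
so every stage can be exercised without laboratory data.

## What it computes

**Invasion success** is the proportional change of the invader's frequency,
an odds ratio

```
v = x₂ (1 − x₁) / (x₁ (1 − x₂))
```

where the initial invader proportion averages over the three invasion
events (days 4, 8, 12 of a 16-day experiment),

```
x₁ = (1/3) Σ_{t∈{4,8,12}}  I_t / (I_t + R_t)
```

with `I_t` the invader density added on day `t` and `R_t` the resident
density it meets. Resident densities on days 8 and 12 cannot be measured
without destroying undisturbed microcosms, so they are reconstructed from
day-4 sacrifice replicates: reused directly for 1-, 2- and 4-day
disturbance intervals, and divided by the 0.01 survival fraction for the 8-
and 16-day intervals (whose disturbance history up to day 4 matches the
4-day treatment before its dilution). Success is scored as `ln(v + 1)`;
values above `ln 2 ≈ 0.69` mean the invader increased in proportion.

Around the statistic sit the resident-community summaries (Simpson's
`D = 1 − Σ pᵢ²` over the three morphotypes, `log₁₀(cfu/ml + 1)` density)
and the inference battery: OLS models with disturbance frequency
(continuous, optionally quadratic) × resource abundance (categorical) ×
invader type, type III→II ANOVA, likelihood-ratio model selection,
per-resource slopes with t-based 95% CIs, and Bonferroni-adjusted marginal
(estimated) mean comparisons.

The `synthetic` module provides (a) a mechanistic serial-transfer simulator
(logistic broth growth, WS mat niche above a density threshold, toxic-waste
mortality between transfers, mutation, Poisson transfer/plating noise) and
(b) a parametric linear-response generator with known coefficients for
calibration and recovery studies.

## Worked example

Simulate the full factorial design (3 resource levels × 5 disturbance
intervals × 2 invader types × 6 replicates = 180 microcosms, plus 45 day-4
reference microcosms) and run the whole model battery:

```sh
invasionlab simulate --seed 42 --out demo
invasionlab analyze --counts demo/counts.csv --day4 demo/day4_reference.csv \
    --out demo/analysis
invasionlab report demo/analysis/report.json
```

which prints:

```
three-way disturbance x resource x invader type: F_2,168 = 33.50, p = 5.71e-13
SM disturbance x resource: F_2,84 = 89.42, p = 1.56e-21
  SM slope at high: 0.225 (95% CI 0.195, 0.254) *
  SM slope at low: -0.051 (95% CI -0.081, -0.022) *
  SM slope at medium: 0.035 (95% CI 0.005, 0.065) *
WS disturbance x resource: F_2,84 = 6.07, p = 0.00345
  WS slope at high: -0.286 (95% CI -0.358, -0.214) *
  WS slope at low: -0.110 (95% CI -0.182, -0.039) *
  WS slope at medium: -0.224 (95% CI -0.296, -0.152) *
```

Reading: invader success depends on a three-way interaction between
disturbance frequency, resource abundance and invader type (the F test on
2 and 168 df), so each invader is analysed separately. The fast-growing SM
invader gains from disturbance under high resources (slope +0.225 per
disturbance event per 16 days, CI excluding zero) but loses under low
resources, while the slow-growing, mat-forming WS invader loses from
disturbance under high resources — the qualitative signature of
disturbance-mediated invasion being contingent on resource abundance and
invader life history. Slopes are per disturbance event in 16 days (interval
`d` days codes to `16/d` events; other codings are selectable).

The same pipeline is available as library calls
(`invasionlab.run_full_analysis`) returning a JSON-serializable report,
and reads real tidy count CSVs (one plating observation per row; an
optional column-mapping config adapts externally deposited files).

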