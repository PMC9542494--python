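# Methods

This note documents the models, conventions and design choices behind
`invasionlab`, in the spirit of a statistical methods appendix.

## The experiment the package models

A 16-day serial-transfer experiment: static 6-ml microcosms at three
resource levels (full-strength rich medium, 10%, 1%) are pulse-disturbed
every 1, 2, 4, 8 or 16 days by transferring 1% of homogenized culture into
fresh medium (99% mortality, equal intensity across treatments), and
invaded on days 4, 8 and 12 — immediately post-disturbance when the two
coincide — with one of two marked invader morphotypes: a fast-growing
broth colonizer (SM) or a slower, mat-forming competitor (WS). On day 16
everything is plated and resident/invader colonies of the three
morphotypes (SM, WS, FS) are counted. The canonical design is 3 × 5 × 2
× 6 = 180 invaded microcosms, plus 3 resident-only reference microcosms
per resource × interval cell (45) sacrificed at day 4.

## The invasion-success statistic

Success is the proportional change of invader frequency,
`v = x₂(1−x₁) / (x₁(1−x₂))` — the ratio of final to initial invader odds.
`x₁` averages the invader's frequency at introduction over the three
invasion events, `x₁ = ⅓ Σ_t I_t/(I_t + R_t)`.

* `I_t` defaults to the per-event inoculum implied by the experiment's
  totals over three events (SM 8.1×10⁶, WS 6.6×10⁶ cfu), split evenly and
  divided by the 6-ml volume: 4.5×10⁵ and 3.67×10⁵ cfu/ml per event. Both
  are configurable (`InvasionSchedule`).
* `R_t` comes from the day-4 sacrifice replicates. Treatments disturbed
  every 1, 2 or 4 days are invaded post-disturbance each time, so
  `R₄ = R₈ = R₁₂ =` the measured day-4 density. The 8- and 16-day
  treatments were not sampled at day 4 (sampling is destructive); their
  disturbance history up to day 4 is identical to the 4-day treatment
  *before* its day-4 dilution, so their `R` is the 4-day treatment's
  measured density divided by the 0.01 survival fraction. The 8-day
  treatment's day-8 entry is multiplied back down by 0.01 to account for
  its day-8 disturbance. Every imputed entry carries a provenance flag
  (`measured`, `assumed-equal`, `imputed-by-mortality-division`).

`x₂` pools all invader morphotypes against all resident morphotypes at day
16 (populations are distinguished by marker colour, not morphology). To
remove zero inflation, 1 cfu/ml is added to the final invader density
before forming `x₂` (default); an alternative mode applies no density
offset and relies on the +1 inside the transform alone — the historical
description of this correction is ambiguous between the two readings, so
both are implemented with the density reading as default. The score is
`s = ln(v+1)`; `s > ln 2 ≈ 0.69` flags an invader that increased in
proportion. Exact fixation (`x₂ = 1`) is reported as flagged-missing
rather than clamped — the +1 offset makes it effectively impossible, so
the path is defensive — and flagged rows are excluded listwise from models
with a logged count.

## Community summaries

Simpson's `D = 1 − Σ pᵢ²` over the three canonical morphotype classes of
the resident population only; unobserved classes contribute p = 0, so
`0 ≤ D ≤ ⅔`. D is scale-invariant, hence identical on raw counts and
volume-standardized densities. Total resident density is
`log₁₀(cfu/ml + 1)`.

## Inference battery

All models are Gaussian OLS. Disturbance enters as a continuous regressor;
the default coding is **events per 16 days** (interval d → 16/d events),
chosen because treatments are described by how often disturbance occurs in
the fixed experimental window; interval-days and log₂(events) codings are
selectable, and slope magnitudes depend on this choice. Categorical
factors use treatment contrasts (reference: low resource, SM invader) for
coefficients; type III ANOVA internally refits with sum-to-zero contrasts,
under which its main-effect tests are meaningful. Success models use a
degree-1 disturbance term; diversity and density models default to
degree 2 (the disturbance–diversity relationship in this system is
unimodal), with likelihood-ratio backward selection deciding the retained
terms under marginality (no main effect is dropped while its interaction
remains; the quadratic counts as the linear term twice). For nested
Gaussian fits the LRT statistic is `n·ln(RSS₀/RSS₁)` on a χ² reference.

The full sequence (`run_full_analysis`): (1) assemble the per-microcosm
table of success, diversity and density; (2) fit success ~ disturbance ×
resource × invader type with type III ANOVA, falling back to type II when
no interaction is significant at α = 0.05; (3) given a significant
three-way interaction, refit per invader type and report the disturbance ×
resource interaction, per-resource slopes with t-based Wald 95% CIs
(significance = CI excluding zero), and Bonferroni-adjusted pairwise
comparisons of resource marginal means (model predictions averaged over
the observed values of all other predictors); (4) diversity and density
models per invader type with LRT selection; (5) resident-effect models —
success against diversity × density alone, then treatments plus resident
effects, type III→II.

Marginal means and slopes are computed by averaging model predictions over
the observed covariate distribution, so they are contrast-invariant;
per-resource slopes use an exact finite difference of the linear
predictor. Rank-deficient designs raise an error listing aliased columns.

## The mechanistic simulator

The simulator reproduces the *data-generating structure* of the
experiment, not its physiology. Per microcosm it tracks resident and
invader densities of SM/WS/FS and integrates, in 0.05-day exponential-
Euler steps:

* logistic broth growth toward a resource-dependent carrying capacity
  (K = 5×10⁷ / 5×10⁸ / 5×10⁹ cfu/ml for 1%/10%/100% medium, proportional
  to medium concentration) at maximal rates 8/11/14 per day for SM, with
  WS at 0.6× and FS at 0.7× (the competitor's growth cost);
* a **mat niche**: above 20% of K total density, WS gains access to an
  additional interface habitat (rate 1.2/day, capacity 25% of K) —
  mat formation requires a threshold density;
* **toxic-waste mortality**: a stale-culture stress accumulating with
  biomass between transfers (rate 0.4/day at saturation, scaled 1 / 0.45 /
  0.12 by medium concentration — rich cultures foul faster in absolute
  terms) and reset by transfer into fresh medium; it kills SM fastest
  (0.6 per unit toxin per day), FS at 0.25, WS — sheltered at the
  interface — at 0.02;
* SM → WS (2×10⁻⁴/day) and SM → FS (5×10⁻⁵/day) mutation;
* a resource-dependent **marker effect** on the invader's growth (×1.06
  in rich medium, ×1.0 at 10%, ×0.95 at 1%), standing in for the known
  non-neutrality of the colour marker;
* pulse disturbance (multiply by 0.01, binomially/Poisson-sampled cells
  when demographic noise is on; toxin reset) on multiples of the
  treatment interval, invasion inocula added post-disturbance on days
  4/8/12;
* plating: a decade dilution chosen to keep expected colonies within a
  countable window, counts Poisson-drawn per morphotype.

These ingredients jointly yield the study system's qualitative signatures:
frequent disturbance in rich medium favours the fast-growing (and
marker-advantaged) SM invader through repeated regrowth cycles; rare
disturbance in rich medium lets toxin accumulate and the mat form, so WS
sweeps and SM invaders fail; in poor medium the marker's slight cost makes
each regrowth cycle erode the SM invader, giving a negative disturbance
slope; and resident diversity is unimodal in disturbance (WS washed out at
high frequency, WS sweeping to near-monoculture at low frequency, mixtures
between). Parameters were tuned once to this qualitative pattern and live
in `SimulationConfig` with these defaults; they are artifact choices, not
measured *P. fluorescens* quantities.

Seeding: a master seed spawns per-microcosm streams via a stable hash of
(role, treatment, replicate), so enlarging the design never perturbs
existing microcosms and identical seeds give byte-identical CSV output.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: evolution beyond fixed mutation rates,
spatial mat structure, oxygen dynamics, measurement error other than
Poisson counting, day-to-day environmental variation, and any quantitative
calibration of growth parameters. Tests on simulated data demonstrate that
the estimators recover known structure, not that the biological
conclusions hold.

The parametric generator is simpler still: response = intercept +
slope(resource, invader) × coded disturbance + Gaussian noise, with the
default slope set taken from the study's reported per-resource slopes
(SM: 0.12, −0.048, −0.089; WS: −0.24, −0.033, −0.076 for high/medium/low)
so that recovery and coverage studies target realistic effect sizes
(default residual σ = 0.3, 6 replicates per cell).

## Numerical choices and problem sizes

* Sub-daily integration step 0.05 day; the exponential update preserves
  positivity and is stable for all default rates.
* Calibration of the three-way interaction test uses 1000 null replicates
  of the full parametric design (the binomial Monte-Carlo error of a
  200-replicate estimate is comparable to the ±0.02 acceptance band, so
  block estimates at that size fluctuate across the band by luck; 1000
  replicates make the verdict reliable without touching the band).
* Coverage uses 200 replicates × 3 resource levels; slope-bias checks use
  500 replicates at σ = 0.1; qualitative simulator checks average 20 full
  experiments.
* Ties and degenerate inputs: zero colony counts are valid (zero
  density); all-zero morphotype vectors make Simpson's D undefined
  (error, not NaN propagation); `x₁ ∉ (0,1)` or `x₂ = 1` flag the
  microcosm rather than producing infinities; LRT of a model against
  itself returns statistic 0, p = 1.

## Known limitations

* The numeric coding of disturbance frequency is a genuine degree of
  freedom; published slope magnitudes are only comparable under the same
  coding, which is why it is explicit and configurable.
* Type III tests require the internal sum-to-zero refit; user-supplied
  aliased designs error out rather than silently dropping terms.
* The mechanistic simulator's parameters are qualitative by design;
  quantitative agreement with any particular dataset is out of scope.
* Marginal means average over the observed covariate distribution (not a
  balanced reference grid); the two conventions coincide on balanced
  designs like the canonical one.
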