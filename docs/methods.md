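# Methods

This note documents the model, its synthetic inputs, the numerical
choices, and what the tests do and do not demonstrate.

## Model structure

The simulation is an annual-cycle, individual-level microsimulation of a
closed adult cohort. Each year, in order: (1) prices and the MUP
threshold are uprated by their inflation indices; (2) the policy
transform censors each price-paid distribution at the year's threshold;
(3) the percentage price change of each subgroup × beverage relative to
the *same-year control scenario* is converted into participation and
conditional consumption responses via the elasticity matrices and
applied to individuals; (4) drinker groups and hence subgroups are
reassigned; (5) lag-weighted effective consumption and per-condition
risks are evaluated; (6) stratum mortality and morbidity rates are
updated by the Potential Impact Fraction; (7) deaths are drawn and
removed; (8) survivors age one year, rescaling consumption on age-band
crossings; (9) outputs are recorded.

Because responses are driven by the contrast against the same-year
control prices, the control run itself carries only underlying (ageing)
dynamics, and the intervention effect is a pure policy contrast rather
than a compounding year-on-year shock. Policy-induced consumption
changes therefore persist exactly as long as the price contrast does.

### Price bookkeeping

Every price point stores its current price and its *original*
(never-censored) price, both uprated together. Introduction, increase,
reduction and removal of the MUP all reduce to
`current = max(original, threshold)`, which makes removal restore the
uprated original prices exactly and makes reductions re-bind at the new
threshold without any purchase-mass accounting ambiguity. Prices are
held in pence as floats with an epsilon guard on threshold comparisons;
generated points sit on an integer-pence (£0.01) grid so thresholds off
£0.10 band edges (e.g. £0.65) partition the mass exactly.

### Participation mechanism

Published participation elasticities are per beverage, but participation
itself (drinking at all) is a single state. The engine collapses the
per-beverage participation responses into one individual-level response
using the individual's own units mix as weights (the subgroup's mean
drinker mix for abstainers). Exits are drawn uniformly at random among a
subgroup's drinkers with probability equal to the percentage decline;
entries assign the slice's mean drinker profile with probability scaled
by the drinker/abstainer odds so the drinker share rises by the stated
percentage in expectation. A persistent per-individual uniform drives
these switches inside the engine, so the same individuals remain
switched while a policy persists and revert when it is removed.

### Harm model

Conditions fall in four categories:

- **partial-chronic**: log-quadratic relative risk,
  `ln RR = β₁x + β₂x²` on lag-weighted weekly units; β₂ > 0 with β₁ < 0
  gives the J-shaped (cardioprotective) curves used for ischaemic heart
  disease and ischaemic stroke.
- **partial-acute**: an occasion model converts weekly units into
  drinking occasions (gamma-distributed sizes whose mean grows with
  weekly intake; occasion frequency preserves annual intake = 52 ×
  weekly units) and the annual RR is
  `1 + (RR_binge − 1) × E[binges/year]`, a binge being an occasion above
  8 units.
- **wholly-chronic**: absolute-risk multiplier `(x/x_ref)^γ`, zero at
  zero consumption.
- **wholly-acute**: multiplier proportional to expected annual binges.

Lag curves are piecewise-linear cumulative weights reaching 1 after 10
years (chronic), 20 years (cancers) or 1 year (acute); they are
config-supplied, these being documented defaults rather than estimates.
Effective consumption applies each year-on-year change in proportion to
the cumulative lag weight at its age, with the earliest recorded year
treated as fully lagged in.

Stratum rates (age band × sex × SIMD quintile) are scaled by
`Σw·RR_scenario / Σw·RR_control` (the 1 − PIF factor) and distributed to
individuals proportionally to their own RR, so wholly-attributable
hazards are identically zero for never-drinkers. The per-individual
annual death probability is `1 − exp(−Σ_c hazard_c − background)`;
cause of death is allocated proportionally to cause-specific hazards
(the competing-risk rule). A background (non-alcohol) mortality rate —
Gompertz in age with sex and deprivation gradients — makes overall
deaths and person-years meaningful.

### Common random numbers

All stochastic draws (participation switches, death uniforms, cause
uniforms) come from streams keyed by (seed, year, purpose) and are
identical across scenarios run with the same seed. An intervention
identical to the control therefore produces *exactly* zero differences,
and death differences between thresholds are nearly nested, which is
what makes threshold orderings detectable at moderate population sizes.

## Synthetic inputs

The generator emulates the structure of the real appraisal inputs
without any access to them:

- **Population.** Income quintile uniform; SIMD quintile joint with
  income by iterative proportional fitting at 60% concordance, with the
  SIMD marginal implied by the published drinker shares and abstention
  rates. Abstention is *aligned*: each quintile receives exactly its
  calibrated abstainer count, membership random. Drinker-group shares
  per quintile scale the hazardous/harmful shares so that quintile mean
  consumption matches the calibrated means exactly in expectation.
  Within-group consumption uses Beta draws on the group interval
  (moderate, hazardous) and a shifted exponential (harmful), with means
  matching the calibrated group means. Beverage mix is a drinker-group
  level Dirichlet around documented default shares. Smoking groups are
  uniform and affect only baseline rates.
- **Price distributions.** Band masses by drinker group × SIMD are
  fitted by IPF to both published margins; because distributions are
  keyed by income-based subgroups whose members span SIMD quintiles, the
  fitted cells are deconvolved through the income→SIMD mixing matrix so
  the *population-weighted aggregates* reproduce both margins within
  ±0.5 pp. A configurable fraction (default 35%) of each 50–60p band
  carries original prices of 30–49p, so the 2018 £0.50 step is
  non-trivial. The open 80p+ band uses a wider grid for on-trade
  beverages (to £4.50/unit) than off-trade (to £1.80/unit).
- **Conditions.** 45 conditions across liver disease, mental &
  behavioural disorders due to alcohol, cancers, cardiovascular,
  injuries and other; 6 wholly-chronic, 3 wholly-acute, 24
  partial-chronic, 12 partial-acute. Risk slopes are jittered ±10% by
  seed around documented central values.
- **Inflation** is constant-rate (RPI 3.5%/yr, CPIH 2.5%/yr, base
  2017); the **life table** declines ~0.82 years of remaining
  expectancy per year of age from 63/59 (female/male) at 18.
- **Elasticities.** The packaged matrices are synthetic with
  conventional signs: conditional own-price −0.4 to −0.9, participation
  own-price −0.08 to −0.17, small positive cross terms. The
  "alternative" set scales the base magnitudes by 0.35. Published
  matrices can be supplied as CSV.

## What the defaults do and do not show

With these synthetic inputs the model reproduces the appraisal's
*qualitative* results: consumption and death effects monotone in the
threshold, sign reversal under removal, larger effects in more deprived
quintiles, a shrinking harmful-drinker group, a partial cardiovascular
offset, and the rising lag profile of deaths averted. It does **not**
reproduce the published headline magnitudes (e.g. the −12.0%
consumption change at £0.65): those depend on the non-public purchase
and survey microdata and the published elasticity values. Two visible
consequences of the defaults: effect magnitudes are roughly an order of
magnitude smaller, and spending *rises* with the threshold (the
packaged matrices are net inelastic, |row sum| < 1) where the published
base case prints small spending declines. Conclusions about magnitudes
should not be read off this artifact.

## Numerical choices

- Drinker-group intervals are half-open, closed above: moderate =
  (0, 14], hazardous = (14, 35] women / (14, 50] men; exactly 14
  units/week is moderate.
- The PIF denominator is guarded at 1e-12; a zero denominator in the
  public function raises.
- Death probabilities are clipped to [0, 1] with a logged warning if
  negative hazards appear (they cannot under the packaged inputs).
- Weighted death counts are integer multiples of the per-row weight;
  ordering tests quantise to whole persons to avoid float-sum ties.
- Individuals dying in year *t* contribute the full person-year of *t*.
- The cohort is closed: no births, immigration or replenishment with new
  18-year-olds (a hook exists but is off by default).
- Default problem sizes: 20,000 individuals for appraisal runs (results
  scale-checked against 200,000 at generation level), 200,000 for
  baseline calibration measurements; the full horizon is 2017–2040 with
  policy divergence from 2019.

## Known limitations

- Beverage-level band shares are identical within a subgroup except for
  the on-/off-trade tail of the 80p+ band; real purchasing data would
  differentiate more.
- The income→SIMD deconvolution clips negative solutions, so extreme
  (near-degenerate) band targets can shift aggregates slightly; with
  the packaged targets the error is <0.4 pp.
- Participation and conditional effects are applied in a single linear
  step per annual cycle; very large price changes would warrant a
  compounding or arc-elasticity treatment.
- No supply-side responses, product reformulation, cross-border
  purchasing, income effects, or within-year dynamics.
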