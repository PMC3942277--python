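# Methods

## State space and bookkeeping

The public state space is (health state × treatment line): 12 alive states
per line — stable AF, seven one-cycle acute tunnel states (major/minor
ischemic stroke, systemic embolism, myocardial infarction, minor/major
extracranial bleed, intracranial bleed) and four chronic post-event states
(post major stroke, post minor stroke, post MI, post IC bleed) — plus two
absorbing dead states (event-related vs other-cause), 26 compartments in
all.

A patient occupies at most one chronic state. A new permanent event
overwrites it by severity priority (post major stroke > post IC bleed >
post MI > post minor stroke), so a post-MI patient who suffers a major
stroke becomes post-major-stroke, while an MI in a post-major-stroke
patient leaves the chronic state unchanged. Survivors of transient events
(SE, extracranial bleeds) return to the chronic state they came from.
Because the origin of an acute tunnel is not part of the public label, the
engine internally tracks (chronic state × pending event × line) — 82
compartments — and reports traces on the 26-compartment aggregation. The
individual-level oracle (below) uses the same overwrite rule, so the
comparison isolates traversal errors only.

Within a cycle, the competing exits from a chronic state are the acute
event probabilities, the chronic excess mortality, and background
mortality, treated additively (proportionally rescaled in the rare case the
sum exceeds 1, which happens only at extreme ages). Permanent
discontinuation (first-line → second-line) applies to event-free survivors
only and is independent of events. Acute tunnels resolve within the event
cycle: case fatality to event death, survivors onward; IC-bleed survivors
stop oral anticoagulation with probability 1 (configurable). Background
mortality does not additionally act inside the one-cycle tunnel. No
half-cycle correction is applied in the base case (an option exists in
`ModelSettings`); state membership is valued at cycle start.

## Key parameters (defaults)

| Parameter | Default | Unit / note |
|---|---|---|
| Cycle length | 3 months | all probabilities per cycle |
| Start / terminal age | 75 / 110 | residual mass forced to death at 110 |
| Discount rate | 3.5%/yr | costs and outcomes, `(1+r)^(−t/4)` |
| VKA per-cycle event risks | 0.40 / 0.28 / 0.05 / 0.19 / 2.97 / 0.69 % | IS / MI / SE / IC / minor EC / major EC |
| Rivaroxaban RRs (on-treatment) | 0.94, 0.81, 0.23, 0.67, 1.04, 1.14 | multiplicative on per-cycle risk |
| Discontinuation | 8.9%/8.0% first cycle; 4.39%/4.46% later | rivaroxaban / VKA, per cycle |
| Baseline utility | 0.779 | VKA multiplies all alive states by 0.95 |
| Drug cost | €2.16 / €0.05 / €0 per day | rivaroxaban / VKA / second line |
| VKA monitoring | 6 visits init. cycle, 3 per maint. cycle | first visit €32, later €22, INR-inclusive |
| Transport | 50% uptake × €70/visit | VKA visits only, booked under monitoring |
| Stroke split | 70% of IS major | calibrated, documented range 0.3–0.7 |
| Major-stroke acute cost | severe DRG tier (€2,475) | minor event: €900 |

The RR is applied on the probability scale with a clamp at 1; at these
per-cycle risks (≤3%) the clamp never binds and the difference from
rate-space application is negligible. The persistence conversion
`1 − (y/x)^(1/3)` maps 3- and 12-month persistence proportions to the
constant per-cycle discontinuation probability over the last three quarters
of year one; the engine consumes the four per-cycle probabilities directly.
The payer drug-price rule (reference price minus 25% co-payment plus half
of any retail–reference gap, then entry/volume rebates multiplicatively)
is implemented in `payer_drug_cost_per_day`; with no listed reference price
the retail price applies, which is the base case for both drugs. Visit
tariffs are treated as INR-inclusive; an additive per-visit INR test cost
exists and defaults to €0.

## Synthetic inputs and calibration

Two inputs required by the structure are not part of the published
parameter set and are shipped as clearly-labelled synthetic fixtures:

* **Background life table** — Gompertz annual probabilities
  `q(a) = min(1, q0·e^{g(a−75)})` with `q0 = 0.030`, `g = 0.11`, terminal
  age 110. This is a calibration fixture, not demographic data.
* **Second-line event rates** — the on-VKA baseline with ischemic events
  (IS, SE) × 2.0 and bleeds × 0.5 for aspirin (× 2.8 / × 0.25 for no
  treatment), reflecting that aspirin preserves roughly half of the
  anticoagulant's stroke protection with about half the bleeding.

These, the major-stroke fraction (0.7) and the severe-tier costing of major
strokes were fixed once, by calibrating the base case to the reference
evaluation's headline outputs (discounted QALYs ≈ 6.5, ΔQALY ≈ 0.2,
rivaroxaban total cost ≈ €7.9k), and are not revisited per analysis. A
known limitation: under discounting and any non-trivial elderly mortality,
the printed per-cycle discontinuation probabilities cap discounted
first-line exposure near 18 cycles, so the model's incremental acquisition
(≈ €3.0k) and monitoring (≈ €2.8k) components — and hence the small net
saving (≈ €46) and the ITT-scenario classification — sit materially below
the reference component table, which is arithmetically consistent only
with near-undiscounted accumulation. No knob in the documented calibration
ranges moves the net cost difference by more than ~€15.

## What the generator and tests do and do not show

The degenerate fixtures (`no_events`, `no_death`, `null_effect`,
`zero_costs`, `jittered`) exercise every pipeline stage against closed
forms: geometric survival and the discounted life-year series, utility ×
time QALY accrual, arm symmetry under a null effect, and cost-decomposition
conservation (components sum to totals within €0.01; occupancy rows sum to
1 within 1e-9). The microsimulation oracle re-traverses the same
per-compartment transition distributions individual-by-individual
(n = 50,000, 40 cycles) and must agree with the cohort trace within three
binomial standard errors per compartment-cycle, allowing only the handful
of chance exceedances expected across ~800 simultaneous comparisons (hard
cap four standard errors). Passing these shows the engine propagates its
inputs correctly; it does not validate the inputs themselves against real
patients — event rates come from one trial population, utilities from
heterogeneous literature sources, and the synthetic life table and
second-line rates are assumptions.

## Uncertainty analysis choices

* **PSA** (default 1,000 iterations): beta for probabilities and utilities,
  gamma for unit costs, lognormal for RRs with location `ln(point)` and
  scale `(ln hi − ln lo)/(2·1.959964)`. Where no interval is published the
  standard error defaults to 20% of the mean. The VKA utility multiplier is
  sampled through its disutility complement (1 − 0.95), keeping draws in a
  plausible 0.90–1.00 band. Administered drug prices and the discount rate
  are fixed. Parameters are sampled independently (no correlation
  information is available). All draws come from one seeded generator in a
  fixed order: identical (seed, n) give bit-identical outputs.
* **CEAC**: fraction of draws with `λ·ΔQALY − ΔC ≥ 0`; ties count as
  cost-effective.
* **OWSA**: one parameter at a time at its published low/high (95% CI for
  efficacy parameters, reported ranges otherwise; ±20% convention where
  nothing is reported). "Rivaroxaban effectiveness" is a global multiplier
  on all rivaroxaban RRs. An optional filter reports only parameters moving
  the ICER by more than a chosen amount (the reference used €1,000).
* **Scenarios**: ITT effect estimates (efficacy endpoints only — bleeding
  endpoints keep on-treatment values), switch-to-nothing second line,
  no VKA disutility, 9% and 14% manufacturer rebates.

## Numerical notes

* Transition matrices are cached per (integer age, first-cycle flag); a
  lifetime run is ~140 sparse-ish 82×82 products and takes ~25 ms, so the
  1,000-iteration PSA completes in well under a minute.
* The cohort loop stops early once alive mass < 1e-6; at the terminal age
  any residual alive mass is moved to other-cause death.
* Degenerate incremental comparisons (ΔQALY exactly 0) are flagged and
  classified by cost sign; the ICER is reported as undefined.
* Problem sizes used in validation: 50,000 individuals × 40 cycles for the
  oracle comparison; 100,000 draws for distribution-recovery checks; 1,000
  PSA iterations for the acceptability curve.
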