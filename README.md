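# afcea — cost-utility model of anticoagulation in atrial fibrillation

`afcea` is a lifetime Markov cohort model comparing rivaroxaban (a fixed-dose
oral factor-Xa inhibitor) with dose-adjusted vitamin-K antagonists (VKA,
acenocoumarol) for stroke prevention in non-valvular atrial fibrillation,
from the perspective of a third-party public payer (Greek 2013 tariffs and
prices). It is aimed at health-economics analysts who want a transparent,
fully scriptable re-implementation of this class of evaluation: base-case
cost-utility analysis, scenario analyses, one-way (tornado) sensitivity
analysis, and probabilistic sensitivity analysis (PSA) with
cost-effectiveness acceptability curves (CEAC).

## Model

A cohort of 75-year-old patients with uncomplicated AF moves through
quarterly cycles until death (horizon: age 110). Each cycle a patient can
remain stable, suffer one acute complication — major/minor ischemic stroke
(IS), systemic embolism (SE), myocardial infarction (MI), intracranial (IC)
bleed, major/minor extracranial (EC) bleed — or die from the event,
event-related excess mortality, or background causes. Acute events occupy a
one-cycle tunnel state carrying the event's DRG cost and acute utility;
major IS, IC bleed and MI leave chronic post-event states with follow-up
cost, reduced utility and excess mortality. Patients may permanently stop
their first-line drug (trial-based per-cycle probabilities, IC-bleed
survivors always stop) and continue on a second line (aspirin or nothing).

Per-cycle probabilities come from annual rates via
`q = 1 − (1 − p)^(1/4)`; rivaroxaban applies trial relative risks
multiplicatively to the VKA baseline. Being on VKA carries a treatment
disutility (utility × 0.95) and an INR-monitoring schedule (six visits in
the initiation cycle, three per maintenance cycle, half the patients using
payer-funded transport at €70/visit). Outcomes are discounted
quality-adjusted life years (QALYs), life years, and costs decomposed into
drug acquisition, monitoring (incl. transport) and event management, all at
3.5% per year. Strategies are compared by dominance or the incremental
cost-effectiveness ratio ICER = ΔC/ΔE; the PSA samples beta (probabilities,
utilities), lognormal (relative risks, from their 95% CIs) and gamma (unit
costs) distributions and reports the probability of a non-negative net
monetary benefit `λ·ΔQALY − ΔC` over a willingness-to-pay grid.

Background all-cause mortality and off-treatment event rates are not part
of the published inputs; the package ships clearly-labelled synthetic
fixtures for both (a Gompertz life table and ratio-derived second-line rate
tables), calibrated once within documented ranges (see
`docs/methods.md`).

## Worked example

```python
from afcea import load_base_case, compare_strategies

params = load_base_case()
riva, vka, inc = compare_strategies(params)
print(f"riva: €{riva.cost_total:.0f}, {riva.qaly_discounted:.2f} QALYs")
print(f"vka:  €{vka.cost_total:.0f}, {vka.qaly_discounted:.2f} QALYs")
print(f"ΔC = €{inc.delta_cost:.0f}, ΔQALY = {inc.delta_qaly:.2f} "
      f"→ {inc.classification}")
```

prints

```
riva: €7862, 6.53 QALYs
vka:  €7908, 6.32 QALYs
ΔC = €-46, ΔQALY = 0.21 → dominant
```

i.e. over a lifetime the rivaroxaban strategy costs slightly less than the
VKA strategy (its ~€2,990 extra acquisition cost is offset by ~€2,764 lower
monitoring/transport cost and ~€273 lower event-management cost) and yields
0.21 additional QALYs — rivaroxaban *dominates* (cheaper and more
effective), so no ICER is defined.

The same analyses from the shell:

```bash
afcea run                     # base case, traces + results + manifest
afcea run --scenario itt_none # an intention-to-treat scenario
afcea owsa                    # tornado CSV over the default plan
afcea psa --n 1000 --seed 42  # PSA samples, CEAC CSV and plot
afcea validate my_config.yaml
```

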