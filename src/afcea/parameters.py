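"""Model inputs for the anticoagulation cost-utility model.

All quantities live on a quarterly (3-month) cycle unless stated otherwise.
Event probabilities are per-cycle probabilities, not rates; treatment effects
are relative risks applied multiplicatively on the per-cycle probability.
Costs are 2013 euros from the public third-party-payer perspective: drug
acquisition, monitoring visits (INR-inclusive), acute event tariffs (DRG),
chronic follow-up care and payer-sponsored patient transport.
"""

from __future__ import annotations

import math
from typing import Literal, NamedTuple, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

CYCLES_PER_YEAR = 4
CYCLE_YEARS = 0.25
DAYS_PER_CYCLE = 365.25 / CYCLES_PER_YEAR

Probability = Field(ge=0.0, le=1.0)


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class EventRateTable(_Model):
    """Per-cycle probabilities of acute clinical events on a given therapy."""

    ischemic_stroke: float = Probability
    myocardial_infarction: float = Probability
    systemic_embolism: float = Probability
    intracranial_bleed: float = Probability
    minor_extracranial_bleed: float = Probability
    major_extracranial_bleed: float = Probability


class RelativeRisk(_Model):
    """Point estimate with 95% CI bounds, all on the risk-ratio scale."""

    point: float = Field(gt=0.0)
    lo: float = Field(gt=0.0)
    hi: float = Field(gt=0.0)

    @model_validator(mode="after")
    def _ordered(self) -> "RelativeRisk":
        if not (self.lo <= self.point <= self.hi):
            raise ValueError(
                f"CI must bracket the point estimate: {self.lo} <= {self.point} <= {self.hi}"
            )
        return self


class TreatmentEffect(_Model):
    """Relative risks of rivaroxaban vs VKA per event type."""

    rr_is: RelativeRisk
    rr_mi: RelativeRisk
    rr_se: RelativeRisk
    rr_ic: RelativeRisk
    rr_major_ec: RelativeRisk
    rr_minor_ec: RelativeRisk
    population_tag: Literal["SOT", "ITT"] = "SOT"


class MortalityModel(_Model):
    """Event case fatality, chronic excess mortality and background mortality.

    Case fatalities apply once, within the acute event cycle.  Post-event
    excess probabilities apply every cycle spent in the corresponding chronic
    state, additively to background all-cause mortality.  The life table maps
    integer age to the annual all-cause death probability and must reach 1.0
    at its terminal age.
    """

    case_fatality_major_stroke: float = Probability
    case_fatality_minor_stroke: float = Probability
    case_fatality_major_bleed: float = Probability
    case_fatality_minor_bleed: float = Probability
    case_fatality_ic_bleed: float = Probability
    case_fatality_se: float = Probability
    case_fatality_mi: float = Probability
    post_major_stroke_excess: float = Probability
    post_minor_stroke_excess: float = Probability
    post_ic_excess: float = Probability
    post_mi_excess: float = Probability
    life_table: dict[int, float]
    start_age: int = Field(ge=0)

    @model_validator(mode="after")
    def _table_valid(self) -> "MortalityModel":
        if not self.life_table:
            raise ValueError("life_table must be non-empty")
        ages = sorted(self.life_table)
        for a in ages:
            q = self.life_table[a]
            if not (0.0 <= q <= 1.0):
                raise ValueError(f"life_table[{a}]={q} outside [0, 1]")
        if self.start_age < ages[0]:
            raise ValueError(
                f"life_table starts at {ages[0]} but start_age is {self.start_age}"
            )
        if self.life_table[ages[-1]] != 1.0:
            raise ValueError("life_table must end with annual probability 1.0")
        if ages != list(range(ages[0], ages[-1] + 1)):
            raise ValueError("life_table must cover consecutive integer ages")
        return self

    @property
    def terminal_age(self) -> int:
        return max(self.life_table)


class UtilitySet(_Model):
    """EQ-5D-style utilities on the 0 (dead) .. 1 (full health) scale.

    Acute utilities replace the chronic-state utility for the event cycle.
    The VKA multiplier expresses the treatment-related disutility of being
    on a vitamin-K antagonist and applies to every alive state while on
    first-line VKA (``vka_disutility_mode`` switches to subtracting
    ``1 - vka_multiplier`` instead of multiplying).
    """

    baseline: float = Probability
    vka_multiplier: float = Probability
    vka_disutility_mode: Literal["multiplicative", "additive"] = "multiplicative"
    acute_major_is: float = Probability
    acute_minor_is: float = Probability
    acute_mi: float = Probability
    acute_minor_bleed: float = Probability
    acute_major_bleed: float = Probability
    acute_ic: float = Probability
    acute_se: float = Probability
    post_minor_is: float = Probability
    post_major_is: float = Probability
    post_mi: float = Probability
    post_ic: float = Probability


NonNegative = Field(ge=0.0)


class CostSet(_Model):
    """Unit costs (€, 2013) and the payer pricing/monitoring schedule knobs."""

    drug_daily_riva: float = NonNegative
    drug_daily_vka: float = NonNegative
    drug_daily_secondline: float = NonNegative
    visit_cost_vka_first: float = NonNegative
    visit_cost_vka_subsequent: float = NonNegative
    visit_cost_other: float = NonNegative
    inr_test_cost: float = 0.0
    acute_minor_is: float = NonNegative
    acute_moderate_is: float = NonNegative
    acute_severe_is: float = NonNegative
    acute_se: float = NonNegative
    acute_ic: float = NonNegative
    acute_minor_ec: float = NonNegative
    acute_major_ec: float = NonNegative
    acute_mi: float = NonNegative
    followup_major_stroke: float = NonNegative
    followup_ic: float = NonNegative
    followup_mi: float = NonNegative
    transport_cost_per_visit: float = NonNegative
    transport_uptake: float = Probability
    rebate_entry: float = Probability
    rebate_volume: float = Probability
    copay_rate: float = Probability
    maintenance_visits_per_cycle_vka: float = NonNegative
    other_visits_per_cycle: float = NonNegative


class PersistenceModel(_Model):
    """Permanent treatment discontinuation and the second-line therapy."""

    disc_first_cycle_riva: float = Probability
    disc_first_cycle_vka: float = Probability
    disc_subsequent_riva: float = Probability
    disc_subsequent_vka: float = Probability
    second_line: Literal["aspirin", "none"] = "aspirin"
    ic_bleed_discontinuation_prob: float = 1.0

    @model_validator(mode="after")
    def _ic_prob(self) -> "PersistenceModel":
        if not (0.0 <= self.ic_bleed_discontinuation_prob <= 1.0):
            raise ValueError("ic_bleed_discontinuation_prob outside [0, 1]")
        return self


class ModelSettings(_Model):
    """Global run settings: discounting, horizon, thresholds, stroke splits."""

    discount_rate_annual: float = Field(ge=0.0)
    terminal_age: int = 110
    wtp_grid: list[float] = Field(default_factory=lambda: [30_000.0, 40_000.0, 60_000.0])
    stroke_major_fraction: float = Probability
    major_stroke_cost_weights: dict[str, float] = Field(
        default_factory=lambda: {"moderate": 0.5, "severe": 0.5}
    )
    minor_stroke_cost_weights: dict[str, float] = Field(
        default_factory=lambda: {"minor": 1.0}
    )
    half_cycle_correction: bool = False

    @model_validator(mode="after")
    def _weights(self) -> "ModelSettings":
        for name, w in (
            ("major_stroke_cost_weights", self.major_stroke_cost_weights),
            ("minor_stroke_cost_weights", self.minor_stroke_cost_weights),
        ):
            bad = set(w) - {"minor", "moderate", "severe"}
            if bad:
                raise ValueError(f"{name}: unknown severity tier(s) {sorted(bad)}")
            if any(v < 0 for v in w.values()):
                raise ValueError(f"{name}: negative weight")
            if abs(sum(w.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name}: weights must sum to 1")
        return self


class ParameterSet(_Model):
    """The complete, validated input bundle for one model run."""

    event_rates_vka: EventRateTable
    event_rates_secondline: EventRateTable
    effect: TreatmentEffect
    mortality: MortalityModel
    utilities: UtilitySet
    costs: CostSet
    persistence: PersistenceModel
    settings: ModelSettings

    @model_validator(mode="after")
    def _consistent(self) -> "ParameterSet":
        if self.settings.terminal_age > self.mortality.terminal_age:
            raise ValueError(
                "settings.terminal_age exceeds the life table's terminal age"
            )
        return self


# ---------------------------------------------------------------------------
# Rate and persistence conversions
# ---------------------------------------------------------------------------

def annual_to_cycle_probability(annual: float) -> float:
    """Convert an annual event probability to the quarterly-cycle scale.

    Uses the constant-hazard identity ``q = 1 - (1 - p)**(1/4)``.
    """
    if not 0.0 <= annual <= 1.0:
        raise ValueError(f"annual probability {annual} outside [0, 1]")
    return 1.0 - (1.0 - annual) ** (1.0 / CYCLES_PER_YEAR)


def cycle_to_annual_probability(cycle: float) -> float:
    """Inverse of :func:`annual_to_cycle_probability`."""
    if not 0.0 <= cycle <= 1.0:
        raise ValueError(f"cycle probability {cycle} outside [0, 1]")
    return 1.0 - (1.0 - cycle) ** CYCLES_PER_YEAR


class DiscontinuationRates(NamedTuple):
    first_cycle: float
    subsequent: float


def subsequent_discontinuation(persist_3mo: float, persist_12mo: float) -> DiscontinuationRates:
    """Per-cycle permanent discontinuation from persistence proportions.

    Given the proportion still on therapy at 3 months (``x``) and at 12
    months (``y``), the first-cycle discontinuation probability is ``1 - x``
    and the constant per-cycle probability over the remaining three quarters
    of the first year is ``1 - (y/x)**(1/3)``.
    """
    x, y = persist_3mo, persist_12mo
    if not (0.0 < x <= 1.0) or not (0.0 <= y <= 1.0):
        raise ValueError("persistence proportions must lie in (0, 1]")
    if y > x:
        raise ValueError(
            f"12-month persistence ({y}) cannot exceed 3-month persistence ({x})"
        )
    return DiscontinuationRates(1.0 - x, 1.0 - (y / x) ** (1.0 / 3.0))


def treated_event_probability(baseline: float, rr: float) -> float:
    """Apply a relative risk to a per-cycle baseline probability.

    Multiplicative on the probability scale, clamped at certainty.  With the
    quarterly baseline risks of this model (all below 3%) the clamp is never
    active for any plausible RR.
    """
    if not 0.0 <= baseline <= 1.0:
        raise ValueError(f"baseline probability {baseline} outside [0, 1]")
    if rr < 0.0:
        raise ValueError(f"relative risk {rr} is negative")
    return min(1.0, baseline * rr)


def treated_event_rates(
    baseline: EventRateTable, effect: TreatmentEffect, effectiveness: float = 1.0
) -> EventRateTable:
    """Baseline per-cycle rates scaled by the treatment's relative risks.

    ``effectiveness`` is a global multiplier on every RR (1.0 = the trial
    estimate), used by the one-way sensitivity analysis.
    """
    return EventRateTable(
        ischemic_stroke=treated_event_probability(
            baseline.ischemic_stroke, effect.rr_is.point * effectiveness
        ),
        myocardial_infarction=treated_event_probability(
            baseline.myocardial_infarction, effect.rr_mi.point * effectiveness
        ),
        systemic_embolism=treated_event_probability(
            baseline.systemic_embolism, effect.rr_se.point * effectiveness
        ),
        intracranial_bleed=treated_event_probability(
            baseline.intracranial_bleed, effect.rr_ic.point * effectiveness
        ),
        minor_extracranial_bleed=treated_event_probability(
            baseline.minor_extracranial_bleed, effect.rr_minor_ec.point * effectiveness
        ),
        major_extracranial_bleed=treated_event_probability(
            baseline.major_extracranial_bleed, effect.rr_major_ec.point * effectiveness
        ),
    )


# ---------------------------------------------------------------------------
# Payer cost rules
# ---------------------------------------------------------------------------

def payer_drug_cost_per_day(
    retail: float,
    reference: Optional[float] = None,
    copay_rate: float = 0.25,
    rebate_entry: float = 0.0,
    rebate_volume: float = 0.0,
) -> float:
    """Daily drug cost borne by the payer under the internal reference-price
    system.

    With a reference (reimbursement) price, the payer covers the reference
    price net of the patient co-payment, plus half of any positive gap
    between retail and reference.  Without a listed reference price the full
    retail price applies.  Manufacturer rebates (positive-list entry rebate
    and volume rebate) then reduce the payer cost multiplicatively.
    """
    if retail < 0 or (reference is not None and reference < 0):
        raise ValueError("prices must be non-negative")
    for name, f in (("copay_rate", copay_rate), ("rebate_entry", rebate_entry),
                    ("rebate_volume", rebate_volume)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name}={f} outside [0, 1]")
    if reference is None:
        payer = retail
    elif retail > reference:
        payer = reference * (1.0 - copay_rate) + 0.5 * (retail - reference)
    else:
        payer = reference * (1.0 - copay_rate)
    return payer * (1.0 - rebate_entry) * (1.0 - rebate_volume)


class MonitoringCost(NamedTuple):
    monitoring: float
    transport: float


def monitoring_cost_per_cycle(
    treatment_line: Literal["vka", "riva", "secondline"],
    phase: Literal["initiation", "maintenance"],
    costs: CostSet,
) -> MonitoringCost:
    """Per-cycle monitoring and payer-transport cost for one therapy.

    VKA initiation assumes one weekly INR visit during the first month (the
    first at the higher first-visit tariff) and monthly visits thereafter:
    six visits in the first quarterly cycle, then
    ``maintenance_visits_per_cycle_vka`` per cycle.  Rivaroxaban and the
    second-line therapy need no INR monitoring, only routine visits.
    Transport is payer-reimbursed only for the frequent VKA clinic visits.
    """
    if treatment_line == "vka":
        if phase == "initiation":
            visits = 6.0
            monitoring = (
                costs.visit_cost_vka_first + 5.0 * costs.visit_cost_vka_subsequent
            )
        else:
            visits = costs.maintenance_visits_per_cycle_vka
            monitoring = visits * costs.visit_cost_vka_subsequent
        monitoring += visits * costs.inr_test_cost
        transport = visits * costs.transport_uptake * costs.transport_cost_per_visit
    elif treatment_line in ("riva", "secondline"):
        monitoring = costs.other_visits_per_cycle * costs.visit_cost_other
        transport = 0.0
    else:
        raise ValueError(f"unknown treatment line {treatment_line!r}")
    return MonitoringCost(monitoring, transport)


def acute_stroke_costs(costs: CostSet, settings: ModelSettings) -> tuple[float, float]:
    """(major, minor) acute ischemic-stroke cost from the severity-tier mix."""
    tiers = {
        "minor": costs.acute_minor_is,
        "moderate": costs.acute_moderate_is,
        "severe": costs.acute_severe_is,
    }
    major = sum(w * tiers[k] for k, w in settings.major_stroke_cost_weights.items())
    minor = sum(w * tiers[k] for k, w in settings.minor_stroke_cost_weights.items())
    return major, minor


def strategy_drug_cost_per_day(strategy: str, costs: CostSet) -> float:
    """Payer daily acquisition cost for the first-line drug of a strategy."""
    if strategy == "riva":
        retail = costs.drug_daily_riva
    elif strategy == "vka":
        retail = costs.drug_daily_vka
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return payer_drug_cost_per_day(
        retail,
        reference=None,
        copay_rate=costs.copay_rate,
        rebate_entry=costs.rebate_entry,
        rebate_volume=costs.rebate_volume,
    )


def discount_factor(cycle_index: int, annual_rate: float) -> float:
    """Discount multiplier for a cycle index (quarterly compounding of the
    annual rate): ``(1 + r)**(-t/4)``."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    return (1.0 + annual_rate) ** (-cycle_index / CYCLES_PER_YEAR)
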