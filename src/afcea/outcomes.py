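"""Aggregation of a cohort trace into QALYs, life-years, costs and events,
plus the incremental cost-effectiveness comparison."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .cohort import ALIVE_STATES, CohortTrace, TREATMENT_LINES
from .parameters import (
    CYCLE_YEARS,
    DAYS_PER_CYCLE,
    ParameterSet,
    UtilitySet,
    acute_stroke_costs,
    monitoring_cost_per_cycle,
    payer_drug_cost_per_day,
    strategy_drug_cost_per_day,
)


@dataclass
class StrategyResult:
    """Discounted and undiscounted lifetime outcomes for one strategy.

    Costs are decomposed into drug acquisition, monitoring (payer transport
    included) and event management (acute episodes plus chronic follow-up
    care); the components always sum to the total.
    """

    strategy: str
    qaly_discounted: float
    qaly_undiscounted: float
    ly_discounted: float
    ly_undiscounted: float
    cost_total: float
    cost_acquisition: float
    cost_monitoring: float
    cost_events: float
    cost_total_undiscounted: float
    expected_strokes: float
    expected_bleeds: float
    expected_events: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class IncrementalResult:
    """Pairwise comparison of a new strategy against a comparator.

    ``classification`` is ``dominant`` (cheaper and more effective),
    ``dominated`` (the reverse) or ``icer``.  When the QALY difference is
    exactly zero the ICER is undefined and ``degenerate`` is set; the
    classification then follows the sign of the cost difference alone.
    """

    new: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    classification: str
    icer_per_qaly: Optional[float] = None
    icer_per_ly: Optional[float] = None
    degenerate: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


def _state_utilities(u: UtilitySet) -> dict[str, float]:
    return {
        "stable_af": u.baseline,
        "acute_major_is": u.acute_major_is,
        "acute_minor_is": u.acute_minor_is,
        "acute_se": u.acute_se,
        "acute_mi": u.acute_mi,
        "acute_minor_ec": u.acute_minor_bleed,
        "acute_major_ec": u.acute_major_bleed,
        "acute_ic": u.acute_ic,
        "post_major_is": u.post_major_is,
        "post_minor_is": u.post_minor_is,
        "post_mi": u.post_mi,
        "post_ic": u.post_ic,
    }


def _acute_event_costs(params: ParameterSet) -> dict[str, float]:
    c = params.costs
    major_is, minor_is = acute_stroke_costs(c, params.settings)
    return {
        "major_is": major_is,
        "minor_is": minor_is,
        "se": c.acute_se,
        "mi": c.acute_mi,
        "minor_ec": c.acute_minor_ec,
        "major_ec": c.acute_major_ec,
        "ic": c.acute_ic,
    }


def accumulate_outcomes(
    trace: CohortTrace, params: ParameterSet, strategy: Optional[str] = None
) -> StrategyResult:
    """Roll a cohort trace up into lifetime QALYs, life-years and costs.

    Per cycle: utility accrues on alive-state occupancy (acute tunnel
    utilities replace the chronic utility for the event cycle; the VKA
    disutility applies to all alive states while on first-line VKA); drug and
    monitoring costs accrue on each treatment line's alive occupancy, with
    the VKA initiation visit schedule in the first cycle; acute event costs
    attach to incident events, follow-up costs to chronic post-state
    occupancy.  Everything is accumulated once undiscounted and once with
    quarterly-compounded discounting.
    """
    strategy = strategy or trace.strategy
    occ = trace.occupancy
    if params.settings.half_cycle_correction:
        w = occ.to_numpy()
        w = np.vstack([0.5 * (w[:-1] + w[1:]), w[-1:]])
        occ = occ.copy()
        occ.iloc[:, :] = w
    dfs = trace.discount_factors
    util = _state_utilities(params.utilities)
    u = params.utilities

    # Per-cycle utility of each (state, line) column.
    col_utility = {}
    for state in ALIVE_STATES:
        for line in TREATMENT_LINES:
            value = util[state]
            if strategy == "vka" and line == "first_line":
                if u.vka_disutility_mode == "multiplicative":
                    value *= u.vka_multiplier
                else:
                    value = max(0.0, value - (1.0 - u.vka_multiplier))
            col_utility[f"{state}|{line}"] = value

    utility_per_cycle = np.zeros(len(occ))
    for col, value in col_utility.items():
        utility_per_cycle += occ[col].to_numpy() * value
    alive = trace.alive_mass() if not params.settings.half_cycle_correction else None
    if alive is None:
        dead_cols = [c for c in occ.columns if c.startswith("dead")]
        alive = 1.0 - occ[dead_cols].sum(axis=1).to_numpy()

    qaly_d = float((utility_per_cycle * CYCLE_YEARS * dfs).sum())
    qaly_u = float((utility_per_cycle * CYCLE_YEARS).sum())
    ly_d = float((alive * CYCLE_YEARS * dfs).sum())
    ly_u = float((alive * CYCLE_YEARS).sum())

    # Drug acquisition.
    line1 = trace.line_mass("first_line")
    line2 = trace.line_mass("second_line")
    c = params.costs
    daily_first = strategy_drug_cost_per_day(strategy, c)
    daily_second = payer_drug_cost_per_day(
        c.drug_daily_secondline,
        reference=None,
        copay_rate=c.copay_rate,
        rebate_entry=c.rebate_entry,
        rebate_volume=c.rebate_volume,
    )
    acq_flow = (line1 * daily_first + line2 * daily_second) * DAYS_PER_CYCLE
    cost_acq = float((acq_flow * dfs).sum())
    cost_acq_u = float(acq_flow.sum())

    # Monitoring + transport.
    first_label = "vka" if strategy == "vka" else "riva"
    init = sum(monitoring_cost_per_cycle(first_label, "initiation", c))
    maint = sum(monitoring_cost_per_cycle(first_label, "maintenance", c))
    second = sum(monitoring_cost_per_cycle("secondline", "maintenance", c))
    mon_first = np.full(len(occ), maint)
    mon_first[0] = init
    mon_flow = line1 * mon_first + line2 * second
    cost_mon = float((mon_flow * dfs).sum())
    cost_mon_u = float(mon_flow.sum())

    # Event costs: acute tariffs on incidence, follow-up on post states.
    acute_cost = _acute_event_costs(params)
    inc = trace.incidence
    acute_flow = np.zeros(len(occ))
    for ev, cost in acute_cost.items():
        acute_flow += inc[ev].to_numpy() * cost
    followup = {
        "post_major_is": c.followup_major_stroke,
        "post_ic": c.followup_ic,
        "post_mi": c.followup_mi,
    }
    follow_flow = np.zeros(len(occ))
    for state, cost in followup.items():
        for line in TREATMENT_LINES:
            follow_flow += occ[f"{state}|{line}"].to_numpy() * cost
    events_flow = acute_flow + follow_flow
    cost_events = float((events_flow * dfs).sum())
    cost_events_u = float(events_flow.sum())

    counts = expected_event_counts(trace)
    return StrategyResult(
        strategy=strategy,
        qaly_discounted=qaly_d,
        qaly_undiscounted=qaly_u,
        ly_discounted=ly_d,
        ly_undiscounted=ly_u,
        cost_total=cost_acq + cost_mon + cost_events,
        cost_acquisition=cost_acq,
        cost_monitoring=cost_mon,
        cost_events=cost_events,
        cost_total_undiscounted=cost_acq_u + cost_mon_u + cost_events_u,
        expected_strokes=counts["strokes"],
        expected_bleeds=counts["bleeds"],
        expected_events=counts,
    )


def expected_event_counts(trace: CohortTrace) -> dict[str, float]:
    """Undiscounted lifetime expected events per patient, by type.

    ``strokes`` aggregates major and minor ischemic strokes; ``bleeds``
    aggregates intracranial plus major and minor extracranial bleeds.
    """
    totals = trace.incidence.sum(axis=0)
    out = {ev: float(totals[ev]) for ev in trace.incidence.columns}
    out["strokes"] = out["major_is"] + out["minor_is"]
    out["bleeds"] = out["ic"] + out["major_ec"] + out["minor_ec"]
    return out


def incremental_analysis(
    new: StrategyResult, comparator: StrategyResult
) -> IncrementalResult:
    """Classify a pair of strategies by dominance or report the ICER."""
    dc = new.cost_total - comparator.cost_total
    dq = new.qaly_discounted - comparator.qaly_discounted
    dly = new.ly_discounted - comparator.ly_discounted

    degenerate = dq == 0.0
    if dc < 0.0 and dq > 0.0:
        cls = "dominant"
    elif dc > 0.0 and dq < 0.0:
        cls = "dominated"
    elif degenerate:
        cls = "dominant" if dc < 0.0 else ("dominated" if dc > 0.0 else "icer")
    else:
        cls = "icer"

    icer_q = dc / dq if dq != 0.0 else None
    icer_ly = dc / dly if dly != 0.0 else None
    return IncrementalResult(
        new=new.strategy,
        comparator=comparator.strategy,
        delta_cost=dc,
        delta_qaly=dq,
        delta_ly=dly,
        classification=cls,
        icer_per_qaly=icer_q if cls == "icer" else None,
        icer_per_ly=icer_ly if cls == "icer" else None,
        degenerate=degenerate,
    )


def run_strategy(strategy: str, params: ParameterSet) -> StrategyResult:
    """Convenience wrapper: cohort run plus outcome accumulation."""
    from .cohort import run_cohort

    return accumulate_outcomes(run_cohort(strategy, params), params, strategy)


def compare_strategies(params: ParameterSet) -> tuple[StrategyResult, StrategyResult, IncrementalResult]:
    """Run rivaroxaban and VKA on one parameter set; return both results and
    the incremental analysis (rivaroxaban as the new strategy)."""
    riva = run_strategy("riva", params)
    vka = run_strategy("vka", params)
    return riva, vka, incremental_analysis(riva, vka)
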