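"""Cohort state-transition engine.

The public state space is (health state x treatment line) plus two absorbing
dead states: 12 alive states per line (stable AF, seven one-cycle acute
tunnel states, four chronic post-event states), giving 26 compartments.

Internally the engine tracks, in addition, which chronic state a patient in
an acute tunnel came from, because survivors of transient events (systemic
embolism, extracranial bleeds) return to their origin chronic state, and
survivors of permanent events move to the worse of their origin state and
the event's sequela state (severity priority: post major stroke > post
intracranial bleed > post MI > post minor stroke).  The internal space is
(chronic x {none, event} x line) + 2 dead = 82 compartments; traces are
reported on the public 26-compartment aggregation.

Within-cycle ordering: competing acute events, chronic excess mortality and
background mortality are additive exit probabilities (proportionally rescaled
in the rare case they exceed 1); permanent discontinuation to second-line
therapy applies to event-free survivors only.  Acute tunnels resolve in the
event cycle itself: case fatality to the event-death state, survivors onward.
Intracranial-bleed survivors stop oral anticoagulation (configurable
probability, default 1) and continue on the second line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .parameters import (
    CYCLES_PER_YEAR,
    EventRateTable,
    ParameterSet,
    annual_to_cycle_probability,
    discount_factor,
    treated_event_rates,
)

# Chronic states in ascending severity priority (overwrite rule uses max).
CHRONIC_STATES = ("stable_af", "post_minor_is", "post_mi", "post_ic", "post_major_is")
_PRIORITY = {name: i for i, name in enumerate(CHRONIC_STATES)}

# Acute event types and their tunnel-state names.
EVENTS = ("major_is", "minor_is", "se", "mi", "minor_ec", "major_ec", "ic")
ACUTE_STATE = {
    "major_is": "acute_major_is",
    "minor_is": "acute_minor_is",
    "se": "acute_se",
    "mi": "acute_mi",
    "minor_ec": "acute_minor_ec",
    "major_ec": "acute_major_ec",
    "ic": "acute_ic",
}
# Sequela chronic state of each permanent event; transient events return to
# their origin chronic state.
PERMANENT_SEQUELA = {
    "major_is": "post_major_is",
    "minor_is": "post_minor_is",
    "mi": "post_mi",
    "ic": "post_ic",
}

ALIVE_STATES = (
    "stable_af",
    "acute_major_is",
    "acute_minor_is",
    "acute_se",
    "acute_mi",
    "acute_minor_ec",
    "acute_major_ec",
    "acute_ic",
    "post_major_is",
    "post_minor_is",
    "post_mi",
    "post_ic",
)
TREATMENT_LINES = ("first_line", "second_line")
DEAD_STATES = ("dead_event", "dead_other")

STRATEGIES = ("riva", "vka")


def build_state_space(persistence=None) -> list[tuple[str, str]]:
    """Ordered public compartments: every alive state on both treatment
    lines, then the two dead states.

    The ordering is deterministic and independent of the second-line drug
    (aspirin or none): the structure is the same, only second-line costs and
    event rates differ.
    """
    space = [(s, line) for line in TREATMENT_LINES for s in ALIVE_STATES]
    space += [(d, "") for d in DEAD_STATES]
    return space


def compartment_labels(persistence=None) -> list[str]:
    return [f"{s}|{line}" if line else s for s, line in build_state_space(persistence)]


def background_mortality_per_cycle(age: float, life_table: dict[int, float]) -> float:
    """Per-cycle all-cause death probability at a (possibly fractional) age.

    The annual probability of the containing integer age is converted to the
    quarterly scale; the terminal age (annual probability 1) maps to 1.
    """
    year = int(np.floor(age))
    if year > max(life_table):
        year = max(life_table)
    if year not in life_table:
        raise ValueError(f"age {age} outside the life table range")
    return annual_to_cycle_probability(life_table[year])


# ---------------------------------------------------------------------------
# Internal state indexing
# ---------------------------------------------------------------------------

def _internal_states() -> list[tuple]:
    """(chronic, event-or-None, line_idx) triples, then the dead states."""
    states: list[tuple] = []
    for line in (0, 1):
        for c in CHRONIC_STATES:
            states.append((c, None, line))
        for c in CHRONIC_STATES:
            for e in EVENTS:
                states.append((c, e, line))
    states.append(("dead_event",))
    states.append(("dead_other",))
    return states


INTERNAL_STATES = _internal_states()
_IDX = {s: i for i, s in enumerate(INTERNAL_STATES)}
N_INTERNAL = len(INTERNAL_STATES)
IDX_DEAD_EVENT = _IDX[("dead_event",)]
IDX_DEAD_OTHER = _IDX[("dead_other",)]

# Map internal index -> public compartment index (26-dim aggregation).
PUBLIC_SPACE = build_state_space()
_PUBLIC_IDX = {s: i for i, s in enumerate(PUBLIC_SPACE)}


def _public_index(internal: tuple) -> int:
    if internal == ("dead_event",):
        return _PUBLIC_IDX[("dead_event", "")]
    if internal == ("dead_other",):
        return _PUBLIC_IDX[("dead_other", "")]
    c, e, line = internal
    name = c if e is None else ACUTE_STATE[e]
    return _PUBLIC_IDX[(name, TREATMENT_LINES[line])]


PUBLIC_OF_INTERNAL = np.array([_public_index(s) for s in INTERNAL_STATES])


def _event_probs(rates: EventRateTable, major_fraction: float) -> dict[str, float]:
    return {
        "major_is": rates.ischemic_stroke * major_fraction,
        "minor_is": rates.ischemic_stroke * (1.0 - major_fraction),
        "se": rates.systemic_embolism,
        "mi": rates.myocardial_infarction,
        "minor_ec": rates.minor_extracranial_bleed,
        "major_ec": rates.major_extracranial_bleed,
        "ic": rates.intracranial_bleed,
    }


def _case_fatality(params: ParameterSet) -> dict[str, float]:
    m = params.mortality
    return {
        "major_is": m.case_fatality_major_stroke,
        "minor_is": m.case_fatality_minor_stroke,
        "se": m.case_fatality_se,
        "mi": m.case_fatality_mi,
        "minor_ec": m.case_fatality_minor_bleed,
        "major_ec": m.case_fatality_major_bleed,
        "ic": m.case_fatality_ic_bleed,
    }


def _excess_mortality(params: ParameterSet) -> dict[str, float]:
    m = params.mortality
    return {
        "stable_af": 0.0,
        "post_major_is": m.post_major_stroke_excess,
        "post_minor_is": m.post_minor_stroke_excess,
        "post_mi": m.post_mi_excess,
        "post_ic": m.post_ic_excess,
    }


def line_event_rates(params: ParameterSet, strategy: str, line: int) -> EventRateTable:
    """Per-cycle event probabilities for a treatment line under a strategy."""
    if line == 0:
        if strategy == "riva":
            return treated_event_rates(params.event_rates_vka, params.effect)
        if strategy == "vka":
            return params.event_rates_vka
        raise ValueError(f"unknown strategy {strategy!r}")
    return params.event_rates_secondline


def transition_row(
    state: tuple,
    params: ParameterSet,
    strategy: str,
    q_background: float,
    first_cycle: bool,
) -> dict[tuple, float]:
    """One internal compartment's outgoing probability distribution.

    ``state`` is an internal (chronic, event-or-None, line) triple or a dead
    state tuple.  Probabilities sum to 1 (validated downstream).
    """
    if state in (("dead_event",), ("dead_other",)):
        return {state: 1.0}

    c, e, line = state
    row: dict[tuple, float] = {}

    if e is not None:
        # Acute tunnel: resolve within the event cycle.
        f = _case_fatality(params)[e]
        if f > 0.0:
            row[("dead_event",)] = f
        survive = 1.0 - f
        if survive > 0.0:
            if e in PERMANENT_SEQUELA:
                dest_c = max(c, PERMANENT_SEQUELA[e], key=_PRIORITY.__getitem__)
            else:
                dest_c = c
            if e == "ic" and line == 0:
                p_stop = params.persistence.ic_bleed_discontinuation_prob
                if p_stop > 0.0:
                    row[(dest_c, None, 1)] = row.get((dest_c, None, 1), 0.0) + survive * p_stop
                if p_stop < 1.0:
                    row[(dest_c, None, 0)] = row.get((dest_c, None, 0), 0.0) + survive * (1.0 - p_stop)
            else:
                row[(dest_c, None, line)] = row.get((dest_c, None, line), 0.0) + survive
        return row

    # Chronic state: competing events + excess + background mortality.
    rates = line_event_rates(params, strategy, line)
    probs = _event_probs(rates, params.settings.stroke_major_fraction)
    excess = _excess_mortality(params)[c]
    total_exit = sum(probs.values()) + excess + q_background
    scale = 1.0 / total_exit if total_exit > 1.0 else 1.0

    for ev, p in probs.items():
        if p > 0.0:
            row[(c, ev, line)] = p * scale
    if excess > 0.0:
        row[("dead_event",)] = row.get(("dead_event",), 0.0) + excess * scale
    if q_background > 0.0:
        row[("dead_other",)] = row.get(("dead_other",), 0.0) + q_background * scale

    stay = max(0.0, 1.0 - min(total_exit, 1.0))
    if stay > 0.0:
        if line == 0:
            p_ = params.persistence
            if strategy == "riva":
                d = p_.disc_first_cycle_riva if first_cycle else p_.disc_subsequent_riva
            else:
                d = p_.disc_first_cycle_vka if first_cycle else p_.disc_subsequent_vka
            if d > 0.0:
                row[(c, None, 1)] = row.get((c, None, 1), 0.0) + stay * d
            if d < 1.0:
                row[(c, None, 0)] = row.get((c, None, 0), 0.0) + stay * (1.0 - d)
        else:
            row[(c, None, 1)] = row.get((c, None, 1), 0.0) + stay
    return row


def transition_probabilities(
    health_state: str,
    line: str,
    params: ParameterSet,
    strategy: str,
    age: Optional[float] = None,
    origin: str = "stable_af",
    first_cycle: bool = False,
) -> dict[tuple[str, str], float]:
    """Public-compartment transition distribution for one compartment.

    For acute tunnel states the origin chronic state (not part of the public
    label) determines where transient-event survivors return and how the
    severity-overwrite rule resolves; it defaults to stable AF.
    """
    if health_state in DEAD_STATES:
        return {(health_state, ""): 1.0}
    line_idx = TREATMENT_LINES.index(line)
    if health_state in CHRONIC_STATES:
        internal = (health_state, None, line_idx)
    else:
        event = next(e for e, s in ACUTE_STATE.items() if s == health_state)
        internal = (origin, event, line_idx)
    if age is None:
        age = float(params.mortality.start_age)
    q_bg = background_mortality_per_cycle(age, params.mortality.life_table)
    row = transition_row(internal, params, strategy, q_bg, first_cycle)
    out: dict[tuple[str, str], float] = {}
    for dest, p in row.items():
        if len(dest) == 1:
            key = (dest[0], "")
        else:
            c, e, li = dest
            key = (c if e is None else ACUTE_STATE[e], TREATMENT_LINES[li])
        out[key] = out.get(key, 0.0) + p
    return out


# ---------------------------------------------------------------------------
# Cohort trace
# ---------------------------------------------------------------------------

@dataclass
class CohortTrace:
    """Per-cycle cohort distribution and event incidence for one strategy.

    ``occupancy``: rows = cycles, columns = the 26 public compartments.
    ``incidence``: rows = cycles, columns = event types; the fraction of the
    cohort newly entering each acute tunnel that cycle.
    ``ages``: cohort age at the start of each cycle.
    """

    strategy: str
    occupancy: pd.DataFrame
    incidence: pd.DataFrame
    ages: np.ndarray
    discount_factors: np.ndarray
    internal_occupancy: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.occupancy)

    def alive_mass(self) -> np.ndarray:
        dead_cols = [c for c in self.occupancy.columns if c.startswith("dead")]
        return 1.0 - self.occupancy[dead_cols].sum(axis=1).to_numpy()

    def line_mass(self, line: str) -> np.ndarray:
        cols = [c for c in self.occupancy.columns if c.endswith(f"|{line}")]
        return self.occupancy[cols].sum(axis=1).to_numpy()

    def to_csv(self, path) -> None:
        out = self.occupancy.copy()
        out.insert(0, "age", self.ages)
        out.insert(1, "discount_factor", self.discount_factors)
        out.to_csv(path, index_label="cycle")


def _transition_matrix(
    params: ParameterSet, strategy: str, q_bg: float, first_cycle: bool
) -> np.ndarray:
    m = np.zeros((N_INTERNAL, N_INTERNAL))
    for i, state in enumerate(INTERNAL_STATES):
        for dest, p in transition_row(state, params, strategy, q_bg, first_cycle).items():
            m[i, _IDX[dest]] += p
    sums = m.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-12):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(
            f"transition row for {INTERNAL_STATES[bad]} sums to {sums[bad]!r}"
        )
    if (m < 0).any() or not np.isfinite(m).all():
        raise ValueError("negative or non-finite transition probability")
    return m


def run_cohort(
    strategy: str,
    params: ParameterSet,
    max_cycles: Optional[int] = None,
    alive_tolerance: float = 1e-6,
) -> CohortTrace:
    """Evolve the full cohort from stable AF at the start age to the horizon.

    The cohort starts with all mass in (stable AF, first line).  The first
    transition uses the first-cycle discontinuation probability, later ones
    the subsequent per-cycle probability.  Iteration stops at the terminal
    age (any remaining alive mass is then moved to other-cause death) or as
    soon as the alive mass falls below ``alive_tolerance``.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    settings = params.settings
    start_age = params.mortality.start_age
    horizon = (settings.terminal_age - start_age) * CYCLES_PER_YEAR
    if max_cycles is not None:
        horizon = min(horizon, max_cycles)
    if horizon < 1:
        raise ValueError("horizon must cover at least one cycle")

    v = np.zeros(N_INTERNAL)
    v[_IDX[("stable_af", None, 0)]] = 1.0

    rows = [v.copy()]
    incidence_rows = [np.zeros(len(EVENTS))]
    tunnel_idx = {
        e: [_IDX[(c, e, line)] for c in CHRONIC_STATES for line in (0, 1)]
        for e in EVENTS
    }
    matrix_cache: dict[tuple, np.ndarray] = {}

    for t in range(horizon):
        age = start_age + t / CYCLES_PER_YEAR
        q_bg = background_mortality_per_cycle(age, params.mortality.life_table)
        key = (int(np.floor(age)), t == 0)
        m = matrix_cache.get(key)
        if m is None:
            m = _transition_matrix(params, strategy, q_bg, t == 0)
            matrix_cache[key] = m
        v = v @ m
        rows.append(v.copy())
        incidence_rows.append(
            np.array([v[tunnel_idx[e]].sum() for e in EVENTS])
        )
        alive = 1.0 - v[IDX_DEAD_EVENT] - v[IDX_DEAD_OTHER]
        if alive < alive_tolerance:
            break

    internal = np.vstack(rows)
    # Force any residual alive mass at the horizon into other-cause death.
    at_terminal = start_age + (len(internal) - 1) / CYCLES_PER_YEAR >= settings.terminal_age
    residual = 1.0 - internal[-1, IDX_DEAD_EVENT] - internal[-1, IDX_DEAD_OTHER]
    if residual > 0.0 and at_terminal:
        internal[-1, :IDX_DEAD_EVENT] = 0.0
        internal[-1, IDX_DEAD_OTHER] += residual

    n = len(internal)
    public = np.zeros((n, len(PUBLIC_SPACE)))
    np.add.at(public.T, PUBLIC_OF_INTERNAL, internal.T)

    cycles = np.arange(n)
    occupancy = pd.DataFrame(public, index=cycles, columns=compartment_labels())
    occupancy.index.name = "cycle"
    incidence = pd.DataFrame(
        np.vstack(incidence_rows), index=cycles, columns=list(EVENTS)
    )
    incidence.index.name = "cycle"
    ages = start_age + cycles / CYCLES_PER_YEAR
    dfs = np.array(
        [discount_factor(int(t), settings.discount_rate_annual) for t in cycles]
    )
    return CohortTrace(
        strategy=strategy,
        occupancy=occupancy,
        incidence=incidence,
        ages=ages,
        discount_factors=dfs,
        internal_occupancy=internal,
    )
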