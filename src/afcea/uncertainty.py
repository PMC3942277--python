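"""Uncertainty analyses: one-way sensitivity, named scenarios, and the
probabilistic sensitivity analysis with its acceptability curve.

Distribution conventions follow standard decision-modelling practice:
beta for probabilities and utilities, lognormal for relative risks (location
and scale recovered from the published point estimate and 95% CI), gamma for
unit costs.  Where no interval is published the standard error defaults to
20% of the mean.  Parameters are sampled independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import fixtures
from .outcomes import IncrementalResult, StrategyResult, compare_strategies
from .parameters import ParameterSet, RelativeRisk

Z975 = 1.959964  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# Distribution helpers
# ---------------------------------------------------------------------------

def lognormal_from_ci(point: float, lo: float, hi: float) -> tuple[float, float]:
    """(location, scale) of a lognormal matching a ratio estimate's 95% CI.

    location = ln(point); scale = (ln hi - ln lo) / (2 * 1.959964).
    """
    if not (0.0 < lo <= point <= hi):
        raise ValueError(f"need 0 < lo <= point <= hi, got ({lo}, {point}, {hi})")
    return math.log(point), (math.log(hi) - math.log(lo)) / (2.0 * Z975)


def moment_match(family: str, mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments parameters for a beta or gamma distribution.

    Beta returns (alpha, beta); gamma returns (shape, scale).  The matched
    distribution reproduces the requested mean and standard deviation
    exactly.  A beta request with se**2 >= mean*(1-mean) is infeasible.
    """
    if se <= 0.0:
        raise ValueError("se must be positive")
    var = se * se
    if family == "beta":
        if not 0.0 < mean < 1.0:
            raise ValueError("beta mean must lie in (0, 1)")
        if var >= mean * (1.0 - mean):
            raise ValueError(
                f"beta infeasible: se^2={var} >= mean*(1-mean)={mean * (1 - mean)}"
            )
        alpha = mean * (mean * (1.0 - mean) / var - 1.0)
        return alpha, alpha * (1.0 - mean) / mean
    if family == "gamma":
        if mean <= 0.0:
            raise ValueError("gamma mean must be positive")
        return mean * mean / var, var / mean
    raise ValueError(f"unknown family {family!r}")


@dataclass
class DistributionSpec:
    """Sampling recipe for one scalar parameter, addressed by dotted path.

    Families: ``beta`` and ``gamma`` need (mean, se); ``one_minus_beta``
    samples ``1 - Beta`` for near-one multipliers whose complement is the
    natural uncertain quantity; ``lognormal`` needs (point, lo, hi);
    ``fixed`` keeps the base value.
    """

    path: str
    family: str
    mean: Optional[float] = None
    se: Optional[float] = None
    point: Optional[float] = None
    lo: Optional[float] = None
    hi: Optional[float] = None

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "fixed":
            return float(self.mean if self.mean is not None else self.point)
        if self.family == "beta":
            a, b = moment_match("beta", self.mean, self.se)
            return float(rng.beta(a, b))
        if self.family == "one_minus_beta":
            a, b = moment_match("beta", 1.0 - self.mean, self.se)
            return float(1.0 - rng.beta(a, b))
        if self.family == "gamma":
            shape, scale = moment_match("gamma", self.mean, self.se)
            return float(rng.gamma(shape, scale))
        if self.family == "lognormal":
            mu, sigma = lognormal_from_ci(self.point, self.lo, self.hi)
            return float(rng.lognormal(mu, sigma))
        raise ValueError(f"unknown family {self.family!r}")


# ---------------------------------------------------------------------------
# Parameter paths
# ---------------------------------------------------------------------------

RIVA_EFFECTIVENESS = "riva_effectiveness"
_RR_PATHS = ("rr_is", "rr_mi", "rr_se", "rr_ic", "rr_major_ec", "rr_minor_ec")


def get_parameter(params: ParameterSet, path: str) -> float:
    """Resolve a dotted parameter path to its scalar base value."""
    if path == RIVA_EFFECTIVENESS:
        return 1.0
    obj = params
    for part in path.split("."):
        if not hasattr(obj, part):
            raise KeyError(f"unknown parameter path {path!r} (at {part!r})")
        obj = getattr(obj, part)
    if isinstance(obj, RelativeRisk):
        return obj.point
    if not isinstance(obj, (int, float)):
        raise KeyError(f"path {path!r} does not address a scalar")
    return float(obj)


def _set_inplace(ps: ParameterSet, path: str, value: float) -> None:
    if path == RIVA_EFFECTIVENESS:
        for name in _RR_PATHS:
            rr = getattr(ps.effect, name)
            setattr(ps.effect, name, RelativeRisk(
                point=rr.point * value, lo=rr.lo * value, hi=rr.hi * value
            ))
        return
    parts = path.split(".")
    obj = ps
    for part in parts[:-1]:
        if not hasattr(obj, part):
            raise KeyError(f"unknown parameter path {path!r} (at {part!r})")
        obj = getattr(obj, part)
    leaf = parts[-1]
    if not hasattr(obj, leaf):
        raise KeyError(f"unknown parameter path {path!r} (at {leaf!r})")
    current = getattr(obj, leaf)
    if isinstance(current, RelativeRisk):
        setattr(obj, leaf, RelativeRisk(
            point=value, lo=min(current.lo, value), hi=max(current.hi, value)
        ))
    else:
        setattr(obj, leaf, value)


def set_parameter(params: ParameterSet, path: str, value: float) -> ParameterSet:
    """Return a copy of the parameter set with one path replaced.

    Relative-risk paths replace the point estimate (widening the stored CI
    if needed so it still brackets the point).  The special path
    ``riva_effectiveness`` scales every rivaroxaban relative risk.
    """
    ps = params.model_copy(deep=True)
    _set_inplace(ps, path, value)
    return ps


DEFAULT_SE_FRACTION = 0.2


def default_psa_specs(
    params: ParameterSet, se_fraction: float = DEFAULT_SE_FRACTION
) -> list[DistributionSpec]:
    """The default sampling plan over every substantively uncertain input.

    Baseline and second-line event probabilities, case fatalities, excess
    mortality, persistence and transport uptake: beta.  Utilities: beta (the
    VKA multiplier via its disutility complement).  Relative risks: lognormal
    from their published CIs.  Event, visit and transport unit costs: gamma.
    Administered drug prices and the discount rate stay fixed.
    """
    specs: list[DistributionSpec] = []

    def beta(path: str) -> None:
        m = get_parameter(params, path)
        if 0.0 < m < 1.0:
            specs.append(DistributionSpec(path, "beta", mean=m, se=m * se_fraction))

    def gamma(path: str) -> None:
        m = get_parameter(params, path)
        if m > 0.0:
            specs.append(DistributionSpec(path, "gamma", mean=m, se=m * se_fraction))

    for table in ("event_rates_vka", "event_rates_secondline"):
        for name in (
            "ischemic_stroke", "myocardial_infarction", "systemic_embolism",
            "intracranial_bleed", "minor_extracranial_bleed",
            "major_extracranial_bleed",
        ):
            beta(f"{table}.{name}")

    for name in _RR_PATHS:
        rr = getattr(params.effect, name)
        if rr.lo < rr.hi:
            specs.append(DistributionSpec(
                f"effect.{name}", "lognormal", point=rr.point, lo=rr.lo, hi=rr.hi
            ))

    for name in (
        "case_fatality_major_stroke", "case_fatality_major_bleed",
        "case_fatality_ic_bleed", "case_fatality_mi",
        "post_major_stroke_excess", "post_ic_excess", "post_mi_excess",
    ):
        beta(f"mortality.{name}")

    for name in (
        "baseline", "acute_major_is", "acute_minor_is", "acute_mi",
        "acute_minor_bleed", "acute_major_bleed", "acute_ic", "acute_se",
        "post_minor_is", "post_major_is", "post_mi", "post_ic",
    ):
        beta(f"utilities.{name}")
    mult = params.utilities.vka_multiplier
    if mult < 1.0:
        specs.append(DistributionSpec(
            "utilities.vka_multiplier", "one_minus_beta",
            mean=mult, se=(1.0 - mult) * se_fraction,
        ))

    for name in (
        "acute_minor_is", "acute_moderate_is", "acute_severe_is", "acute_se",
        "acute_ic", "acute_minor_ec", "acute_major_ec", "acute_mi",
        "followup_major_stroke", "followup_ic", "followup_mi",
        "visit_cost_vka_first", "visit_cost_vka_subsequent",
        "visit_cost_other", "transport_cost_per_visit",
    ):
        gamma(f"costs.{name}")
    beta("costs.transport_uptake")

    for name in (
        "disc_first_cycle_riva", "disc_first_cycle_vka",
        "disc_subsequent_riva", "disc_subsequent_vka",
    ):
        beta(f"persistence.{name}")
    return specs


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSASample:
    """One joint parameter draw and its incremental outcome pair."""

    index: int
    values: dict[str, float]
    delta_cost: float
    delta_qaly: float


def sampled_parameter_set(
    params: ParameterSet, values: dict[str, float]
) -> ParameterSet:
    """Apply a dict of sampled path values to a base parameter set."""
    ps = params.model_copy(deep=True)
    for path, value in values.items():
        _set_inplace(ps, path, value)
    return ps


def run_psa(
    params: ParameterSet,
    specs: Optional[Sequence[DistributionSpec]] = None,
    n_iterations: int = 1000,
    seed: int = 0,
) -> list[PSASample]:
    """Monte-Carlo propagation of parameter uncertainty.

    Each iteration draws every spec once (in a fixed order from a single
    seeded generator, so identical (seed, n) reproduce bit-identical
    output), rebuilds the parameter set, runs both strategies and records
    the discounted incremental cost and QALY pair.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if specs is None:
        specs = default_psa_specs(params)
    rng = np.random.default_rng(seed)
    samples: list[PSASample] = []
    for i in range(n_iterations):
        values = {spec.path: spec.sample(rng) for spec in specs}
        ps = sampled_parameter_set(params, values)
        _, _, inc = compare_strategies(ps)
        if not (math.isfinite(inc.delta_cost) and math.isfinite(inc.delta_qaly)):
            raise ValueError(f"non-finite PSA outcome at draw {i}: {values}")
        samples.append(PSASample(
            index=i, values=values,
            delta_cost=inc.delta_cost, delta_qaly=inc.delta_qaly,
        ))
    return samples


def ceac_curve(
    samples: Sequence[PSASample], wtp_grid: Sequence[float]
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over willingness-to-pay values.

    At each threshold lambda the probability is the fraction of draws with
    non-negative net monetary benefit lambda * dQALY - dCost (ties count as
    cost-effective).
    """
    if len(samples) == 0:
        raise ValueError("samples must be non-empty")
    if len(wtp_grid) == 0:
        raise ValueError("wtp_grid must be non-empty")
    dc = np.array([s.delta_cost for s in samples])
    dq = np.array([s.delta_qaly for s in samples])
    probs = [float(np.mean(wtp * dq - dc >= 0.0)) for wtp in wtp_grid]
    return pd.DataFrame({"wtp": list(wtp_grid), "probability": probs})


def probability_cost_effective(samples: Sequence[PSASample], wtp: float) -> float:
    return float(ceac_curve(samples, [wtp])["probability"].iloc[0])


def psa_samples_frame(samples: Sequence[PSASample]) -> pd.DataFrame:
    """Flat table of draws: one row per iteration, sampled values + deltas."""
    rows = []
    for s in samples:
        row = {"iteration": s.index, **s.values,
               "delta_cost": s.delta_cost, "delta_qaly": s.delta_qaly}
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# One-way sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    parameter: str
    base: float
    low: float
    high: float
    result_low: IncrementalResult
    result_high: IncrementalResult

    def icer_or_classification(self, which: str):
        res = self.result_low if which == "low" else self.result_high
        return res.icer_per_qaly if res.classification == "icer" else res.classification


# Published one-way ranges for the headline tornado; clinical-efficacy rows
# use the 95% CIs, the rest the ranges reported alongside the base values.
DEFAULT_OWSA_PLAN: list[tuple[str, float, float]] = [
    ("costs.maintenance_visits_per_cycle_vka", 1.0, 5.0),
    ("persistence.disc_subsequent_riva", 0.0, 0.09),
    ("utilities.vka_multiplier", 0.92, 1.00),
    ("persistence.disc_first_cycle_riva", 0.0, 0.54),
    ("persistence.disc_subsequent_vka", 0.0, 0.06),
    ("persistence.disc_first_cycle_vka", 0.0, 0.31),
    ("effect.rr_mi", 0.63, 1.06),
    (RIVA_EFFECTIVENESS, 0.75, 1.25),
    ("effect.rr_is", 0.75, 1.17),
    ("costs.visit_cost_vka_subsequent", 17.69, 26.31),
    ("costs.visit_cost_vka_first", 25.73, 38.27),
    ("costs.transport_uptake", 0.0, 1.0),
    ("costs.other_visits_per_cycle", 0.0, 1.0),
]


def one_way_sensitivity(
    params: ParameterSet,
    plan: Optional[Sequence[tuple[str, float, float]]] = None,
    min_icer_change: Optional[float] = None,
) -> list[TornadoEntry]:
    """Re-run the incremental analysis with one parameter at its low and
    high bound, everything else at base.

    With ``min_icer_change`` set, entries whose ICER moves from the base
    result by less than that amount at both bounds are filtered out
    (dominance flips always count as a material change).
    """
    if plan is None:
        plan = DEFAULT_OWSA_PLAN
    _, _, base_inc = compare_strategies(params)
    base_icer = base_inc.icer_per_qaly if base_inc.classification == "icer" else 0.0

    entries: list[TornadoEntry] = []
    for path, low, high in plan:
        base = get_parameter(params, path)
        if not (low <= base <= high):
            raise ValueError(
                f"{path}: base {base} outside [{low}, {high}]"
            )
        results = {}
        for tag, value in (("low", low), ("high", high)):
            _, _, inc = compare_strategies(set_parameter(params, path, value))
            results[tag] = inc
        entry = TornadoEntry(
            parameter=path, base=base, low=low, high=high,
            result_low=results["low"], result_high=results["high"],
        )
        if min_icer_change is not None:
            def _moved(res: IncrementalResult) -> bool:
                if res.classification != base_inc.classification:
                    return True
                if res.classification != "icer":
                    return False
                return abs((res.icer_per_qaly or 0.0) - base_icer) > min_icer_change
            if not (_moved(results["low"]) or _moved(results["high"])):
                continue
        entries.append(entry)
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "parameter": e.parameter,
            "base": e.base,
            "low": e.low,
            "high": e.high,
            "icer_or_class_low": e.icer_or_classification("low"),
            "icer_or_class_high": e.icer_or_classification("high"),
        }
        for e in entries
    ])


# ---------------------------------------------------------------------------
# Named scenarios
# ---------------------------------------------------------------------------

SCENARIOS = (
    "sot_aspirin", "itt_aspirin", "sot_none", "itt_none",
    "no_vka_disutility", "rebate_9", "rebate_14",
)


def scenario_parameters(name: str, params: ParameterSet) -> ParameterSet:
    """Parameter swaps defining each named scenario relative to the base
    case (SOT effects, switch to aspirin, VKA disutility, no rebates)."""
    ps = params.model_copy(deep=True)
    if name == "sot_aspirin":
        return ps
    if name in ("itt_aspirin", "itt_none"):
        ps = ps.model_copy(update={"effect": fixtures.itt_effect()})
    if name in ("sot_none", "itt_none"):
        ps = ps.model_copy(update={
            "event_rates_secondline": fixtures.secondline_rates(
                "none", ps.event_rates_vka
            ),
            "persistence": ps.persistence.model_copy(
                update={"second_line": "none"}
            ),
        })
    if name == "no_vka_disutility":
        ps = ps.model_copy(update={
            "utilities": ps.utilities.model_copy(update={"vka_multiplier": 1.0})
        })
    if name == "rebate_9":
        ps = ps.model_copy(update={
            "costs": ps.costs.model_copy(update={"rebate_entry": 0.09})
        })
    if name == "rebate_14":
        ps = ps.model_copy(update={
            "costs": ps.costs.model_copy(
                update={"rebate_entry": 0.09, "rebate_volume": 0.05}
            )
        })
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}")
    return ps


def run_scenario(
    name: str, params: ParameterSet
) -> tuple[StrategyResult, StrategyResult, IncrementalResult]:
    """Run both strategies under a named scenario's parameter swaps."""
    return compare_strategies(scenario_parameters(name, params))
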