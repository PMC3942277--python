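"""Rate conversions, persistence, treatment effects and payer cost rules."""

import math

import pytest
from hypothesis import given, settings, strategies as st
from pydantic import ValidationError

from afcea import fixtures
from afcea.parameters import (
    CostSet,
    EventRateTable,
    annual_to_cycle_probability,
    cycle_to_annual_probability,
    discount_factor,
    monitoring_cost_per_cycle,
    payer_drug_cost_per_day,
    subsequent_discontinuation,
    treated_event_probability,
    treated_event_rates,
)


@pytest.mark.parametrize(
    "annual, expected",
    [
        (0.0, 0.0),
        (1.0, 1.0),
        (0.04, 0.01015359923204695),  # 1 - 0.96**(1/4), evaluated directly
    ],
)
def test_annual_to_cycle_examples(annual, expected):
    assert annual_to_cycle_probability(annual) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("bad", [-0.1, 1.1])
def test_annual_to_cycle_rejects_out_of_range(bad):
    with pytest.raises(ValueError):
        annual_to_cycle_probability(bad)
    with pytest.raises(ValueError):
        cycle_to_annual_probability(bad)


@settings(max_examples=200, derandomize=True)
@given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
def test_rate_conversion_round_trips(p):
    assert cycle_to_annual_probability(annual_to_cycle_probability(p)) == pytest.approx(
        p, abs=1e-12
    )


@settings(max_examples=100, derandomize=True)
@given(
    st.floats(min_value=1e-6, max_value=1 - 1e-6),
    st.floats(min_value=1e-6, max_value=1 - 1e-6),
)
def test_rate_conversion_strictly_increasing(a, b):
    lo, hi = sorted((a, b))
    if lo < hi:
        assert annual_to_cycle_probability(lo) < annual_to_cycle_probability(hi)


class TestDiscontinuation:
    def test_no_further_loss_means_zero_subsequent(self):
        assert subsequent_discontinuation(0.9, 0.9).subsequent == 0.0

    def test_full_persistence(self):
        rates = subsequent_discontinuation(1.0, 1.0)
        assert rates.first_cycle == 0.0
        assert rates.subsequent == 0.0

    def test_trial_persistence_reproduces_quarterly_rate(self):
        # invert 1-(y/x)**(1/3) for the published 4.39%: round-trip check
        rates = subsequent_discontinuation(0.911, 0.7962)
        assert rates.first_cycle == pytest.approx(0.089)
        assert rates.subsequent == pytest.approx(0.0439, abs=1e-4)
        x = 0.911
        y = x * (1 - rates.subsequent) ** 3
        assert y == pytest.approx(0.7962, abs=1e-12)

    def test_inconsistent_persistence_rejected(self):
        with pytest.raises(ValueError):
            subsequent_discontinuation(0.7, 0.8)


class TestTreatedProbability:
    @pytest.mark.parametrize(
        "baseline, rr, expected",
        [(0.0040, 1.0, 0.0040), (0.0040, 0.94, 0.00376), (0.6, 2.0, 1.0)],
    )
    def test_examples(self, baseline, rr, expected):
        assert treated_event_probability(baseline, rr) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            treated_event_probability(-0.1, 1.0)
        with pytest.raises(ValueError):
            treated_event_probability(0.1, -1.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(min_value=0.0, max_value=0.01),
        st.floats(min_value=0.0, max_value=2.0),
    )
    def test_never_clamps_for_small_risks(self, baseline, rr):
        assert treated_event_probability(baseline, rr) == baseline * rr

    def test_table_application(self, base_params):
        treated = treated_event_rates(base_params.event_rates_vka, base_params.effect)
        assert treated.ischemic_stroke == pytest.approx(0.0040 * 0.94)
        assert treated.major_extracranial_bleed == pytest.approx(0.0069 * 1.14)


class TestPayerDrugCost:
    def test_no_reference_price_passes_retail_through(self):
        assert payer_drug_cost_per_day(2.16) == pytest.approx(2.16)

    def test_entry_rebate(self):
        assert payer_drug_cost_per_day(2.16, rebate_entry=0.09) == pytest.approx(1.9656)

    def test_retail_equal_reference_pays_reference_less_copay(self):
        assert payer_drug_cost_per_day(1.0, reference=1.0) == pytest.approx(0.75)

    def test_retail_above_reference_splits_difference(self):
        # reference*(1-copay) + half the gap
        assert payer_drug_cost_per_day(2.0, reference=1.0) == pytest.approx(
            0.75 + 0.5 * 1.0
        )

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
    )
    def test_non_increasing_in_rebates_and_non_negative(self, re_, rv):
        value = payer_drug_cost_per_day(2.16, rebate_entry=re_, rebate_volume=rv)
        assert 0.0 <= value <= 2.16


class TestMonitoringSchedule:
    def test_vka_maintenance(self, base_params):
        mon, transport = monitoring_cost_per_cycle(
            "vka", "maintenance", base_params.costs
        )
        assert mon == pytest.approx(66.0)
        assert transport == pytest.approx(105.0)

    def test_vka_initiation(self, base_params):
        mon, transport = monitoring_cost_per_cycle(
            "vka", "initiation", base_params.costs
        )
        assert mon == pytest.approx(142.0)
        assert transport == pytest.approx(210.0)

    def test_riva_has_no_transport(self, base_params):
        mon, transport = monitoring_cost_per_cycle(
            "riva", "maintenance", base_params.costs
        )
        assert mon == pytest.approx(2.50)
        assert transport == 0.0

    def test_unknown_line_rejected(self, base_params):
        with pytest.raises(ValueError):
            monitoring_cost_per_cycle("warfarin", "maintenance", base_params.costs)


def test_discount_factor_examples():
    assert discount_factor(0, 0.035) == 1.0
    assert discount_factor(17, 0.0) == 1.0
    assert discount_factor(4, 0.035) == pytest.approx(0.9661835748792271, abs=1e-12)


class TestBaseCaseValues:
    """The bundled configuration carries the published inputs verbatim."""

    def test_event_rates(self, base_params):
        t = base_params.event_rates_vka
        assert (
            t.ischemic_stroke,
            t.myocardial_infarction,
            t.systemic_embolism,
            t.intracranial_bleed,
            t.minor_extracranial_bleed,
            t.major_extracranial_bleed,
        ) == (0.0040, 0.0028, 0.0005, 0.0019, 0.0297, 0.0069)

    def test_effects_and_cis(self, base_params):
        e = base_params.effect
        assert (e.rr_is.point, e.rr_is.lo, e.rr_is.hi) == (0.94, 0.75, 1.17)
        assert (e.rr_se.point, e.rr_se.lo, e.rr_se.hi) == (0.23, 0.09, 0.61)
        assert e.rr_ic.point == 0.67 and e.rr_major_ec.point == 1.14

    def test_mortality_and_utilities(self, base_params):
        m, u = base_params.mortality, base_params.utilities
        assert m.case_fatality_ic_bleed == 0.388
        assert m.case_fatality_mi == 0.0969
        assert m.post_mi_excess == 0.0268
        assert u.baseline == 0.779 and u.vka_multiplier == 0.95
        assert u.post_major_is == 0.48

    def test_costs(self, base_params):
        c = base_params.costs
        assert c.drug_daily_riva == 2.16 and c.drug_daily_vka == 0.05
        assert (c.visit_cost_vka_first, c.visit_cost_vka_subsequent) == (32.0, 22.0)
        assert c.acute_mi == 1783.0 and c.followup_mi == 1296.0
        assert c.transport_cost_per_visit == 70.0 and c.transport_uptake == 0.5


class TestValidation:
    def test_out_of_range_rate_rejected(self, base_params):
        data = base_params.model_dump()
        data["event_rates_vka"]["ischemic_stroke"] = 1.5
        with pytest.raises(ValidationError, match="ischemic_stroke"):
            type(base_params).model_validate(data)

    def test_missing_block_rejected(self, base_params):
        data = base_params.model_dump()
        del data["utilities"]
        with pytest.raises(ValidationError, match="utilities"):
            type(base_params).model_validate(data)

    def test_life_table_must_terminate(self, base_params):
        data = base_params.model_dump()
        table = data["mortality"]["life_table"]
        table[max(table, key=int)] = 0.5
        with pytest.raises(ValidationError, match="1.0"):
            type(base_params).model_validate(data)

    def test_ci_must_bracket_point(self):
        from afcea.parameters import RelativeRisk

        with pytest.raises(ValidationError):
            RelativeRisk(point=0.5, lo=0.6, hi=0.9)

    def test_severity_weights_must_sum_to_one(self, base_params):
        data = base_params.model_dump()
        data["settings"]["major_stroke_cost_weights"] = {"severe": 0.6, "moderate": 0.6}
        with pytest.raises(ValidationError, match="sum to 1"):
            type(base_params).model_validate(data)
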