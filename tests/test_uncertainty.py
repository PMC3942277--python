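"""Distribution fitting, PSA/CEAC, one-way sensitivity and scenarios."""

import numpy as np
import pytest

from afcea import uncertainty
from afcea.uncertainty import (
    DistributionSpec,
    PSASample,
    ceac_curve,
    default_psa_specs,
    get_parameter,
    lognormal_from_ci,
    moment_match,
    one_way_sensitivity,
    probability_cost_effective,
    run_psa,
    run_scenario,
    set_parameter,
)


class TestLognormalFromCI:
    def test_degenerate_interval_gives_zero_scale(self):
        mu, sigma = lognormal_from_ci(0.8, 0.8, 0.8)
        assert mu == pytest.approx(np.log(0.8))
        assert sigma == 0.0

    def test_stroke_rr_parameters(self):
        mu, sigma = lognormal_from_ci(0.79, 0.65, 0.95)
        assert mu == pytest.approx(-0.23572233352106983, abs=1e-9)
        assert sigma == pytest.approx(0.0968103551149163, abs=1e-9)

    def test_percentile_recovery_by_sampling(self):
        mu, sigma = lognormal_from_ci(0.79, 0.65, 0.95)
        rng = np.random.default_rng(2024)
        draws = rng.lognormal(mu, sigma, size=100_000)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert lo == pytest.approx(0.65, rel=0.02)
        assert hi == pytest.approx(0.95, rel=0.02)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            lognormal_from_ci(0.8, 0.9, 1.0)
        with pytest.raises(ValueError):
            lognormal_from_ci(0.8, -0.1, 1.0)


class TestMomentMatch:
    def test_beta_symmetric_example(self):
        assert moment_match("beta", 0.5, 0.1) == pytest.approx((12.0, 12.0))

    def test_gamma_example(self):
        assert moment_match("gamma", 100.0, 20.0) == pytest.approx((25.0, 4.0))

    def test_beta_infeasible_variance_rejected(self):
        with pytest.raises(ValueError):
            moment_match("beta", 0.5, 0.5)

    @pytest.mark.parametrize(
        "family, mean, se",
        [("beta", 0.0040, 0.0008), ("beta", 0.779, 0.05), ("gamma", 1093.0, 218.6)],
    )
    def test_moments_recovered_analytically(self, family, mean, se):
        a, b = moment_match(family, mean, se)
        if family == "beta":
            m = a / (a + b)
            v = a * b / ((a + b) ** 2 * (a + b + 1))
        else:
            m, v = a * b, a * b * b
        assert m == pytest.approx(mean, abs=1e-9)
        assert np.sqrt(v) == pytest.approx(se, abs=1e-9)

    def test_moments_recovered_empirically(self):
        a, b = moment_match("gamma", 1093.0, 218.6)
        rng = np.random.default_rng(7)
        draws = rng.gamma(a, b, size=100_000)
        se_of_mean = 218.6 / np.sqrt(draws.size)
        assert abs(draws.mean() - 1093.0) < 3 * se_of_mean


class TestParameterPaths:
    def test_get_and_set_scalar(self, base_params):
        assert get_parameter(base_params, "costs.transport_uptake") == 0.5
        ps = set_parameter(base_params, "costs.transport_uptake", 0.0)
        assert ps.costs.transport_uptake == 0.0
        assert base_params.costs.transport_uptake == 0.5  # original untouched

    def test_relative_risk_path_sets_point(self, base_params):
        ps = set_parameter(base_params, "effect.rr_is", 0.75)
        assert ps.effect.rr_is.point == 0.75

    def test_riva_effectiveness_scales_all_rrs(self, base_params):
        ps = set_parameter(base_params, uncertainty.RIVA_EFFECTIVENESS, 1.25)
        assert ps.effect.rr_is.point == pytest.approx(0.94 * 1.25)
        assert ps.effect.rr_ic.point == pytest.approx(0.67 * 1.25)

    def test_unknown_path_rejected(self, base_params):
        with pytest.raises(KeyError):
            get_parameter(base_params, "costs.nonexistent")
        with pytest.raises(KeyError):
            set_parameter(base_params, "nope.nope", 1.0)


class TestPSA:
    def test_fixed_specs_reproduce_base_deltas(self, base_params):
        from afcea.outcomes import compare_strategies

        _, _, base_inc = compare_strategies(base_params)
        specs = [DistributionSpec("costs.acute_mi", "fixed",
                                  mean=base_params.costs.acute_mi)]
        samples = run_psa(base_params, specs, n_iterations=3, seed=5)
        for s in samples:
            assert s.delta_cost == pytest.approx(base_inc.delta_cost, abs=1e-9)
            assert s.delta_qaly == pytest.approx(base_inc.delta_qaly, abs=1e-9)

    def test_seed_determinism_is_bit_exact(self, base_params):
        a = run_psa(base_params, n_iterations=5, seed=42)
        b = run_psa(base_params, n_iterations=5, seed=42)
        for sa, sb in zip(a, b):
            assert sa.values == sb.values
            assert sa.delta_cost == sb.delta_cost
            assert sa.delta_qaly == sb.delta_qaly

    def test_different_seeds_differ(self, base_params):
        a = run_psa(base_params, n_iterations=2, seed=1)
        b = run_psa(base_params, n_iterations=2, seed=2)
        assert a[0].values != b[0].values

    def test_default_specs_cover_the_uncertain_blocks(self, base_params):
        paths = {s.path for s in default_psa_specs(base_params)}
        assert "event_rates_vka.ischemic_stroke" in paths
        assert "effect.rr_is" in paths
        assert "utilities.vka_multiplier" in paths
        assert "costs.followup_mi" in paths
        assert "persistence.disc_subsequent_riva" in paths
        # administered prices stay fixed
        assert not any(p.startswith("costs.drug_daily") for p in paths)


class TestCEAC:
    def _samples(self, pairs):
        return [
            PSASample(index=i, values={}, delta_cost=dc, delta_qaly=dq)
            for i, (dc, dq) in enumerate(pairs)
        ]

    def test_all_dominant_gives_probability_one(self):
        samples = self._samples([(-10, 0.1), (-5, 0.2)])
        curve = ceac_curve(samples, [0.0, 30_000.0, 1e9])
        assert (curve["probability"] == 1.0).all()

    def test_brute_force_four_pairs(self):
        # NMB at 30k: 3100, -20, 400, -290 -> exactly half the draws qualify
        samples = self._samples([(-100, 0.1), (50, 0.001), (200, 0.02), (-10, -0.01)])
        assert probability_cost_effective(samples, 30_000.0) == pytest.approx(0.5)

    def test_zero_wtp_counts_cost_savings(self):
        samples = self._samples([(-100, 0.1), (50, 0.001), (200, 0.02), (-10, -0.01)])
        assert probability_cost_effective(samples, 0.0) == pytest.approx(0.5)

    def test_limit_is_fraction_with_positive_qaly_gain(self):
        samples = self._samples([(-100, 0.1), (50, 0.001), (200, 0.02), (-10, -0.01)])
        assert probability_cost_effective(samples, 1e12) == pytest.approx(0.75)

    def test_probabilities_stay_in_unit_interval(self, base_params):
        samples = self._samples([(0, 0), (1, -1), (-1, 1)])
        curve = ceac_curve(samples, base_params.settings.wtp_grid)
        assert ((curve["probability"] >= 0) & (curve["probability"] <= 1)).all()

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            ceac_curve([], [30_000.0])
        with pytest.raises(ValueError):
            ceac_curve(self._samples([(0, 0)]), [])


class TestOneWaySensitivity:
    def test_base_bounds_reproduce_base_classification(self, base_params):
        from afcea.outcomes import compare_strategies

        _, _, base_inc = compare_strategies(base_params)
        base_value = base_params.costs.maintenance_visits_per_cycle_vka
        entries = one_way_sensitivity(
            base_params,
            plan=[("costs.maintenance_visits_per_cycle_vka", base_value, base_value)],
        )
        e = entries[0]
        assert e.result_low.classification == base_inc.classification
        assert e.result_low.delta_cost == pytest.approx(base_inc.delta_cost, abs=1e-9)

    def test_monitoring_visits_drive_the_decision(self, base_params):
        entries = one_way_sensitivity(
            base_params, plan=[("costs.maintenance_visits_per_cycle_vka", 1.0, 5.0)]
        )
        e = entries[0]
        # sparse monitoring makes the comparator cheap: positive ICER;
        # intensive monitoring preserves dominance
        assert e.result_low.classification == "icer"
        assert e.result_low.icer_per_qaly > 0
        assert e.result_high.classification == "dominant"

    def test_transport_uptake_drives_the_decision(self, base_params):
        entries = one_way_sensitivity(
            base_params, plan=[("costs.transport_uptake", 0.0, 1.0)]
        )
        e = entries[0]
        assert e.result_low.classification == "icer"
        assert e.result_high.classification == "dominant"

    def test_base_outside_bounds_rejected(self, base_params):
        with pytest.raises(ValueError):
            one_way_sensitivity(base_params, plan=[("costs.transport_uptake", 0.6, 1.0)])

    def test_default_plan_runs_and_reports(self, base_params):
        entries = one_way_sensitivity(base_params)
        assert len(entries) == len(uncertainty.DEFAULT_OWSA_PLAN)
        frame = uncertainty.tornado_frame(entries)
        assert set(frame.columns) >= {"parameter", "base", "low", "high"}


class TestScenarios:
    def test_base_scenario_is_dominant(self, base_params):
        _, _, inc = run_scenario("sot_aspirin", base_params)
        assert inc.classification == "dominant"

    def test_switch_to_none_raises_event_burden(self, base_params):
        r_asp, _, _ = run_scenario("sot_aspirin", base_params)
        r_none, _, inc = run_scenario("sot_none", base_params)
        assert r_none.cost_events > r_asp.cost_events
        assert inc.classification == "dominant"

    def test_itt_with_no_second_line_yields_small_positive_icer(self, base_params):
        _, _, inc = run_scenario("itt_none", base_params)
        assert inc.classification == "icer"
        assert 0 < inc.icer_per_qaly < 5_000

    def test_no_disutility_remains_dominant_with_small_qaly_gain(self, base_params):
        _, _, base_inc = run_scenario("sot_aspirin", base_params)
        _, _, inc = run_scenario("no_vka_disutility", base_params)
        assert inc.classification == "dominant"
        assert 0 < inc.delta_qaly < base_inc.delta_qaly

    def test_rebates_deepen_the_saving(self, base_params):
        _, _, base_inc = run_scenario("sot_aspirin", base_params)
        _, _, r9 = run_scenario("rebate_9", base_params)
        _, _, r14 = run_scenario("rebate_14", base_params)
        assert r9.delta_cost < base_inc.delta_cost
        assert r14.delta_cost < r9.delta_cost

    def test_unknown_scenario_rejected(self, base_params):
        with pytest.raises(ValueError):
            run_scenario("warfarin_vs_placebo", base_params)
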