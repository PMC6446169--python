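"""Tornado ranges and CRN discipline, PSA convergence, scenario runners."""

import dataclasses

import numpy as np
import pytest

from cannacea.parameters import PATIENT_LEVEL_PARAMS, ParameterSpecs
from cannacea.sensitivity import (
    SCENARIOS,
    _pairwise_run,
    apply_override,
    one_way_ranges,
    one_way_tornado,
    run_psa,
    run_scenario,
)

N = 30_000
SEED = 11


class TestRanges:
    def test_class_rules(self, specs):
        r = one_way_ranges(specs)
        assert r["cannabis.or_nonserious"] == (1.42, 2.14)        # 95% CI
        assert r["cannabis.adherence"] == (0.78, 0.90)            # 95% CI
        assert r["cannabis.daily_thc_g"] == pytest.approx((0.033, 0.101))  # +/-1 SD
        assert r["cannabis.price_per_gram"] == pytest.approx((7.28, 14.84))
        assert r["utilities.mild"] == pytest.approx((0.5, 0.9))
        assert r["adherence_threshold"] == (0.5, 1.0)
        lo, hi = r["agents.duloxetine.p_nonserious_ae"]           # +/-25%
        assert (lo, hi) == pytest.approx((0.495, 0.825))
        lo, hi = r["utilities.moderate_severe"]                   # +/-50%
        assert (lo, hi) == pytest.approx((0.195, 0.585))
        assert all(lo < hi for lo, hi in r.values())

    def test_override_roundtrip(self, params):
        p = apply_override(params, "cannabis.daily_thc_g", 0.101)
        assert p.cannabis.daily_thc_g == 0.101
        p = apply_override(params, "agents.gabapentin.adherence", 0.5)
        assert p.agent("gabapentin").adherence_mean == 0.5
        p = apply_override(params, "utilities.mild", 0.9)
        assert p.u_mild == 0.9

    def test_override_outside_support_clipped(self, params, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="cannacea.sensitivity"):
            p = apply_override(params, "agents.duloxetine.adherence", 1.04)
        assert 0 < p.agent("duloxetine").adherence_mean < 1
        assert any("clipped" in r.message for r in caplog.records)

    def test_unknown_override_rejected(self, params):
        with pytest.raises(KeyError):
            apply_override(params, "cannabis.flavor", 1.0)


class TestCommonRandomNumbers:
    def test_endpoint_fixed_at_base_recovers_base_icer_exactly(self, params):
        """CRN discipline: an 'override' equal to the base value reproduces
        the base pairwise ICER bit for bit."""
        base_icer, _ = _pairwise_run(params, N, SEED, 1.0, None)
        p = apply_override(params, "cannabis.daily_thc_g",
                           params.cannabis.daily_thc_g)
        again, _ = _pairwise_run(p, N, SEED, 1.0, None)
        assert again == base_icer

    def test_tornado_directions_for_reported_parameters(self, params, specs):
        """Lower cannabis adherence raises the ICER sharply; a higher THC
        dose raises it but leaves second-line cost-effective at $100k."""
        base_icer, _ = _pairwise_run(params, N, SEED, 1.0, None)
        entries = {e.parameter: e for e in one_way_tornado(
            params, specs, N, SEED,
            parameters=["cannabis.adherence", "cannabis.daily_thc_g"])}
        adh = entries["cannabis.adherence"]
        assert adh.icer_at_low > 1.5 * base_icer
        thc = entries["cannabis.daily_thc_g"]
        assert base_icer < thc.icer_at_high < 100_000
        assert thc.icer_at_low < base_icer


class TestPsa:
    def test_single_iteration_ceac_is_indicator(self, specs):
        res = run_psa(specs, n_iterations=1, n_patients_per_iteration=2000,
                      wtp_grid=[0.0, 100_000.0], seed=5)
        assert set(np.unique(res.ceac.values)) <= {0.0, 1.0}
        assert np.allclose(res.ceac.sum(axis=1), 1.0)

    def test_degenerate_dispersions_collapse_to_point_estimates(self, specs, params):
        """With every second-order dispersion collapsed to zero, each PSA
        parameter draw equals the point-estimate parameter set, so the PSA
        converges to the base case (the engine itself is deterministic
        given a seed, which is covered separately)."""
        degenerate = {}
        for name in specs.names():
            s = specs[name]
            changes = {}
            if s.dispersion is not None:
                changes["dispersion"] = 0.0
            if s.ci_low is not None:
                eps = abs(s.mean) * 1e-13 + 1e-15
                changes.update(ci_low=s.mean - eps, ci_high=s.mean + eps)
            if s.family == "triangular":
                changes.update(lo=s.mean - 1e-13, hi=s.mean + 1e-13, mode=s.mean)
            degenerate[name] = dataclasses.replace(s, **changes)
        dspecs = ParameterSpecs(degenerate, specs.settings)
        rng = np.random.default_rng(9)
        for _ in range(5):
            drawn = dspecs.sample(rng)
            for field in ("u_mild", "u_modsev", "visit_regular", "adherence_threshold",
                          "sae_hospital_oop"):
                assert getattr(drawn, field) == pytest.approx(
                    getattr(params, field), abs=1e-9)
            assert drawn.cannabis.price_per_gram == pytest.approx(11.06, abs=1e-9)
            for got, want in zip(drawn.agents, params.agents):
                assert got.p_nonserious_ae == want.p_nonserious_ae
                assert got.discontinuation_rate == want.discontinuation_rate
                assert got.wholesale_cost_per_month == pytest.approx(
                    want.wholesale_cost_per_month, abs=1e-9)

    def test_psa_reproducible_under_seed(self, specs):
        a = run_psa(specs, 4, 1500, [50_000.0], seed=21)
        b = run_psa(specs, 4, 1500, [50_000.0], seed=21)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.qalys, b.qalys)

    def test_patient_level_params_stay_fixed_across_iterations(self, specs):
        rng = np.random.default_rng(2)
        draws = [specs.sample(rng) for _ in range(5)]
        assert len({d.cannabis.pain_reduction_mean for d in draws}) == 1
        assert len({d.cannabis.price_per_gram for d in draws}) == 5
        assert "cannabis.pain_reduction" in PATIENT_LEVEL_PARAMS


class TestScenarios:
    def test_base_scenario_is_identity(self, params):
        sc = run_scenario("base", params, N, SEED)
        from cannacea.engine import run_strategies
        direct = run_strategies(params, N, SEED)
        assert sc.results["usual_care"] == direct["usual_care"]
        assert sc.results["second_line_cannabis"] == direct["second_line_cannabis"]

    def test_unknown_scenario_rejected(self, params):
        with pytest.raises(ValueError, match="unknown scenario"):
            run_scenario("martian", params, 100, SEED)

    def test_wastage_raises_cannabis_arm_costs_only(self, params):
        base = run_scenario("base", params, N, SEED)
        wst = run_scenario("wastage", params, N, SEED)
        assert wst.results["usual_care"] == base.results["usual_care"]
        for arm in ("first_line_cannabis", "second_line_cannabis", "third_line_cannabis"):
            assert wst.results[arm].mean_cost > base.results[arm].mean_cost
            assert wst.results[arm].mean_qaly == base.results[arm].mean_qaly

    def test_nonuser_ors_shrink_gain_and_raise_cost(self, params):
        """Excluding active users raises both odds ratios: the second-line
        QALY gain over usual care shrinks and its incremental cost grows."""
        base = run_scenario("base", params, N, SEED)
        alt = run_scenario("nonuser_ors", params, N, SEED)

        def deltas(sc):
            u, s = sc.results["usual_care"], sc.results["second_line_cannabis"]
            return s.mean_cost - u.mean_cost, s.mean_qaly - u.mean_qaly

        dc_base, dq_base = deltas(base)
        dc_alt, dq_alt = deltas(alt)
        assert dq_alt < dq_base
        assert dc_alt > dc_base

    def test_horizon_scenarios_extend_cycles(self, params):
        sc = run_scenario("horizon_5y", params, 2000, SEED)
        assert sc.horizon_years == 5.0
        assert sc.results["usual_care"].mean_qaly > 4 * \
            run_scenario("base", params, 2000, SEED).results["usual_care"].mean_qaly

    def test_all_named_scenarios_run(self, params):
        for name in SCENARIOS:
            sc = run_scenario(name, params, 1000, SEED)
            assert len(sc.frontier) == 4
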