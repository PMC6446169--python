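"""Cycle logic: odds ratios, adverse events, switching, and cohort runs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cannacea.cohort import Patient
from cannacea.engine import (
    Regimen,
    advance_cycle,
    apply_odds_ratio,
    classify_pain_state,
    cycle_weights,
    draw_adverse_events,
    run_cohort,
    run_strategies,
    simulate_patient,
)
from cannacea.parameters import AGENTS

from conftest import tweak_agents, tweak_cannabis


class TestOddsRatio:
    @pytest.mark.parametrize("p, or_, expected", [
        (0.66, 1.0, 0.66),
        (0.0, 3.7, 0.0),
        (1.0, 0.2, 1.0),
        (0.66, 1.74, 0.7716),   # duloxetine nonserious rate under co-use
        (0.024, 1.08, 0.02587),
    ])
    def test_known_values(self, p, or_, expected):
        assert apply_odds_ratio(p, or_) == pytest.approx(expected, abs=5e-5)

    @given(p=st.floats(0.0, 1.0), logo=st.floats(-3, 3))
    @settings(max_examples=200, derandomize=True)
    def test_stays_a_probability_and_monotone(self, p, logo):
        out = apply_odds_ratio(p, float(np.exp(logo)))
        assert 0.0 <= out <= 1.0
        assert apply_odds_ratio(p, np.exp(logo) * 1.5) >= out - 1e-12


class TestPainState:
    @pytest.mark.parametrize("baseline, reductions, state", [
        (6.20, [2.57], "mild"),            # mean duloxetine response
        (6.20, [], "moderate_severe"),
        (8.0, [4.0], "moderate_severe"),   # achieved exactly 4: strict cutoff
        (4.5, [9.0], "mild"),              # floor at zero
    ])
    def test_classification(self, baseline, reductions, state):
        assert classify_pain_state(baseline, reductions) == state

    def test_invalid_baseline_rejected(self):
        with pytest.raises(ValueError):
            classify_pain_state(11.0, [])


class TestAdverseEvents:
    def test_fully_nonadherent_patient_never_has_events(self, params, rng):
        regimen = Regimen(agent="duloxetine", agent_adherent=False,
                          cannabis_active=True, cannabis_adherent=False)
        assert all(draw_adverse_events(regimen, params, rng) == "none"
                   for _ in range(200))

    def test_couse_serious_rate_matches_odds_transform(self, params):
        """Monte-Carlo frequency of serious AEs on duloxetine + cannabis
        matches the closed-form odds-ratio modification of 2.4%."""
        regimen = Regimen(agent="duloxetine", agent_adherent=True,
                          cannabis_active=True, cannabis_adherent=True)
        rng = np.random.default_rng(12)
        n = 40_000
        hits = sum(draw_adverse_events(regimen, params, rng) == "serious"
                   for _ in range(n))
        expected = apply_odds_ratio(0.024, 1.08)
        se = np.sqrt(expected * (1 - expected) / n)
        assert hits / n == pytest.approx(expected, abs=3 * se)

    def test_cannabis_only_branch_uses_monotherapy_rates(self, params):
        from cannacea.engine import _ae_probability_arrays, _agent_arrays
        p_ns, p_int, p_sae = _ae_probability_arrays(
            params, _agent_arrays(params), np.array([0]),
            agent_contrib=np.array([False]), cann_contrib=np.array([True]))
        assert (p_ns[0], p_int[0], p_sae[0]) == (0.586, 0.046, 0.005)

    def test_couse_intolerable_combines_independent_risks(self, params):
        from cannacea.engine import _ae_probability_arrays, _agent_arrays
        _, p_int, _ = _ae_probability_arrays(
            params, _agent_arrays(params), np.array([0]),
            agent_contrib=np.array([True]), cann_contrib=np.array([True]))
        assert p_int[0] == pytest.approx(1 - (1 - 0.157) * (1 - 0.046))


class TestCycleWeights:
    def test_one_year_is_eight_and_two_thirds_cycles(self):
        w = cycle_weights(1.0)
        assert len(w) == 9
        assert np.all(w[:8] == 1.0)
        assert w[8] == pytest.approx(2 / 3, abs=1e-9)
        assert w.sum() == pytest.approx(52 / 6)

    def test_five_years(self):
        w = cycle_weights(5.0)
        assert len(w) == 44 and w[-1] == pytest.approx(1 / 3, abs=1e-9)

    def test_bad_horizon(self):
        with pytest.raises(ValueError):
            cycle_weights(0.0)


def _quiet_patient(baseline=9.0, reduction=0.5, cannabis_response=0.3,
                   adherent=True, cannabis_adherent=True):
    return Patient(age=59.0, age_band="45-64", baseline_pain=baseline,
                   agent_sequence=AGENTS,
                   response_draws={a: reduction for a in AGENTS},
                   adherent={a: adherent for a in AGENTS},
                   cannabis_response=cannabis_response,
                   cannabis_adherent=cannabis_adherent, _band_index=1)


@pytest.fixture(scope="session")
def no_event_params(null_cannabis_params):
    """No adverse events or discontinuation anywhere: switching can only
    come from the two-cycle poor-relief rule."""
    return tweak_agents(null_cannabis_params,
                        p_nonserious_ae=0.0, p_intolerable_ae=0.0,
                        p_serious_ae=0.0, discontinuation_rate=0.0)


class TestAdvanceCycle:
    def test_two_poor_relief_cycles_trigger_switch(self, no_event_params, rng):
        patient = _quiet_patient()
        out0 = advance_cycle(patient, "usual_care", no_event_params, 0, rng)
        assert not out0.switched and patient.poor_relief_cycles_on_current == 1
        out1 = advance_cycle(patient, "usual_care", no_event_params, 1, rng)
        assert out1.switched and patient.current_line == 2
        assert patient.poor_relief_cycles_on_current == 0

    def test_usual_care_never_starts_cannabis(self, no_event_params, rng):
        patient = _quiet_patient()
        for k in range(6):
            advance_cycle(patient, "usual_care", no_event_params, k, rng)
        assert patient.cannabis_state == "not_started"

    def test_second_line_cannabis_starts_with_second_agent(self, no_event_params, rng):
        patient = _quiet_patient()
        advance_cycle(patient, "second_line_cannabis", no_event_params, 0, rng)
        advance_cycle(patient, "second_line_cannabis", no_event_params, 1, rng)
        assert patient.cannabis_state == "not_started"  # still on first agent
        assert patient.current_line == 2
        advance_cycle(patient, "second_line_cannabis", no_event_params, 2, rng)
        assert patient.cannabis_state == "active"

    def test_good_relief_resets_poor_counter(self, no_event_params, rng):
        patient = _quiet_patient(baseline=4.5, reduction=2.0)
        out = advance_cycle(patient, "usual_care", no_event_params, 0, rng)
        assert out.good_relief and out.end_pain_state == "mild"
        assert patient.poor_relief_cycles_on_current == 0

    def test_cannot_advance_the_dead(self, no_event_params, rng):
        patient = _quiet_patient()
        patient.alive = False
        with pytest.raises(ValueError):
            advance_cycle(patient, "usual_care", no_event_params, 0, rng)

    def test_nonadherent_cannabis_fails_after_two_cycles(self, no_event_params, rng):
        patient = _quiet_patient(cannabis_adherent=False)
        for k in range(3):
            advance_cycle(patient, "first_line_cannabis", no_event_params, k, rng)
        assert patient.cannabis_state == "failed"


class TestSimulatePatient:
    def test_closed_form_qalys_when_always_mild(self, deterministic_mild_params):
        """Relief from cycle 1 on: QALYs are the discounted mild-utility
        series, matching the closed form exactly."""
        p = deterministic_mild_params
        ledger = simulate_patient("usual_care", p, rng=np.random.default_rng(0),
                                  horizon_years=1.0)
        w = cycle_weights(1.0)
        dt = 42 / 365.25
        expected = sum(wk * dt * 0.7 * 1.03 ** (-(k * dt)) for k, wk in enumerate(w))
        assert ledger.discounted_qalys == pytest.approx(expected, rel=1e-12)
        assert ledger.cycles_survived == len(w)
        # drug + visit costs, never a hospitalization
        drug = (254 + 13) * 42 / 30.4375
        visits = 111 + 51
        exp_cost = sum(wk * (drug + visits) * 1.03 ** (-(k * dt))
                       for k, wk in enumerate(w))
        assert ledger.discounted_cost_total == pytest.approx(exp_cost, rel=1e-12)
        assert ledger.cost_components.sae_hospital == 0.0

    def test_single_cycle_horizon(self, deterministic_mild_params):
        ledger = simulate_patient("usual_care", deterministic_mild_params,
                                  horizon_cycles=1, rng=np.random.default_rng(0))
        assert ledger.discounted_qalys == pytest.approx(0.7 * 42 / 365.25)

    def test_zero_cycle_horizon_rejected(self, params):
        with pytest.raises(ValueError):
            simulate_patient("usual_care", params, horizon_cycles=0,
                             rng=np.random.default_rng(0))

    def test_all_nonadherent_patient_trace(self, no_event_params, rng):
        """Adherent to nothing: never mild, switches agents every two
        cycles, no adverse-event costs."""
        p = no_event_params.replace(adherence_threshold=1.0)
        patient = _quiet_patient(adherent=False, cannabis_adherent=False)
        lines = []
        for k in range(8):
            out = advance_cycle(patient, "usual_care", p, k, rng)
            assert not out.good_relief and out.ae_class == "none"
            lines.append(patient.current_line)
        assert lines == [1, 2, 2, 3, 3, 4, 4, 4]  # capped at the last agent


class TestCohortRuns:
    def test_same_seed_identical_results(self, params):
        a = run_cohort("usual_care", params, 5_000, seed=42)
        b = run_cohort("usual_care", params, 5_000, seed=42)
        assert a == b

    def test_monte_carlo_consistency_across_sizes(self, params):
        small = run_cohort("usual_care", params, 20_000, seed=1)
        large = run_cohort("usual_care", params, 100_000, seed=2)
        se = np.hypot(small.se_qaly, large.se_qaly)
        assert abs(small.mean_qaly - large.mean_qaly) < 4 * se
        se_c = np.hypot(small.se_cost, large.se_cost)
        assert abs(small.mean_cost - large.mean_cost) < 4 * se_c

    def test_null_cannabis_makes_all_arms_coincide(self, null_cannabis_params):
        """With inert cannabis the four strategies are the same model; under
        common random numbers they coincide to numerical precision."""
        res = run_strategies(null_cannabis_params, 20_000, seed=5)
        costs = [r.mean_cost for r in res.values()]
        qalys = [r.mean_qaly for r in res.values()]
        assert max(costs) - min(costs) < 1e-9 * max(costs)
        assert max(qalys) - min(qalys) < 1e-9

    def test_ledger_conservation_and_qaly_bounds(self, params):
        from cannacea.economics import COMPONENTS
        result, ledgers = run_cohort("second_line_cannabis", params, 5_000,
                                     seed=3, return_ledgers=True)
        total = sum(ledgers[c] for c in COMPONENTS)
        assert np.allclose(total, ledgers["total_cost"])
        assert (ledgers["qalys"] >= 0).all()
        assert (ledgers["qalys"] <= 1.0 * params.u_mild + 1e-12).all()
        assert (ledgers[list(COMPONENTS)] >= 0).all().all()

    def test_cost_monotone_in_cannabis_price(self, params):
        costs = []
        for price in (0.0, 11.06, 30.0):
            p = tweak_cannabis(params, price_per_gram=price)
            costs.append(run_cohort("second_line_cannabis", p, 30_000, seed=6).mean_cost)
        assert costs[0] < costs[1] < costs[2]

    def test_qalys_monotone_in_cannabis_efficacy(self, params):
        qalys = []
        for eff in (0.0, 1.11, 3.0):
            p = tweak_cannabis(params, pain_reduction_mean=eff)
            qalys.append(run_cohort("second_line_cannabis", p, 30_000, seed=6).mean_qaly)
        assert qalys[0] < qalys[1] < qalys[2]

    def test_death_only_through_serious_events(self, params):
        p = tweak_agents(params, p_serious_ae=0.0)
        p = tweak_cannabis(p, p_serious_mono=0.0)
        _, ledgers = run_cohort("second_line_cannabis", p, 10_000, seed=7,
                                return_ledgers=True)
        assert (ledgers["cycles_survived"] == len(cycle_weights(1.0))).all()

    def test_unknown_strategy_rejected(self, params):
        with pytest.raises(ValueError, match="unknown strategy"):
            run_cohort("fifth_line", params, 10, seed=1)

    def test_seed_required(self, params):
        with pytest.raises(ValueError, match="seed"):
            run_cohort("usual_care", params, 10)
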