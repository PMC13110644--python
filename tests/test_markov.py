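"""Markov engine: transition-row construction, discounting, cohort
propagation, totals and the microsimulation oracle."""
from __future__ import annotations

import numpy as np
import pytest

from fracture_cea import generate_parameter_set
from fracture_cea.markov import (
    build_transition_matrix,
    cycle1_report,
    discount_factor,
    microsim_oracle,
    run_cohort,
    run_strategy,
    trace_totals,
)
from fracture_cea.decision_tree import initial_state_distribution
from fracture_cea.parameters import ParameterError, deannualize_risk
from fracture_cea.states import (
    DEAD,
    FRACTURE,
    N_STATES,
    POST_FRACTURE,
    STATE_INDEX,
    TREATED_OP,
    UNTREATED_OP,
    StateDistribution,
)

from conftest import edit_bundle, full_health_bundle


def annuity(rate: float, n: int) -> float:
    """Independent closed form for sum of (1+r)^-k, k = 0..n-1."""
    if rate == 0:
        return float(n)
    v = 1.0 / (1.0 + rate)
    return (1.0 - v**n) / (1.0 - v)


class TestTransitionMatrix:
    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("age", [40, 55, 70, 85, 100])
    def test_rows_stochastic_everywhere(self, seed, age):
        P = build_transition_matrix(age, generate_parameter_set(seed))
        np.testing.assert_allclose(P.sum(axis=1), np.ones(N_STATES), atol=1e-10)
        assert np.all(P >= 0) and np.all(P <= 1)

    def test_dead_row_absorbing(self, mof_bundle):
        P = build_transition_matrix(60, mof_bundle)
        expected = np.zeros(N_STATES)
        expected[DEAD] = 1.0
        np.testing.assert_array_equal(P[DEAD], expected)

    def test_untreated_row_death_first_allocation(self, mof_bundle):
        # enumerate the two-event tree: die (0.01), else fracture (0.05)
        bundle = edit_bundle(mof_bundle, **{
            "epidemiology.p10_fracture_by_state.osteoporosis":
                deannualize_risk(0.05, 10),
            "epidemiology.background_mortality.60": 0.01})
        P = build_transition_matrix(60, bundle)
        assert P[UNTREATED_OP, DEAD] == pytest.approx(0.01)
        assert P[UNTREATED_OP, FRACTURE] == pytest.approx(0.99 * 0.05)
        assert P[UNTREATED_OP, UNTREATED_OP] == pytest.approx(1 - 0.01 - 0.0495)

    def test_treatment_relative_risk_is_exact_multiplier(self, mof_bundle):
        bundle = edit_bundle(mof_bundle, **{"epidemiology.rr_bisphosphonate": 0.5})
        P = build_transition_matrix(60, bundle)
        assert P[TREATED_OP, FRACTURE] == pytest.approx(
            0.5 * P[UNTREATED_OP, FRACTURE])

    def test_fracture_state_is_one_cycle_tunnel(self, mof_bundle):
        P = build_transition_matrix(60, mof_bundle)
        assert P[FRACTURE, FRACTURE] == 0.0
        assert P[FRACTURE, POST_FRACTURE] + P[FRACTURE, DEAD] == pytest.approx(1.0)

    def test_excess_mortality_capped_with_warning(self, hf_bundle):
        bundle = edit_bundle(hf_bundle, **{
            "epidemiology.fracture_mortality_multiplier": 10.0})
        with pytest.warns(RuntimeWarning, match="capped"):
            P = build_transition_matrix(99, bundle)
        assert P[FRACTURE, DEAD] == 1.0

    def test_age_outside_range_rejected(self, mof_bundle):
        with pytest.raises(ParameterError, match="age"):
            build_transition_matrix(39, mof_bundle)


class TestDiscounting:
    def test_examples(self):
        assert discount_factor(0.035, 0) == 1.0
        assert discount_factor(0.0, 17) == 1.0
        assert discount_factor(0.035, 1) == pytest.approx(1 / 1.035)

    def test_negative_cycle_rejected(self):
        with pytest.raises(ParameterError):
            discount_factor(0.035, -1)


class TestCohortRun:
    def test_full_health_undiscounted_annuity(self, mof_bundle):
        bundle = full_health_bundle(mof_bundle, discount_rate=0.0)
        _, outcome = run_strategy("S3", edit_bundle(bundle, **{
            "costs.cost_dxa": 0.0, "costs.cost_risk_score": 0.0}))
        assert outcome.mean_qaly == pytest.approx(60.0, abs=1e-9)

    def test_full_health_discounted_annuity_closed_form(self, mof_bundle):
        bundle = full_health_bundle(mof_bundle, discount_rate=0.035)
        _, outcome = run_strategy("S3", bundle)
        assert outcome.mean_qaly == pytest.approx(annuity(0.035, 60), abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_and_dead_monotone(self, seed):
        bundle = generate_parameter_set(seed)
        for sid in ("S1", "S2", "S3"):
            trace, _ = run_strategy(sid, bundle)
            totals = trace.occupancy.sum(axis=1)
            np.testing.assert_allclose(totals, 1000.0, atol=1e-8)
            dead = trace.occupancy[:, DEAD]
            assert np.all(np.diff(dead) >= -1e-12)
            alive = totals - dead
            assert np.all(np.diff(alive) <= 1e-12)

    def test_discounted_streams_bounded_by_undiscounted(self, mof_bundle):
        trace, _ = run_strategy("S2", mof_bundle)
        assert np.all(trace.disc_cost <= trace.cycle_cost + 1e-12)
        assert np.all(trace.disc_qaly <= trace.cycle_qaly + 1e-12)

    def test_qaly_equals_life_expectancy_from_survival_curve(self, mof_bundle):
        # unit utilities, zero discount: QALYs must equal sum of the alive
        # fraction over cycles, computed independently from the trace
        bundle = edit_bundle(mof_bundle, **{
            "config.discount_rate": 0.0,
            "utilities.baseline_utility_by_age":
                {str(a): 1.0 for a in range(40, 101)},
            "utilities.fracture_year_multiplier": 1.0,
            "utilities.postfracture_multiplier": 1.0})
        trace, outcome = run_strategy("S1", bundle)
        alive_per_cycle = 1.0 - trace.occupancy[:-1, DEAD] / trace.cohort_size
        assert outcome.mean_qaly == pytest.approx(alive_per_cycle.sum(), abs=1e-9)

    def test_zero_fracture_risk_equalises_qalys_across_strategies(self, mof_bundle):
        bundle = edit_bundle(mof_bundle, **{
            "epidemiology.p10_fracture_by_state":
                {"osteoporosis": 0.0, "osteopenia": 0.0, "normal": 0.0},
            "epidemiology.refracture_annual": 0.0})
        qalys = [run_strategy(sid, bundle)[1].mean_qaly for sid in ("S1", "S2", "S3")]
        assert max(qalys) - min(qalys) < 1e-9

    def test_ten_year_horizon_runs_ten_cycles(self, mof_bundle):
        bundle = edit_bundle(mof_bundle, **{"config.horizon_mode": "ten_year"})
        trace, _ = run_strategy("S1", bundle)
        assert len(trace.ages) == 10


class TestTotals:
    def test_scale_invariance_of_per_person_means(self, mof_bundle):
        out = initial_state_distribution("S2", mof_bundle)
        trace = run_cohort(out.initial_distribution, mof_bundle, out.upfront_cost)
        base = trace_totals(trace)
        doubled = edit_bundle(mof_bundle, **{"config.cohort_size": 2000.0})
        out2 = initial_state_distribution("S2", doubled)
        trace2 = run_cohort(out2.initial_distribution, doubled, out2.upfront_cost)
        scaled = trace_totals(trace2)
        assert scaled.mean_cost == pytest.approx(base.mean_cost, rel=1e-12)
        assert scaled.mean_qaly == pytest.approx(base.mean_qaly, rel=1e-12)

    def test_all_dead_cohort_accrues_only_upfront_cost(self, mof_bundle):
        counts = np.zeros(N_STATES)
        counts[STATE_INDEX["dead"]] = 1000.0
        trace = run_cohort(StateDistribution(counts), mof_bundle, upfront_cost=5000.0)
        outcome = trace_totals(trace)
        assert outcome.mean_cost == pytest.approx(5.0)
        assert outcome.mean_qaly == 0.0

    def test_trace_frame_tidy_export(self, mof_bundle):
        trace, _ = run_strategy("S1", mof_bundle)
        frame = trace.to_frame()
        assert set(frame.columns) >= {"cycle", "age", "state", "occupancy"}
        assert len(frame) == len(trace.ages) * N_STATES

    def test_cycle1_occupancy_sums_to_cohort(self, mof_bundle):
        report = cycle1_report(mof_bundle)
        np.testing.assert_allclose(report["total"], 1000.0, atol=1e-9)


class TestMicrosimOracle:
    def test_deterministic_chain_matches_cohort_exactly(self, mof_bundle):
        bundle = full_health_bundle(mof_bundle, discount_rate=0.035)
        out = initial_state_distribution("S3", bundle)
        cohort = trace_totals(run_cohort(out.initial_distribution, bundle,
                                         out.upfront_cost))
        micro = microsim_oracle(out.initial_distribution, bundle, out.upfront_cost,
                                n_individuals=500, seed=0)
        # nobody moves and utilities are flat, so the walk is deterministic
        assert micro.mean_qaly == pytest.approx(cohort.mean_qaly, abs=1e-9)
        assert micro.se_qaly == pytest.approx(0.0, abs=1e-9)

    def test_same_seed_reproducible(self, mof_bundle):
        out = initial_state_distribution("S2", mof_bundle)
        runs = [microsim_oracle(out.initial_distribution, mof_bundle,
                                out.upfront_cost, 2000, seed=42) for _ in range(2)]
        assert runs[0] == runs[1]

    def test_cohort_within_monte_carlo_error(self, mof_bundle):
        out = initial_state_distribution("S2", mof_bundle)
        cohort = trace_totals(run_cohort(out.initial_distribution, mof_bundle,
                                         out.upfront_cost))
        micro = microsim_oracle(out.initial_distribution, mof_bundle,
                                out.upfront_cost, 8000, seed=11)
        assert abs(micro.mean_cost - cohort.mean_cost) < 3 * micro.se_cost
        assert abs(micro.mean_qaly - cohort.mean_qaly) < 3 * micro.se_qaly

    def test_rejects_nonpositive_population(self, mof_bundle):
        out = initial_state_distribution("S1", mof_bundle)
        with pytest.raises(ParameterError):
            microsim_oracle(out.initial_distribution, mof_bundle, 0.0, 0, seed=1)
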