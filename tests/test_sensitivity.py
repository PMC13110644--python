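"""Scenario application, the deterministic grid, PSA sampling and CEAC."""
from __future__ import annotations

import numpy as np
import pytest

from fracture_cea.parameters import ParameterError
from fracture_cea.sensitivity import (
    ScenarioSpec,
    apply_scenario,
    builtin_scenario_grid,
    compute_ceac,
    draw_psa_bundle,
    evaluate_bundle,
    run_dsa,
    run_psa,
)
from fracture_cea.states import FRACTURE
from fracture_cea.markov import run_strategy

IDENTITY = ScenarioSpec("identity", "costs.cost_dxa", "multiply", 1.0)


class TestApplyScenario:
    def test_single_field_changed(self, mof_bundle):
        spec = ScenarioSpec("dxa_doubled", "costs.cost_dxa", "multiply", 2.0)
        modified = apply_scenario(mof_bundle, spec)
        assert modified.costs.cost_dxa == 2 * mof_bundle.costs.cost_dxa
        d0, d1 = mof_bundle.to_dict(), modified.to_dict()
        d0["costs"].pop("cost_dxa"), d1["costs"].pop("cost_dxa")
        assert d0 == d1  # everything else bit-identical

    def test_set_value(self, mof_bundle):
        spec = ScenarioSpec("full_adherence", "epidemiology.adherence_annual",
                            "set_value", 1.0)
        assert apply_scenario(mof_bundle, spec).epidemiology.adherence_annual == 1.0

    def test_identity_is_noop(self, mof_bundle):
        assert apply_scenario(mof_bundle, IDENTITY).to_dict() == mof_bundle.to_dict()

    def test_original_untouched(self, mof_bundle):
        before = mof_bundle.to_dict()
        apply_scenario(mof_bundle, ScenarioSpec("x", "costs.cost_dxa", "multiply", 3.0))
        assert mof_bundle.to_dict() == before

    def test_unknown_path_rejected(self, mof_bundle):
        with pytest.raises(ParameterError, match="path"):
            apply_scenario(mof_bundle, ScenarioSpec("x", "costs.nope", "multiply", 2.0))

    def test_invariant_violating_modification_rejected(self, mof_bundle):
        spec = ScenarioSpec("bad", "epidemiology.adherence_annual", "multiply", 5.0)
        with pytest.raises(ParameterError):
            apply_scenario(mof_bundle, spec)


class TestDsa:
    def test_identity_scenario_reproduces_base_case(self, mof_bundle):
        _, base = evaluate_bundle(mof_bundle)
        table = run_dsa(mof_bundle, scenarios=[IDENTITY])
        for comp in base:
            row = table[(table.intervention == comp.intervention)
                        & (table.comparator == comp.comparator)].iloc[0]
            assert row.delta_cost == comp.delta_cost
            assert row.delta_qaly == comp.delta_qaly

    def test_builtin_grid_covers_named_scenarios(self, mof_bundle):
        labels = {s.label for s in builtin_scenario_grid(mof_bundle)}
        assert {"adherence_100pct", "adherence_minus20pct",
                "cost_dxa_halved", "cost_dxa_doubled",
                "s1_screened_fraction_1pct", "s1_screened_fraction_5pct",
                "ten_year_horizon", "lifetime_linear_risk",
                "idfracture_sensitivity_99_9pct"} <= labels

    def test_irrelevant_cost_leaves_icer_unchanged(self, mof_bundle):
        # the risk-score cost touches only scored persons; with no one
        # scored in S1 and no risk-score use in S3, doubling it shifts S2
        # only -- but doubling a cost attached to an unoccupied state
        # (post-fracture when no one can fracture) changes nothing at all
        from conftest import edit_bundle
        zero_risk = edit_bundle(mof_bundle, **{
            "epidemiology.p10_fracture_by_state":
                {"osteoporosis": 0.0, "osteopenia": 0.0, "normal": 0.0},
            "epidemiology.refracture_annual": 0.0})
        _, base = evaluate_bundle(zero_risk)
        spec = ScenarioSpec("fx_cost_doubled", "costs.cost_fracture_year1",
                            "multiply", 2.0)
        _, varied = evaluate_bundle(apply_scenario(zero_risk, spec))
        for c0, c1 in zip(base, varied):
            assert c1.delta_cost == pytest.approx(c0.delta_cost, abs=1e-12)
            assert c1.icer.value == pytest.approx(c0.icer.value, abs=1e-9)

    def test_halved_fracture_cost_matches_subtraction_oracle(self, mof_bundle):
        # linearity: the cost change equals the discounted fracture-state
        # occupancy stream times half the unit cost, from the unmodified trace
        spec = ScenarioSpec("fx_halved", "costs.cost_fracture_year1", "multiply", 0.5)
        modified = apply_scenario(mof_bundle, spec)
        for sid in ("S1", "S2", "S3"):
            trace, base_out = run_strategy(sid, mof_bundle)
            _, mod_out = run_strategy(sid, modified)
            disc = (1 + mof_bundle.config.discount_rate) ** -np.arange(len(trace.ages))
            fx_stream = (trace.occupancy[:-1, FRACTURE] * disc).sum()
            expected_drop = 0.5 * mof_bundle.costs.cost_fracture_year1 * fx_stream / 1000
            assert base_out.mean_cost - mod_out.mean_cost == pytest.approx(
                expected_drop, rel=1e-9)

    def test_empty_scenario_list_rejected(self, mof_bundle):
        with pytest.raises(ParameterError):
            run_dsa(mof_bundle, scenarios=[])


class TestPsaSampling:
    def test_support_constraints(self, mof_bundle):
        for seed in range(5):
            sampled = draw_psa_bundle(mof_bundle, seed)
            sampled.validate()
            epi = sampled.epidemiology
            assert 0 <= epi.adherence_annual <= 1
            assert all(0 <= p <= 1 for p in epi.p10_fracture_by_state.values())
            assert all(c >= 0 for c in vars(sampled.costs).values())

    def test_boundary_parameters_held_fixed(self, mof_bundle):
        sampled = draw_psa_bundle(mof_bundle, 1)
        assert sampled.screening["S3"].sensitivity == 1.0
        assert sampled.screening["S2"].screened_fraction == 1.0

    def test_structural_config_never_sampled(self, mof_bundle):
        sampled = draw_psa_bundle(mof_bundle, 2)
        assert sampled.to_dict()["config"] == mof_bundle.to_dict()["config"]

    def test_tiny_cv_collapses_to_base(self, mof_bundle):
        from conftest import edit_bundle
        tight = edit_bundle(mof_bundle, **{
            "uncertainty": {"probabilities": 1e-4, "utilities": 1e-4, "costs": 1e-4}})
        sampled = draw_psa_bundle(tight, 3)
        assert sampled.epidemiology.adherence_annual == pytest.approx(
            mof_bundle.epidemiology.adherence_annual, rel=1e-3)
        assert sampled.costs.cost_dxa == pytest.approx(
            mof_bundle.costs.cost_dxa, rel=1e-3)

    def test_deterministic_given_seed(self, mof_bundle):
        assert (draw_psa_bundle(mof_bundle, 9).to_dict()
                == draw_psa_bundle(mof_bundle, 9).to_dict())

    def test_empirical_mean_matches_base(self, mof_bundle):
        rng = np.random.default_rng(17)
        draws = [draw_psa_bundle(mof_bundle, rng).epidemiology.adherence_annual
                 for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(
            mof_bundle.epidemiology.adherence_annual, rel=0.01)

    def test_prevalences_still_sum_to_one(self, mof_bundle):
        for seed in range(5):
            epi = draw_psa_bundle(mof_bundle, seed).epidemiology
            assert epi.prev_osteoporosis + epi.prev_osteopenia + epi.prev_normal \
                == pytest.approx(1.0, abs=1e-9)


class TestRunPsa:
    def test_point_counts_and_reproducibility(self, mof_bundle):
        r1 = run_psa(mof_bundle, n_draws=5, seed=21)
        r2 = run_psa(mof_bundle, n_draws=5, seed=21)
        assert set(r1.points) == {"S2_vs_S1", "S3_vs_S1", "S3_vs_S2"}
        for key in r1.points:
            assert r1.points[key].shape == (5, 2)
            np.testing.assert_array_equal(r1.points[key], r2.points[key])

    def test_default_draw_count_is_one_thousand(self):
        import inspect
        assert inspect.signature(run_psa).parameters["n_draws"].default == 1000

    def test_degenerate_single_draw_near_base(self, mof_bundle):
        from conftest import edit_bundle
        tight = edit_bundle(mof_bundle, **{
            "uncertainty": {"probabilities": 1e-4, "utilities": 1e-4, "costs": 1e-4}})
        _, base = evaluate_bundle(mof_bundle)
        result = run_psa(tight, n_draws=1, seed=0)
        for comp in base:
            dc, de = result.points[f"{comp.intervention}_vs_{comp.comparator}"][0]
            assert dc == pytest.approx(comp.delta_cost, abs=0.3)
            assert de == pytest.approx(comp.delta_qaly, abs=1e-3)

    def test_invalid_draw_count_rejected(self, mof_bundle):
        with pytest.raises(ParameterError):
            run_psa(mof_bundle, n_draws=0, seed=1)


class TestCeac:
    def test_uniformly_dominant_cloud(self):
        pts = {"x": np.array([[-1.0, 0.01]] * 10)}
        assert np.all(compute_ceac(pts, [0.0, 1000.0, 1e5])["x"] == 1.0)

    def test_uniformly_dominated_cloud(self):
        pts = {"x": np.array([[1.0, -0.01]] * 10)}
        assert np.all(compute_ceac(pts, [0.0, 1000.0, 1e5])["x"] == 0.0)

    def test_four_point_enumeration_with_strict_tie_rule(self):
        pts = {"x": np.array([[-1, 0.001], [1, 0.001], [1, -0.001], [3, 0.0001]])}
        # NMBs at 1000: {2, 0, -2, -2.9}; the exact zero is NOT cost-effective
        assert compute_ceac(pts, [1000.0])["x"][0] == 0.25

    def test_complement_sums_to_one_up_to_ties(self, mof_bundle):
        result = run_psa(mof_bundle, n_draws=20, seed=5)
        for key, pts in result.points.items():
            dc, de = pts[:, 0], pts[:, 1]
            for lam, p in zip(result.lambdas, result.ceac[key]):
                p_comp = np.mean(lam * de - dc < 0)
                ties = np.mean(lam * de - dc == 0)
                assert p + p_comp + ties == pytest.approx(1.0)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ParameterError):
            compute_ceac({}, [1000.0])
        with pytest.raises(ParameterError):
            compute_ceac({"x": np.ones((3, 2))}, [])
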