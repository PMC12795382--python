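"""MILP construction, solving, objective evaluation and the epsilon sweep."""

import math

import numpy as np
import pytest

from quakerescue import (
    ModelSpec,
    UncertaintySpec,
    build_model,
    evaluate_objectives,
    max_psych_cost,
    pareto_front,
    robust_demand,
    solve_epsilon,
    solve_single,
    with_weights,
)


class TestRobustDemand:
    @pytest.mark.parametrize(
        "gamma, expected",
        [(0.0, 137.0), (1.0, 143.85), (0.4, 139.74)],
    )
    def test_interpolates_the_interval(self, gamma, expected):
        assert robust_demand(137, 6.85, gamma) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            robust_demand(137, 6.85, 1.2)
        with pytest.raises(ValueError):
            robust_demand(-1, 0, 0.5)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            UncertaintySpec(gamma=-0.1)
        with pytest.raises(ValueError):
            ModelSpec(mode="robust")  # uncertainty missing
        with pytest.raises(ValueError):
            ModelSpec(objective="epsilon_constrained")  # epsilon missing

    def test_gamma_broadcast_and_per_class(self, yushu_instance):
        scalar = UncertaintySpec(gamma=0.3, variability=0.05)
        perclass = UncertaintySpec(gamma=[0.3, 0.3, 0.3], variability=0.05)
        np.testing.assert_allclose(
            scalar.robust_rhs(yushu_instance), perclass.robust_rhs(yushu_instance)
        )
        assert scalar.robust_rhs(yushu_instance)[0, 0] == pytest.approx(137 * 1.015)


class TestBuildModel:
    def test_variable_counts_on_fixture(self, yushu_instance):
        model = build_model(yushu_instance)
        assert model.nU + model.nV == 10
        assert model.nx + model.ny == (8 * 6 + 6 * 4) * 3 == 216
        assert (model.integrality == 1).all()

    def test_gamma_zero_robust_matches_deterministic_rows(self, yushu_instance):
        det = build_model(yushu_instance, ModelSpec())
        rob = build_model(
            yushu_instance,
            ModelSpec(mode="robust", uncertainty=UncertaintySpec(gamma=0.0, variability=0.2)),
        )
        np.testing.assert_array_equal(det.A, rob.A)
        np.testing.assert_array_equal(det.c_lb, rob.c_lb)
        # only difference: equality vs ">=" on the demand rows
        demand_rows = [i for i, n in enumerate(det.row_names) if n.startswith("demand")]
        other = [i for i in range(len(det.row_names)) if i not in demand_rows]
        np.testing.assert_array_equal(det.c_ub[other], rob.c_ub[other])
        assert np.isinf(rob.c_ub[demand_rows]).all()

    def test_lp_export(self, tiny_instance, tmp_path):
        model = build_model(tiny_instance)
        model.to_lp(tmp_path / "model.lp")
        text = (tmp_path / "model.lp").read_text()
        for section in ("Minimize", "Subject To", "Binary", "General", "End"):
            assert section in text
        assert "x_I1_J1_serious" in text and "U_J1" in text


class TestSolveSingle:
    def test_tiny_instance_optimum(self, tiny_instance):
        plan = solve_single(tiny_instance)
        assert plan.status == "optimal"
        assert plan.f1 == pytest.approx(4.78125, abs=1e-9)
        assert plan.x[0, 0, 0] == 3 and plan.x[0, 1, 0] == 0

    def test_zero_weights_zero_objective(self, yushu_instance):
        import dataclasses

        zero = yushu_instance.replace(
            classes=[dataclasses.replace(c, weight=0.0) for c in yushu_instance.classes]
        )
        plan = solve_single(zero)
        assert plan.status == "optimal" and plan.f1 == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_instance_flagged(self, tiny_instance):
        cramped = tiny_instance.replace(comp_capacity=2.0)  # 3 casualties, K holds 2
        plan = solve_single(cramped)
        assert plan.status == "infeasible"

    def test_facility_link_correctness(self, yushu_instance):
        plan = solve_single(yushu_instance)
        inflow_temp = plan.x.sum(axis=(0, 2))
        inflow_comp = plan.y.sum(axis=(0, 2))
        np.testing.assert_array_equal(plan.open_temp, (inflow_temp >= 1).astype(int))
        np.testing.assert_array_equal(plan.open_comp, (inflow_comp >= 1).astype(int))

    def test_optimal_plan_residuals_below_tolerance(self, yushu_instance):
        spec = ModelSpec(mode="robust", uncertainty=UncertaintySpec(0.5, 0.1))
        model = build_model(yushu_instance, spec)
        plan = solve_single(yushu_instance, spec)
        z = np.concatenate(
            [plan.open_temp, plan.open_comp, plan.x.ravel(), plan.y.ravel()]
        ).astype(float)
        assert model.residuals(z).max() <= 1e-6

    def test_conservation_and_demand_at_optimum(self, yushu_instance):
        spec = ModelSpec(mode="robust", uncertainty=UncertaintySpec(0.7, 0.2))
        plan = solve_single(yushu_instance, spec)
        np.testing.assert_array_equal(plan.x.sum(axis=0), plan.y.sum(axis=1))
        required = np.ceil(spec.uncertainty.robust_rhs(yushu_instance) - 1e-12)
        assert (plan.x.sum(axis=1) >= required - 1e-9).all()


class TestTieBreak:
    def test_tie_break_preserves_objective_and_never_opens_more(self, yushu_instance):
        base = solve_single(yushu_instance)
        tied = solve_single(yushu_instance, ModelSpec(tie_break_facilities=True))
        assert tied.status == "optimal"
        assert tied.f1 == pytest.approx(base.f1, abs=1e-6)
        n_base = base.open_temp.sum() + base.open_comp.sum()
        n_tied = tied.open_temp.sum() + tied.open_comp.sum()
        assert n_tied <= n_base


class TestMildStayVariant:
    def test_variant_never_worse_and_relaxes_only_mild(self, yushu_instance):
        base = solve_single(yushu_instance)
        variant = solve_single(yushu_instance, ModelSpec(variant_mild_stay=True))
        assert variant.status == "optimal"
        assert variant.f1 <= base.f1 + 1e-9
        # serious and moderate are still fully transferred
        np.testing.assert_array_equal(
            variant.x.sum(axis=0)[:, :2], variant.y.sum(axis=1)[:, :2]
        )
        # mild casualties may stay behind at temporary hospitals
        assert (variant.y.sum(axis=1)[:, 2] <= variant.x.sum(axis=0)[:, 2]).all()
        assert variant.y[:, :, 2].sum() < variant.x[:, :, 2].sum()


class TestEvaluateObjectives:
    def test_zero_flows(self, yushu_instance):
        x = np.zeros((8, 6, 3))
        y = np.zeros((6, 4, 3))
        assert evaluate_objectives(yushu_instance, x, y) == (0.0, 0.0)

    def test_single_arc_contribution(self, yushu_instance):
        """137 serious casualties routed I1 -> J2 (t = 3.17 h): deterioration
        contributes 3 * (1 - 0.5 e^{-4.34}) * 137 to f1 and 6 * 3.17 * 137
        burden-hours to f2."""
        x = np.zeros((8, 6, 3))
        x[0, 1, 0] = 137
        y = np.zeros((6, 4, 3))
        f1, f2 = evaluate_objectives(yushu_instance, x, y)
        assert f1 == pytest.approx(3 * (1 - 0.5 * math.exp(-4.34)) * 137, abs=1e-9)
        assert f2 == pytest.approx(6 * 3.17 * 137, abs=1e-9)

    def test_dimension_mismatch(self, yushu_instance):
        with pytest.raises(ValueError, match="shape"):
            evaluate_objectives(yushu_instance, np.zeros((2, 2, 2)), np.zeros((6, 4, 3)))

    def test_agreement_with_solver_objective(self, yushu_instance):
        plan = solve_single(yushu_instance)
        f1, f2 = evaluate_objectives(yushu_instance, plan.x, plan.y)
        assert f1 == pytest.approx(plan.f1, abs=1e-6)
        assert f2 == pytest.approx(plan.f2, abs=1e-6)


class TestEpsilonConstraint:
    def test_large_epsilon_recovers_f1_optimum(self, yushu_instance):
        unconstrained = solve_single(yushu_instance)
        plan = solve_epsilon(
            yushu_instance,
            ModelSpec(objective="epsilon_constrained", epsilon=1e9),
        )
        assert plan.f1 == pytest.approx(unconstrained.f1, abs=1e-6)

    def test_boundary_and_infeasible_epsilon(self, yushu_instance):
        f2_min = solve_single(yushu_instance, ModelSpec(objective="f2")).f2
        at_min = solve_epsilon(
            yushu_instance,
            ModelSpec(objective="epsilon_constrained", epsilon=f2_min + 1e-6),
        )
        assert at_min.status == "optimal"
        below = solve_epsilon(
            yushu_instance,
            ModelSpec(objective="epsilon_constrained", epsilon=f2_min - 1.0),
        )
        assert below.status == "infeasible"

    def test_pareto_front_structure(self, yushu_instance):
        front = pareto_front(yushu_instance, n_points=6)
        ok = [p for p in front.points if p.status == "optimal"]
        assert len(ok) == 6
        f1s = [p.f1 for p in ok]
        assert all(a >= b - 1e-9 for a, b in zip(f1s, f1s[1:]))  # non-increasing
        assert ok[-1].f1 == pytest.approx(front.f1_star, abs=1e-6)
        # pairwise Pareto consistency: no point dominates another
        for a in ok:
            for b in ok:
                assert not (a.f1 < b.f1 - 1e-9 and a.f2 < b.f2 - 1e-9)
        # every point satisfies its own epsilon budget
        assert all(p.f2 <= p.epsilon + 1e-6 for p in ok)


class TestPsychCostBound:
    def test_bound_dominates_feasible_plans(self, yushu_instance):
        """Worst-arc routing bounds the psychological cost of any feasible
        plan; both objective-anchor plans must respect it."""
        bound = max_psych_cost(yushu_instance)
        for objective in ("f1", "f2"):
            plan = solve_single(yushu_instance, ModelSpec(objective=objective))
            assert plan.f2 <= bound

    def test_bound_value_frozen(self, yushu_instance):
        # independent recomputation: sum over casualties of worst-arc costs
        inst = yushu_instance
        expected = 0.0
        for i in range(inst.n_areas):
            for s, c in enumerate(inst.classes):
                expected += inst.demand[i, s] * c.alpha * inst.stage1_time[i].max()
        for s, c in enumerate(inst.classes):
            expected += inst.demand[:, s].sum() * c.beta * inst.stage2_time.max()
        assert max_psych_cost(inst) == pytest.approx(expected, abs=1e-9)
        assert max_psych_cost(inst) == pytest.approx(51130.93, abs=0.01)
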