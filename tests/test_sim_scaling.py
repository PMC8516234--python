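"""Scaling-invariance test: term decomposition, constraint system, verdicts,
and symmetry-based model reduction."""

import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from identilab import (
    ODEModel,
    ReductionError,
    UnsupportedTermError,
    build_scaling_system,
    decompose_rhs,
    is_func_independent,
    rank_classify,
    scaling_reduce,
    sim_test,
    split_terms,
)
from identilab.registry import random_compartment_model
from identilab.sim import reduction_value_map

x1, x2 = sp.symbols("x1 x2", real=True)
a, b, c, d, k, k1, k2 = sp.symbols("a b c d k k1 k2", real=True)


class TestSplitTerms:
    @pytest.mark.parametrize("expr, expected", [
        (c * (x1 - x1 ** 3 / 3 - x2 + d),
         {c * x1, -c * x1 ** 3 / 3, -c * x2, c * d}),
        (k1 * x1, {k1 * x1}),
        ((x1 + a - b * x2) / c, {x1 / c, a / c, -b * x2 / c}),
    ])
    def test_distributes_products_over_sums(self, expr, expected):
        assert set(split_terms(expr)) == expected

    @given(st.lists(st.sampled_from([x1, x2, a, b, c]), min_size=1,
                    max_size=4),
           st.integers(min_value=-3, max_value=3).filter(lambda n: n != 0),
           st.integers(min_value=0, max_value=2))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_terms_sum_back_to_expression(self, syms, coeff, power):
        expr = coeff * sp.Mul(*syms) * (x1 + b) ** power - sp.Mul(*syms[:2])
        assert sp.simplify(sp.Add(*split_terms(expr)) - expr) == 0


class TestFunctionalIndependence:
    @pytest.mark.parametrize("f, g, expected", [
        (c * x1, -c * x1 ** 3 / 3, True),
        (k * x1, 2 * k * x1, False),
        (a / c, x1 / c, True),
        (a * b, 3 * a * b, False),
    ])
    def test_generic_jacobian_rank_criterion(self, f, g, expected):
        assert is_func_independent(f, g, seed=0) is expected

    def test_dependent_terms_merged_before_row_construction(self):
        m = ODEModel(states=[x1], params=[k], inputs=[],
                     rhs=[k * x1 + 2 * k * x1], outputs=[x1])
        decomp = decompose_rhs(m)
        assert decomp.terms[0] == [3 * k * x1]


class TestScalingSystem:
    def test_fhn_produces_seven_constraint_rows(self, fhn):
        sys_ = build_scaling_system(fhn)
        assert sys_.matrix.rows == 7
        assert [s.name for s in sys_.columns] == ["a", "b", "c", "d", "x2"]

    def test_reduced_compartment_produces_ten_rows(self, lc_reduced):
        sys_ = build_scaling_system(lc_reduced)
        assert sys_.matrix.rows == 10
        assert [s.name for s in sys_.columns] == [
            "a11", "a21", "a22", "a33", "a34", "a43", "a44",
            "x2", "x3", "x4"]

    def test_measured_state_single_parameter_row(self):
        m = ODEModel(states=[x1], params=[k], inputs=[], rhs=[k],
                     outputs=[x1])
        sys_ = build_scaling_system(m)
        assert sys_.matrix == sp.Matrix([[1]])  # forces u_k = 1

    def test_invariant_argument_of_univariate_function(self):
        # sin(k*x2) scales only if its argument is invariant
        m = ODEModel(states=[x1, x2], params=[k, k2], inputs=[],
                     rhs=[k2 * sp.sin(k * x2), -k * x2], outputs=[x1])
        sys_ = build_scaling_system(m)
        res = sim_test(m)
        assert res.is_trivial  # u_k2=1, u_k*u_x2=1 and u_k=1 force all
        assert sys_.matrix.rows == 3

    def test_unscalable_term_is_a_hard_error(self):
        m = ODEModel(states=[x1, x2], params=[k], inputs=[],
                     rhs=[sp.sin(k + x2), -x2], outputs=[x1])
        with pytest.raises(UnsupportedTermError, match="sin"):
            build_scaling_system(m)


class TestSIMVerdicts:
    def test_fhn_all_factors_forced_to_one(self, fhn):
        res = sim_test(fhn)
        assert res.is_trivial and res.forced_factor_value() == 1
        assert res.verdicts == {
            "a": "sim_identifiable", "b": "sim_identifiable",
            "c": "sim_identifiable", "d": "sim_identifiable",
            "x1": "sim_observable", "x2": "sim_observable"}

    def test_reduced_compartment_all_factors_forced_to_one(self, lc_reduced):
        res = sim_test(lc_reduced)
        assert res.is_trivial
        assert all(v in ("sim_identifiable", "sim_observable")
                   for v in res.verdicts.values())

    def test_full_compartment_three_free_scaling_directions(self, lc_full):
        res = sim_test(lc_full)
        assert res.nullspace_dim == 3
        bad = {n for n, v in res.verdicts.items() if v.startswith("scaling")}
        assert bad == {"a12", "a21", "a23", "a34", "a42", "a43",
                       "x2", "x3", "x4"}
        group = res.scaling_group
        assert group["a11"] == 1 and group["a22"] == 1 and group["a44"] == 1

    def test_scaling_group_solves_the_constraints(self, lc_full):
        # substituting u = tau**v into every row must give exponent sum 0
        res = sim_test(lc_full)
        logs = {s: sp.Add(*(sp.Symbol(f"t{j}") * vec[i]
                            for j, vec in enumerate(res.nullspace)))
                for i, s in enumerate(res.system.columns)}
        for i in range(res.system.matrix.rows):
            row = res.system.matrix.row(i)
            total = sp.Add(*(row[j] * logs[s]
                             for j, s in enumerate(res.system.columns)))
            assert sp.expand(total) == 0


class TestScalingReduce:
    def test_full_compartment_reduces_to_published_seven_parameter_form(
            self, lc_full, lc_reduced):
        res = sim_test(lc_full)
        red = scaling_reduce(lc_full, res, normalize=["a12", "a23", "a42"])
        assert len(red.params) == 7
        for got, want in zip(red.rhs, lc_reduced.rhs):
            assert sp.simplify(got - want) == 0
        assert sim_test(red).is_trivial

    def test_default_normalization_reduces_and_clears_symmetry(self, lc_full):
        red = scaling_reduce(lc_full)
        assert len(red.params) == 7
        assert sim_test(red).is_trivial

    def test_trivial_nullspace_is_a_precondition_error(self, fhn):
        with pytest.raises(ReductionError, match="no scaling symmetry"):
            scaling_reduce(fhn, sim_test(fhn))

    def test_two_state_cascade_fixes_one_rate(self):
        m = ODEModel(states=[x1, x2], params=[k1, k2], inputs=[],
                     rhs=[k1 * x2, k2 * x2], outputs=[x1],
                     name="cascade")
        res = sim_test(m)
        assert res.nullspace_dim == 1
        red = scaling_reduce(m, res)
        assert [p.name for p in red.params] == ["k2"]
        assert sp.simplify(red.rhs[0] - x2) == 0
        assert sim_test(red).is_trivial

    def test_reduction_preserves_output_trajectories(self, lc_full):
        import numpy as np
        from scipy.integrate import solve_ivp

        res = sim_test(lc_full)
        norm = ["a12", "a23", "a42"]
        red = scaling_reduce(lc_full, res, normalize=norm)
        vals = {"a11": -0.5, "a12": 0.8, "a21": 0.3, "a22": -0.6,
                "a23": 0.4, "a33": -0.7, "a34": 0.2, "a42": 0.5,
                "a43": 0.3, "a44": -0.9, "x2": 0.8, "x3": 0.5, "x4": 0.7}
        moved = reduction_value_map(res, norm, vals)
        for p in norm:
            assert moved[p] == pytest.approx(1.0)

        def simulate(model, ic, pvals):
            f = sp.lambdify(
                list(model.states) + list(model.params) + list(model.inputs),
                model.rhs)
            sol = solve_ivp(
                lambda t, x: f(*x, *pvals, np.sin(t) + 2.0), (0, 5), ic,
                t_eval=np.linspace(0, 5, 100), rtol=1e-10, atol=1e-10)
            assert sol.success
            return sol.y[0]

        y1 = simulate(lc_full, [1.0, vals["x2"], vals["x3"], vals["x4"]],
                      [vals[p.name] for p in lc_full.params])
        y2 = simulate(red, [1.0, moved["x2"], moved["x3"], moved["x4"]],
                      [moved[p.name] for p in red.params])
        assert float(np.max(np.abs(y1 - y2))) < 1e-8


class TestSoundness:
    """A scaling symmetry implies rank deficiency — the converse fails."""

    @pytest.mark.parametrize("seed", range(10))
    def test_scaling_symmetry_implies_rank_deficiency(self, seed):
        m = random_compartment_model(seed)
        res = sim_test(m, seed=seed)
        if not res.is_trivial:
            assert not rank_classify(m, seed=seed).is_full_rank

    def test_converse_fails_on_the_counter_examples(
            self, fhn, lc_reduced, fhn_rank, lc_reduced_rank):
        assert sim_test(fhn).is_trivial
        assert not fhn_rank.is_full_rank
        assert sim_test(lc_reduced).is_trivial
        assert not lc_reduced_rank.is_full_rank
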