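"""Lie symmetry discovery, exponentiation, and invariance verification."""

import pytest
import sympy as sp

from identilab import (
    EPS,
    ODEModel,
    check_transform,
    determining_system,
    exponentiate,
    find_generators,
    numeric_validate,
    parse_transform,
)
from identilab.symmetry import LieGenerator, OneParameterTransform

x, x1, x2, x3, x4 = sp.symbols("x x1 x2 x3 x4", real=True)
a, b, c, d, k = sp.symbols("a b c d k", real=True)
a33, a34, a43, a44 = sp.symbols("a33 a34 a43 a44", real=True)

FHN_PARAMS = [0.2, 0.5, 3.0, 0.7]
FHN_IC = [0.5, 0.3]


@pytest.fixture(scope="module")
def fhn_generator(fhn):
    gens = find_generators(fhn, degree=1)
    assert len(gens) == 1
    return gens[0]


@pytest.fixture(scope="module")
def lc_generator(lc_reduced):
    gens = find_generators(lc_reduced, degree=1)
    assert len(gens) == 1
    return gens[0]


class TestDeterminingSystem:
    def test_fhn_solution_space_is_one_dimensional(self, fhn):
        assert determining_system(fhn, degree=1).solution_dim == 1

    def test_identifiable_decay_admits_only_zero(self):
        m = ODEModel(states=[x], params=[k], inputs=[], rhs=[-k * x],
                     outputs=[x])
        assert determining_system(m, degree=1).solution_dim == 0
        assert find_generators(m, degree=2) == []

    def test_measured_states_are_pinned(self, fhn_generator):
        assert fhn_generator.eta[x1] == 0


class TestGenerators:
    def test_fhn_generator_is_the_affine_symmetry(self, fhn_generator):
        eta = fhn_generator.eta
        assert (eta[x2], eta[a], eta[d]) == (1, b, 1)
        assert eta[b] == eta[c] == 0

    def test_reduced_compartment_generator(self, lc_generator):
        eta = lc_generator.eta
        assert eta[x4] == x3
        assert eta[a33] == -a34
        assert eta[a43] == a33 - a44
        assert eta[a44] == a34
        assert eta[x2] == eta[x3] == 0

    def test_full_compartment_has_three_scaling_plus_one_higher(
            self, lc_full):
        gens = find_generators(lc_full, degree=1)
        assert len(gens) == 4
        # scaling generators: every infinitesimal is a multiple of its own
        # variable (flow z -> z * exp(c * eps))
        scaling = [
            g for g in gens
            if all(sp.expand(g.eta[v] - sp.diff(g.eta[v], v) * v) == 0
                   for v in lc_full.states + lc_full.params)]
        assert len(scaling) == 3
        higher = [g for g in gens if g not in scaling]
        assert len(higher) == 1 and higher[0].eta[x4] == x3


class TestExponentiation:
    def test_fhn_flow_is_the_affine_transform(self, fhn_generator):
        tr = exponentiate(fhn_generator)
        assert tr.series_order is None
        assert tr.mapping[x2] == x2 + EPS
        assert sp.expand(tr.mapping[a] - (a + b * EPS)) == 0
        assert tr.mapping[d] == d + EPS

    def test_compartment_flow_has_exact_quadratic_term(self, lc_generator):
        tr = exponentiate(lc_generator)
        assert tr.series_order is None
        assert sp.expand(tr.mapping[x4] - (x4 + x3 * EPS)) == 0
        assert sp.expand(tr.mapping[a33] - (a33 - a34 * EPS)) == 0
        assert sp.expand(tr.mapping[a44] - (a44 + a34 * EPS)) == 0
        assert sp.expand(
            tr.mapping[a43]
            - (a43 + (a33 - a44) * EPS - a34 * EPS ** 2)) == 0

    def test_zero_generator_gives_identity(self, fhn):
        zero = LieGenerator(
            model=fhn, degree=1,
            eta={v: sp.Integer(0) for v in fhn.states + fhn.params})
        assert exponentiate(zero).is_identity()

    def test_flow_derivative_at_zero_recovers_generator(
            self, fhn_generator, lc_generator):
        for gen in (fhn_generator, lc_generator):
            tr = exponentiate(gen)
            for v, img in tr.mapping.items():
                assert sp.expand(
                    sp.diff(img, EPS).subs(EPS, 0) - gen.eta[v]) == 0
                assert img.subs(EPS, 0) == v  # identity at eps = 0

    def test_group_property_of_closed_form_flows(
            self, fhn_generator, lc_generator):
        e1, e2 = sp.symbols("e1 e2", real=True)
        for gen in (fhn_generator, lc_generator):
            tr = exponentiate(gen)
            first = {z: e.subs(EPS, e1) for z, e in tr.mapping.items()}
            composed = {z: e.subs(EPS, e2).subs(first, simultaneous=True)
                        for z, e in tr.mapping.items()}
            direct = {z: e.subs(EPS, e1 + e2)
                      for z, e in tr.mapping.items()}
            for z in composed:
                assert sp.simplify(composed[z] - direct[z]) == 0

    def test_scaling_generator_exponentiates_to_exp_factor(self):
        from identilab import registry_get
        m = registry_get("scaling_pair")
        gen = find_generators(m, degree=1)[0]
        tr = exponentiate(gen)
        moved = {v.name: e for v, e in tr.mapping.items() if e != v}
        assert set(moved) == {"x2", "k1"}
        ratio = sp.simplify(moved["x2"] / x2 * moved["k1"] / sp.Symbol(
            "k1", real=True))
        assert ratio == 1  # u_k1 * u_x2 = 1 along the flow


class TestInvariance:
    def test_published_transforms_leave_equations_invariant(
            self, fhn, lc_reduced, fhn_generator, lc_generator):
        for model, gen in [(fhn, fhn_generator), (lc_reduced, lc_generator)]:
            res = check_transform(model, exponentiate(gen))
            assert res.invariant
            assert all(r == 0 for r in res.state_residuals)
            assert all(r == 0 for r in res.output_residuals)

    def test_corrupted_transform_leaves_a_residual(self, fhn):
        bad = parse_transform(
            "{x2: x2 + eps, a: a + 2*b*eps, d: d + eps}", fhn)
        res = check_transform(fhn, bad)
        assert not res.invariant
        assert sp.simplify(res.state_residuals[1] * c + b * EPS) == 0

    def test_identity_transform_is_invariant(self, lc_reduced):
        identity = OneParameterTransform(
            model=lc_reduced,
            mapping={v: v
                     for v in lc_reduced.states + lc_reduced.params})
        assert check_transform(lc_reduced, identity).invariant

    def test_unknown_symbols_rejected(self, fhn):
        bad = OneParameterTransform(
            model=fhn, mapping={x2: x2 + sp.Symbol("zeta")})
        with pytest.raises(Exception, match="zeta"):
            check_transform(fhn, bad)

    def test_every_found_generator_is_verified(self, lc_full):
        for gen in find_generators(lc_full, degree=1):
            assert check_transform(lc_full, exponentiate(gen)).invariant


class TestNumericValidation:
    @pytest.mark.parametrize("eps_value", [-1, 0.5, 2])
    def test_output_invariant_along_the_flow(self, fhn, fhn_generator,
                                             eps_value):
        nv = numeric_validate(fhn, exponentiate(fhn_generator), eps_value,
                              ic=FHN_IC, params=FHN_PARAMS)
        assert nv.passed
        assert nv.deviation <= nv.threshold

    def test_compartment_flow_with_generic_input(self, lc_reduced,
                                                 lc_generator):
        nv = numeric_validate(
            lc_reduced, exponentiate(lc_generator), 0.5,
            ic=[1.0, 0.8, 0.5, 0.7],
            params=[-0.5, 0.3, -0.6, -0.7, 0.2, 0.4, -0.9])
        assert nv.passed

    def test_corrupted_transform_breaks_output(self, fhn):
        bad = parse_transform(
            "{x2: x2 + eps, a: a + 2*b*eps, d: d + eps}", fhn)
        nv = numeric_validate(fhn, bad, 0.5, ic=FHN_IC, params=FHN_PARAMS)
        assert not nv.passed
        assert nv.deviation > 1e3 * nv.threshold

    def test_zero_eps_gives_solver_noise_only(self, fhn, fhn_generator):
        nv = numeric_validate(fhn, exponentiate(fhn_generator), 0,
                              ic=FHN_IC, params=FHN_PARAMS)
        assert nv.deviation == 0.0
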