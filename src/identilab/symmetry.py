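"""Lie symmetry discovery, exponentiation and verification for ODE models.

A one-parameter Lie symmetry is a transformation group

    x* = X(x, lam; eps),   lam* = L(lam; eps),   X(.; 0) = id,

that maps solutions to solutions while fixing the measured outputs.  Its
infinitesimal generator is the eps-derivative at eps = 0: ``eta_x`` per
state (polynomial ansatz in states and parameters) and ``eta_lam`` per
parameter (polynomial in parameters only, so constancy of the parameters
is preserved).  Measured states must have identically zero infinitesimals,
which makes the model output invariant along the flow.

The generators are found by solving the linear determining system obtained
from the symmetry condition

    sum_j (d eta_xi / d x_j) f_j
        = sum_j (d f_i / d x_j) eta_xj + sum_k (d f_i / d lam_k) eta_lamk

identically in all states, parameters and input symbols.  Each generator is
exponentiated into its finite one-parameter transformation by solving
``dz*/d eps = eta(z*)``: exactly for affine generators (augmented matrix
exponential) and terminating Lie series, or as a truncated eps-series
otherwise.  Invariance of the model equations under the finite transform is
verified symbolically, and can additionally be validated numerically by
simulating the original and transformed systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import sympy as sp
import yaml

from .errors import IdentilabError, ModelError
from .model import ODEModel, parse_expression

__all__ = [
    "EPS", "LieGenerator", "OneParameterTransform", "determining_system",
    "DeterminingSystem", "find_generators", "exponentiate",
    "check_transform", "TransformCheck", "numeric_validate",
    "NumericValidation", "parse_transform",
]

EPS = sp.Symbol("eps", real=True)

SERIES_FALLBACK_ORDER = 6


def _monomials(symbols, degree: int):
    """All monomials in ``symbols`` of total degree 0..degree."""
    monos = [sp.Integer(1)]
    for d in range(1, degree + 1):
        for combo in combinations_with_replacement(symbols, d):
            monos.append(sp.Mul(*combo))
    return monos


@dataclass
class LieGenerator:
    """Infinitesimal generator of a candidate one-parameter symmetry.

    ``eta`` maps every state and parameter symbol to its infinitesimal;
    measured states map to zero.  Coefficients are integer-normalized
    (denominators cleared, gcd one, leading coefficient positive).
    """

    model: ODEModel
    eta: dict[sp.Symbol, sp.Expr]
    degree: int

    def support(self) -> set[str]:
        """Names of variables moved by the generator."""
        return {v.name for v, e in self.eta.items() if e != 0}

    def is_zero(self) -> bool:
        return all(e == 0 for e in self.eta.values())


@dataclass
class OneParameterTransform:
    """Finite one-parameter transformation ``z -> z*(z; eps)``.

    ``series_order`` is ``None`` for exact closed-form flows; a truncated
    Lie series records the order through which it is valid.
    """

    model: ODEModel
    mapping: dict[sp.Symbol, sp.Expr]
    eps: sp.Symbol = EPS
    provenance: str = "user"
    series_order: int | None = None

    def at(self, eps_value) -> dict[sp.Symbol, sp.Expr]:
        """The mapping with a concrete value substituted for eps."""
        v = sp.sympify(eps_value)
        return {z: e.subs(self.eps, v) for z, e in self.mapping.items()}

    def is_identity(self) -> bool:
        return all(z == e for z, e in self.mapping.items())


@dataclass
class DeterminingSystem:
    """Homogeneous linear system ``A c = 0`` over the ansatz coefficients."""

    model: ODEModel
    degree: int
    matrix: sp.Matrix
    coeffs: list[sp.Symbol]
    # coefficient -> (transformed variable, monomial) bookkeeping
    coeff_meta: dict[sp.Symbol, tuple[sp.Symbol, sp.Expr]] = field(
        default_factory=dict)

    @property
    def solution_dim(self) -> int:
        return len(self.matrix.nullspace())


def _ansatz(model: ODEModel, degree: int):
    """Polynomial infinitesimal ansatz with undetermined coefficients."""
    measured = model.measured_states()
    state_monos = _monomials(list(model.states) + list(model.params), degree)
    param_monos = _monomials(list(model.params), degree)
    coeffs: list[sp.Symbol] = []
    meta: dict[sp.Symbol, tuple[sp.Symbol, sp.Expr]] = {}
    eta: dict[sp.Symbol, sp.Expr] = {}

    def make(var: sp.Symbol, monos) -> sp.Expr:
        terms = []
        for m in monos:
            c = sp.Symbol(f"c_{var.name}_{len(coeffs)}")
            coeffs.append(c)
            meta[c] = (var, m)
            terms.append(c * m)
        return sp.Add(*terms)

    for s in model.states:
        eta[s] = sp.Integer(0) if s in measured else make(s, state_monos)
    for p in model.params:
        eta[p] = make(p, param_monos)
    return eta, coeffs, meta


def determining_system(model: ODEModel, degree: int = 1) -> DeterminingSystem:
    """Linear determining equations for polynomial infinitesimals.

    Requires polynomial dynamics; the symmetry condition is expanded and
    the coefficient of every monomial in states, parameters and inputs is
    equated to zero.
    """
    if degree < 1:
        raise ValueError("ansatz degree must be >= 1")
    eta, coeffs, meta = _ansatz(model, degree)
    poly_vars = list(model.states) + list(model.params) + list(model.inputs)
    equations: list[sp.Expr] = []
    for i, (xi, fi) in enumerate(zip(model.states, model.rhs)):
        lhs = sp.Add(*(sp.diff(eta[xi], xj) * fj
                       for xj, fj in zip(model.states, model.rhs)))
        rhs = sp.Add(*(sp.diff(fi, xj) * eta[xj] for xj in model.states))
        rhs += sp.Add(*(sp.diff(fi, pk) * eta[pk] for pk in model.params))
        residual = sp.together(sp.expand(lhs - rhs))
        # rational dynamics: clearing the (generically nonzero) denominator
        # preserves the zero set of the identity
        numer, _ = sp.fraction(residual)
        try:
            poly = sp.Poly(sp.expand(numer), *poly_vars)
        except sp.PolynomialError as exc:
            raise IdentilabError(
                f"symmetry search requires polynomial (or rational) "
                f"dynamics; equation for {xi} is not: {exc}") from exc
        equations.extend(poly.coeffs())
    if equations:
        A, _ = sp.linear_eq_to_matrix(equations, coeffs)
    else:
        A = sp.zeros(0, len(coeffs))
    return DeterminingSystem(model=model, degree=degree, matrix=A,
                             coeffs=coeffs, coeff_meta=meta)


def _normalize_vector(vec: sp.Matrix) -> sp.Matrix:
    """Clear denominators, divide by gcd, make first nonzero entry positive."""
    denoms = [sp.Rational(v).q for v in vec if v != 0]
    if not denoms:
        return vec
    vec = vec * sp.ilcm(*denoms) if len(denoms) > 1 else vec * denoms[0]
    nums = [abs(sp.Integer(v)) for v in vec if v != 0]
    g = sp.igcd(*nums) if len(nums) > 1 else nums[0]
    vec = vec / g
    first = next(v for v in vec if v != 0)
    return -vec if first < 0 else vec


def find_generators(model: ODEModel, degree: int = 1) -> list[LieGenerator]:
    """All polynomial symmetry generators up to the given ansatz degree.

    Returns an integer-normalized rational nullspace basis of the
    determining system in a deterministic (lexicographic) order; an empty
    list means the model admits no polynomial symmetry at this degree.
    """
    system = determining_system(model, degree)
    basis = system.matrix.nullspace()
    gens = []
    for vec in basis:
        vec = _normalize_vector(vec)
        eta = {v: sp.Integer(0) for v in
               list(model.states) + list(model.params)}
        for c, value in zip(system.coeffs, vec):
            if value != 0:
                var, mono = system.coeff_meta[c]
                eta[var] = eta[var] + value * mono
        gens.append(LieGenerator(model=model, eta=eta, degree=degree))
    gens.sort(key=lambda g: [sp.default_sort_key(g.eta[v])
                             for v in list(model.states) + list(model.params)])
    return gens


# ---------------------------------------------------------------------------
# exponentiation


def _lie_series(gen: LieGenerator, cap: int):
    """Lie series of the flow; returns (mapping, terminated, order)."""
    variables = list(gen.model.states) + list(gen.model.params)
    mapping = {}
    terminated = True
    max_used = 0
    for z in variables:
        term: sp.Expr = z
        total: sp.Expr = z
        k = 0
        while True:
            term = sp.expand(sp.Add(*(sp.diff(term, v) * gen.eta[v]
                                      for v in variables)))
            if term == 0:
                break
            k += 1
            if k > cap:
                terminated = False
                break
            total = total + term * EPS ** k / sp.factorial(k)
        max_used = max(max_used, k)
        mapping[z] = sp.expand(total)
    return mapping, terminated, max_used


def _affine_flow(gen: LieGenerator) -> dict[sp.Symbol, sp.Expr] | None:
    """Closed-form flow via augmented matrix exponential, if eta is affine."""
    moved = [v for v in list(gen.model.states) + list(gen.model.params)
             if gen.eta[v] != 0]
    if not moved:
        return {v: v for v in list(gen.model.states) + list(gen.model.params)}
    for z in moved:
        e = gen.eta[z]
        if not e.has(*moved):
            continue
        try:
            if sp.Poly(e, *moved).total_degree() > 1:
                return None
        except sp.PolynomialError:
            return None
    n = len(moved)
    W = sp.zeros(n + 1, n + 1)
    for i, z in enumerate(moved):
        e = sp.expand(gen.eta[z])
        const = e.subs({v: 0 for v in moved})
        W[i, n] = const
        for j, v in enumerate(moved):
            W[i, j] = sp.diff(e, v)
    try:
        flow = sp.simplify((W * EPS).exp())
    except (NotImplementedError, ValueError):
        return None
    zvec = sp.Matrix(moved + [sp.Integer(1)])
    img = flow * zvec
    mapping = {v: v for v in list(gen.model.states) + list(gen.model.params)}
    for i, z in enumerate(moved):
        mapping[z] = sp.expand(sp.simplify(img[i]))
    return mapping


def exponentiate(gen: LieGenerator, cap: int = 8) -> OneParameterTransform:
    """Finite transformation of a generator: solve dz*/deps = eta(z*).

    The Lie series is computed first and kept when it terminates (exact
    polynomial flow, e.g. nilpotent generators).  Otherwise an affine
    generator gets the exact augmented-matrix-exponential flow (covers
    scaling groups, ``x* = exp(eps) x``).  Anything else falls back to a
    truncated Lie series of order ``SERIES_FALLBACK_ORDER`` with the
    truncation recorded on the transform.
    """
    mapping, terminated, _ = _lie_series(gen, cap)
    if terminated:
        return OneParameterTransform(model=gen.model, mapping=mapping,
                                     provenance="lie_series")
    affine = _affine_flow(gen)
    if affine is not None:
        return OneParameterTransform(model=gen.model, mapping=affine,
                                     provenance="matrix_exponential")
    mapping, _, _ = _lie_series(gen, SERIES_FALLBACK_ORDER)
    truncated = {z: e + sp.O(EPS ** (SERIES_FALLBACK_ORDER + 1))
                 for z, e in mapping.items()}
    truncated = {z: e.removeO() for z, e in truncated.items()}
    return OneParameterTransform(model=gen.model, mapping=truncated,
                                 provenance="truncated_series",
                                 series_order=SERIES_FALLBACK_ORDER)


# ---------------------------------------------------------------------------
# verification


@dataclass
class TransformCheck:
    """Symbolic invariance residuals of a finite transformation."""

    state_residuals: list[sp.Expr]
    output_residuals: list[sp.Expr]
    invariant: bool


def check_transform(model: ODEModel,
                    transform: OneParameterTransform) -> TransformCheck:
    """Verify that a transformation leaves the model equations invariant.

    For each state the chain-rule time derivative of the starred state
    (along the original dynamics) is compared with the original RHS
    evaluated at the starred variables; outputs are compared directly.
    All residuals must be identically zero (as polynomials in eps; for a
    truncated-series transform, zero through its stated order).
    """
    declared = set(model.states) | set(model.params) | set(model.inputs)
    for z, e in transform.mapping.items():
        extra = e.free_symbols - declared - {transform.eps}
        if extra:
            raise ModelError(
                f"transform for {z} references unknown symbols "
                f"{sorted(s.name for s in extra)}")
    sub = dict(transform.mapping)

    def _trim(expr: sp.Expr) -> sp.Expr:
        expr = sp.expand(expr)
        if transform.series_order is not None:
            expr = expr + sp.O(transform.eps ** (transform.series_order + 1))
            expr = expr.removeO()
        return sp.simplify(expr)

    state_res = []
    for xi, fi in zip(model.states, model.rhs):
        starred = transform.mapping.get(xi, xi)
        dstar_dt = sp.Add(*(sp.diff(starred, xj) * fj
                            for xj, fj in zip(model.states, model.rhs)))
        state_res.append(_trim(dstar_dt - fi.subs(sub, simultaneous=True)))
    out_res = [_trim(h.subs(sub, simultaneous=True) - h)
               for h in model.outputs]
    invariant = all(r == 0 for r in state_res + out_res)
    return TransformCheck(state_residuals=state_res,
                          output_residuals=out_res, invariant=invariant)


@dataclass
class NumericValidation:
    """Output deviation between original and transformed trajectories."""

    deviation: float
    threshold: float
    passed: bool
    atol: float
    rtol: float


def numeric_validate(model: ODEModel, transform: OneParameterTransform,
                     eps_value, ic, params, tspan=(0.0, 5.0),
                     input_funcs=None, atol: float = 1e-11,
                     rtol: float = 1e-11, n_grid: int = 200
                     ) -> NumericValidation:
    """Simulate original and transformed systems and compare the outputs.

    ``ic`` and ``params`` are numeric vectors aligned with the model's
    state and parameter order.  The transformed run starts from the starred
    initial conditions and parameters (measured-state ICs are unchanged by
    construction).  Known inputs default to the generic test signal
    ``sin(t) + 2``.  The pass threshold is ``10 * (atol + rtol * scale)``
    with ``scale`` the largest output magnitude seen.
    """
    import numpy as np
    from scipy.integrate import solve_ivp

    input_funcs = dict(input_funcs or {})
    for u in model.inputs:
        input_funcs.setdefault(u.name, lambda t: np.sin(t) + 2.0)

    args = list(model.states) + list(model.params) + list(model.inputs)
    f_num = sp.lambdify(args, model.rhs, modules="numpy")
    h_num = sp.lambdify(args, model.outputs, modules="numpy")

    def simulate(x0, pvals):
        def rhs(t, x):
            uvals = [input_funcs[u.name](t) for u in model.inputs]
            return np.asarray(f_num(*x, *pvals, *uvals), dtype=float)

        t_eval = np.linspace(tspan[0], tspan[1], n_grid)
        sol = solve_ivp(rhs, tspan, np.asarray(x0, dtype=float),
                        t_eval=t_eval, rtol=rtol, atol=atol, method="LSODA")
        if not sol.success:
            raise IdentilabError(f"integration failed: {sol.message}")
        uvals = [np.array([input_funcs[u.name](t) for t in sol.t])
                 for u in model.inputs]
        y = np.array(h_num(*sol.y, *[np.full(sol.t.shape, p) for p in pvals],
                           *uvals), dtype=float)
        return y

    ic = list(map(float, ic))
    params = list(map(float, params))
    point = {s: v for s, v in zip(model.states, ic)}
    point.update({p: v for p, v in zip(model.params, params)})
    at_eps = transform.at(eps_value)
    ic2 = [float(at_eps.get(s, s).subs(point)) for s in model.states]
    par2 = [float(at_eps.get(p, p).subs(point)) for p in model.params]

    y1 = simulate(ic, params)
    y2 = simulate(ic2, par2)
    deviation = float(np.max(np.abs(y1 - y2)))
    scale = max(1.0, float(np.max(np.abs(y1))), float(np.max(np.abs(y2))))
    threshold = 10.0 * (atol + rtol * scale)
    return NumericValidation(deviation=deviation, threshold=threshold,
                             passed=deviation <= threshold, atol=atol,
                             rtol=rtol)


def parse_transform(text: str, model: ODEModel) -> OneParameterTransform:
    """Parse a user-supplied transform file (YAML map variable -> expression).

    Unlisted states and parameters map to themselves; expressions may use
    the declared symbols and the group parameter ``eps``.
    """
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ModelError("transform file must be a YAML mapping")
    symbols = {s.name: s for s in
               list(model.states) + list(model.params) + list(model.inputs)}
    symbols[EPS.name] = EPS
    declared = {v.name: v for v in list(model.states) + list(model.params)}
    mapping = {v: v for v in declared.values()}
    for key, value in doc.items():
        if str(key) not in declared:
            raise ModelError(
                f"transform maps unknown variable {key!r}; transformable "
                f"variables: {', '.join(sorted(declared))}")
        mapping[declared[str(key)]] = parse_expression(str(value), symbols)
    return OneParameterTransform(model=model, mapping=mapping,
                                 provenance="user")
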