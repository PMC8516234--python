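"""Scaling-invariance test for structural identifiability and observability.

The test multiplies every unknown parameter and every unmeasured state by an
unknown positive scaling factor ``u`` and demands that each functionally
independent additive term of the dynamics is invariant:

    f_ik(x, lam) = (1/u_xi) * f_ik(u_x * x, u_lam * lam)

Measured states and known inputs carry no factor.  Taking logarithms,
``w = log u``, each term contributes one linear equation in the exponents,
and the set of admissible factor combinations is the rational nullspace of
the resulting exponent matrix.  A variable whose factor is forced to one in
every solution is declared identifiable (parameters) or observable (states)
by the test; variables participating in a nontrivial scaling symmetry are
unidentifiable / unobservable.

The test is one-sided: a nontrivial scaling symmetry proves
unidentifiability, but a trivial solution does **not** prove
identifiability — non-scaling Lie symmetries are invisible here (see the
``rank`` and ``symmetry`` modules for the complete analysis).

All linear algebra is exact over the rationals; verdicts never touch
floating point.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import sympy as sp

from .errors import (
    DegenerateSampleError,
    ReductionError,
    UnsupportedTermError,
)
from .model import ODEModel

__all__ = [
    "split_terms", "is_func_independent", "TermDecomposition",
    "decompose_rhs", "ScalingSystem", "build_scaling_system",
    "SIMResult", "sim_test", "scaling_reduce", "choose_normalization",
    "reduction_value_map",
]

VERDICT_IDENTIFIABLE = "sim_identifiable"
VERDICT_OBSERVABLE = "sim_observable"
VERDICT_UNIDENTIFIABLE = "scaling_unidentifiable"
VERDICT_UNOBSERVABLE = "scaling_unobservable"


def split_terms(expr: sp.Expr) -> list[sp.Expr]:
    """Top-level additive terms of ``expr`` after full distribution.

    Products are distributed over sums first, so ``c*(x1 - x2)`` yields
    ``[c*x1, -c*x2]``.  The terms always sum back to ``expr``.
    """
    expanded = sp.expand(sp.sympify(expr))
    return list(sp.Add.make_args(expanded))


def _sample_point(symbols, rng: random.Random) -> dict:
    """Random rational point with every coordinate in [1, 101)."""
    return {s: sp.Rational(rng.randint(100, 10099), 100) for s in symbols}


def is_func_independent(f: sp.Expr, g: sp.Expr, seed: int = 0,
                        trials: int = 5) -> bool:
    """Generic functional independence of two expressions.

    ``f`` and ``g`` are functionally dependent iff the Jacobian of
    ``(f, g)`` with respect to all involved symbols has generic rank < 2
    (the generalized-Wronskian criterion).  Genericity is decided by exact
    rational evaluation at ``trials`` seeded random points.
    """
    f, g = sp.sympify(f), sp.sympify(g)
    syms = sorted(f.free_symbols | g.free_symbols, key=lambda s: s.name)
    if not syms:
        return False
    jac = sp.Matrix([[sp.diff(f, s) for s in syms],
                     [sp.diff(g, s) for s in syms]])
    rng = random.Random(seed)
    evaluated_any = False
    for _ in range(trials):
        point = _sample_point(syms, rng)
        num = jac.subs(point)
        if any(not e.is_finite for e in num):
            continue
        evaluated_any = True
        if num.rank() == 2:
            return True
    if not evaluated_any:
        raise DegenerateSampleError(
            "all sampled points were degenerate; try a different seed")
    return False


@dataclass
class TermDecomposition:
    """Per-state additive decomposition into functionally independent terms.

    Functionally dependent term pairs are merged by summation, so no two
    terms in one state's list share a rank-deficient joint Jacobian.
    The terms of each state sum symbolically to that state's RHS.
    """

    model: ODEModel
    terms: list[list[sp.Expr]]

    def term_symbols(self, i: int, k: int) -> tuple[set, set]:
        """States and parameters appearing in term ``k`` of state ``i``."""
        free = self.terms[i][k].free_symbols
        return free & set(self.model.states), free & set(self.model.params)


def _merge_dependent(terms: list[sp.Expr], seed: int) -> list[sp.Expr]:
    groups: list[list[sp.Expr]] = []
    for t in terms:
        for grp in groups:
            if not is_func_independent(grp[0], t, seed=seed):
                grp.append(t)
                break
        else:
            groups.append([t])
    return [sp.Add(*grp) for grp in groups]


def decompose_rhs(model: ODEModel, seed: int = 0) -> TermDecomposition:
    """Split each RHS into functionally independent additive terms."""
    per_state = [_merge_dependent(split_terms(e), seed) for e in model.rhs]
    return TermDecomposition(model=model, terms=per_state)


# ---------------------------------------------------------------------------
# scaling-constraint system


@dataclass
class ScalingSystem:
    """Exact linear system ``A w = 0`` over log scaling factors.

    ``columns`` lists the scaled symbols (unknown parameters, then
    unmeasured states); column ``j`` of ``matrix`` is the log-factor
    ``w_j = log u_j``.  ``row_labels`` records the (state, term) pair each
    row came from.
    """

    columns: list[sp.Symbol]
    matrix: sp.Matrix
    row_labels: list[tuple[str, str]] = field(default_factory=list)

    def factor_symbol(self, var: sp.Symbol) -> sp.Symbol:
        return sp.Symbol(f"u_{var.name}", positive=True)


def _monomial_exponents(expr: sp.Expr, scaled: set) -> dict:
    """Exponent map of ``expr`` over the scaled symbols.

    ``expr`` must be a monomial ``c * prod(s_i**e_i)`` with rational ``e_i``
    in the scaled symbols (``c`` free of them); otherwise raises
    :class:`UnsupportedTermError`.
    """
    exps: dict = {}
    for fac in sp.Mul.make_args(expr):
        if not fac.free_symbols & scaled:
            continue
        base, e = fac.as_base_exp()
        if base in scaled and e.is_Rational:
            exps[base] = exps.get(base, sp.Integer(0)) + e
        else:
            raise UnsupportedTermError(
                f"factor {fac} is not a rational-power monomial in the "
                "scaled variables")
    return exps


def _term_rows(term: sp.Expr, scaled: set):
    """Outer exponent map and inner invariance maps for one additive term.

    Supported term shapes: a monomial in the scaled symbols, possibly
    multiplied by univariate functions ``phi(m)`` whose argument ``m`` is
    itself such a monomial — the argument must then be scaling-invariant,
    contributing an extra exponent row that is forced to zero.
    """
    outer: dict = {}
    inner: list[dict] = []
    for fac in sp.Mul.make_args(term):
        if not fac.free_symbols & scaled:
            continue
        base, e = fac.as_base_exp()
        if base in scaled and e.is_Rational:
            outer[base] = outer.get(base, sp.Integer(0)) + e
        elif isinstance(base, sp.Function) and len(base.args) == 1 \
                and e.is_Rational:
            arg_exps = _monomial_exponents(base.args[0], scaled)
            if arg_exps:
                inner.append(arg_exps)
        else:
            raise UnsupportedTermError(
                f"unsupported factor {fac} (not a monomial or a univariate "
                "function of a monomial in the scaled variables)")
    return outer, inner


def build_scaling_system(model: ODEModel,
                         decomp: TermDecomposition | None = None,
                         seed: int = 0) -> ScalingSystem:
    """Assemble the exponent matrix of the term-wise invariance equations.

    One row per (state, term) pair with nontrivial content: the exponents
    of the scaled symbols appearing in the term, minus one on the scaling
    factor of the term's own state when that state is unmeasured.  Terms
    built only from measured states, known inputs and constants impose no
    constraint and produce no row.
    """
    model.assert_sim_eligible()
    if decomp is None:
        decomp = decompose_rhs(model, seed=seed)
    measured = model.measured_states()
    unmeasured = [s for s in model.states if s not in measured]
    columns = list(model.params) + unmeasured
    col_index = {s: j for j, s in enumerate(columns)}
    scaled = set(columns)

    rows, labels = [], []

    def add_row(exps: dict, state: sp.Symbol | None, term: sp.Expr) -> None:
        row = [sp.Integer(0)] * len(columns)
        for s, e in exps.items():
            row[col_index[s]] += e
        if state is not None and state not in measured:
            row[col_index[state]] -= 1
        if any(v != 0 for v in row):
            rows.append(row)
            labels.append((state.name if state is not None else "",
                           sp.sstr(term)))

    for i, state in enumerate(model.states):
        for term in decomp.terms[i]:
            try:
                outer, inner = _term_rows(term, scaled)
            except UnsupportedTermError as exc:
                raise UnsupportedTermError(
                    f"state {state}: term {term}: {exc}") from None
            add_row(outer, state, term)
            for arg_exps in inner:
                add_row(arg_exps, None, term)

    matrix = sp.Matrix(len(rows), len(columns),
                       [v for row in rows for v in row]) \
        if rows else sp.zeros(0, len(columns))
    return ScalingSystem(columns=columns, matrix=matrix, row_labels=labels)


# ---------------------------------------------------------------------------
# verdicts


@dataclass
class SIMResult:
    """Outcome of the scaling-invariance test.

    ``nullspace`` is the exact rational basis of admissible log-factor
    combinations; an empty basis means every factor is forced to one.
    ``scaling_group`` gives, for a nontrivial nullspace, the factor of each
    scaled symbol as a product of powers of free group parameters ``tau_j``.
    """

    model: ODEModel
    system: ScalingSystem
    nullspace: list[sp.Matrix]
    verdicts: dict[str, str]

    @property
    def nullspace_dim(self) -> int:
        return len(self.nullspace)

    @property
    def is_trivial(self) -> bool:
        """True iff the only invariant scaling is the identity."""
        return not self.nullspace

    @property
    def scaling_group(self) -> dict[str, sp.Expr]:
        taus = [sp.Symbol(f"tau{j + 1}", positive=True)
                for j in range(self.nullspace_dim)]
        group = {}
        for i, s in enumerate(self.system.columns):
            factor = sp.Integer(1)
            for tau, vec in zip(taus, self.nullspace):
                factor *= tau ** vec[i]
            group[s.name] = factor
        return group

    def forced_factor_value(self) -> sp.Integer | None:
        """The common value all factors are forced to, or None if free."""
        return sp.Integer(1) if self.is_trivial else None


def sim_test(model: ODEModel, seed: int = 0) -> SIMResult:
    """Run the scaling-invariance test on a model with state-subset outputs.

    Builds the term decomposition, assembles the exponent system and solves
    it exactly over the rationals.  Parameters and unmeasured states whose
    factor is forced to one are classified identifiable / observable;
    coordinates free in the nullspace are unidentifiable / unobservable.
    """
    system = build_scaling_system(model, seed=seed)
    nullspace = system.matrix.nullspace() if system.matrix.rows else [
        v for v in sp.eye(len(system.columns)).columnspace()]
    measured = model.measured_states()
    free_coords = {i for vec in nullspace for i in range(len(vec))
                   if vec[i] != 0}
    verdicts: dict[str, str] = {}
    for j, s in enumerate(system.columns):
        forced = j not in free_coords
        if s in set(model.params):
            verdicts[s.name] = (VERDICT_IDENTIFIABLE if forced
                                else VERDICT_UNIDENTIFIABLE)
        else:
            verdicts[s.name] = (VERDICT_OBSERVABLE if forced
                                else VERDICT_UNOBSERVABLE)
    for s in measured:
        verdicts[s.name] = VERDICT_OBSERVABLE
    return SIMResult(model=model, system=system, nullspace=nullspace,
                     verdicts=verdicts)


# ---------------------------------------------------------------------------
# symmetry-based reduction


def choose_normalization(result: SIMResult,
                         normalize=None) -> tuple[list[sp.Symbol], sp.Matrix]:
    """Pick one parameter per free scaling direction to pin to one.

    Returns the chosen parameters and the reduced-row-echelon basis of the
    nullspace (directions as rows).  The default picks, for each echelon
    direction, the parameter with the lowest declaration index whose
    exponent is +-1; an explicit ``normalize`` list overrides this.  The
    exponent submatrix of the chosen parameters must be invertible so the
    group can reach the ``p = 1`` slice.
    """
    if result.is_trivial:
        raise ReductionError("model has no scaling symmetry to remove")
    model = result.model
    cols = result.system.columns
    basis = sp.Matrix.hstack(*result.nullspace).T
    basis = basis.rref()[0][: len(result.nullspace), :]
    d = basis.rows
    params = set(model.params)
    param_order = {p: i for i, p in enumerate(model.params)}

    if normalize is not None:
        chosen = [sp.Symbol(str(p), real=True) for p in normalize]
        bad = [p for p in chosen if p not in params]
        if bad:
            raise ReductionError(
                f"normalization symbols {bad} are not model parameters")
        if len(chosen) != d:
            raise ReductionError(
                f"need exactly {d} parameters (one per free scaling "
                f"direction), got {len(chosen)}")
    else:
        chosen = []
        for r in range(d):
            row = basis.row(r)
            cands = sorted(
                (s for j, s in enumerate(cols)
                 if s in params and abs(row[j]) == 1 and s not in chosen),
                key=lambda p: param_order[p])
            if not cands:
                raise ReductionError(
                    "a free scaling direction involves no parameter with "
                    "unit exponent (direction acts on states only)")
            chosen.append(cands[0])

    col_index = {s: j for j, s in enumerate(cols)}
    M = sp.Matrix(d, d, lambda i, j: basis[j, col_index[chosen[i]]])
    if M.det() == 0:
        raise ReductionError(
            f"normalization {', '.join(p.name for p in chosen)} does not "
            "span the scaling directions")
    return chosen, basis


def scaling_reduce(model: ODEModel, result: SIMResult | None = None,
                   normalize=None, seed: int = 0) -> ODEModel:
    """Remove the scaling symmetries by pinning chosen parameters to one.

    Every scaling orbit intersects the slice where the chosen parameters
    equal one (generically, for nonzero parameter values), so substituting
    one for them yields an equivalent model with ``nullspace_dim`` fewer
    parameters and a trivial scaling group.
    """
    if result is None:
        result = sim_test(model, seed=seed)
    chosen, _ = choose_normalization(result, normalize)
    reduced = model.subs_params({p: sp.Integer(1) for p in chosen})
    reduced.name = f"{model.name}_scalefixed"
    return reduced


def reduction_value_map(result: SIMResult, normalize=None,
                        values: dict | None = None) -> dict[str, float]:
    """Numeric variable transformation realizing the reduction.

    Given positive numeric ``values`` for every scaled symbol, returns the
    transformed values on the ``p = 1`` slice: the chosen parameters map to
    one and every other scaled symbol is rescaled along the group orbit.
    Used to verify that the reduced model reproduces the original's output.
    """
    import numpy as np

    chosen, basis = choose_normalization(result, normalize)
    cols = result.system.columns
    col_index = {s: j for j, s in enumerate(cols)}
    d = basis.rows
    vals = {sp.Symbol(str(k), real=True): float(v)
            for k, v in (values or {}).items()}
    missing = [s for s in cols if s not in vals]
    if missing:
        raise ValueError(f"missing numeric values for {missing}")
    M = np.array([[float(basis[j, col_index[p]]) for j in range(d)]
                  for p in chosen])
    rhs = np.array([-np.log(vals[p]) for p in chosen])
    t = np.linalg.solve(M, rhs)
    out = {}
    for s in cols:
        w = sum(t[j] * float(basis[j, col_index[s]]) for j in range(d))
        out[s.name] = vals[s] * float(np.exp(w))
    return out
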