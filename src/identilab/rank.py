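"""Observability-identifiability analysis via the extended Lie-derivative rank condition.

The observability-identifiability matrix stacks the gradients of successive
extended Lie derivatives of the outputs with respect to the augmented
variable vector [states; parameters] (parameters are treated as constant
states; known-input derivatives shift up, as the inputs are generic
analytic signals whose derivatives are algebraically independent).  Full
generic rank certifies structural local observability and identifiability;
a variable whose column can be removed without lowering the rank is
unobservable / unidentifiable.

Generic rank is computed exactly: symbols are replaced by random rational
numbers and the rank of the resulting matrix over Q is taken (maximized
over a few seeded trials).  A fully symbolic rank is available as a slow
oracle path.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import sympy as sp

from .errors import DegenerateSampleError, InternalInconsistencyError
from .model import ODEModel

__all__ = ["lie_derivative", "OIMatrix", "build_oi_matrix", "generic_rank",
           "RankResult", "rank_classify"]

V_IDENT = "identifiable"
V_UNIDENT = "unidentifiable"
V_OBS = "observable"
V_UNOBS = "unobservable"


def _input_derivative_map(model: ODEModel, expr: sp.Expr) -> dict:
    """Map u^(j) -> u^(j+1) for every input-derivative symbol in ``expr``."""
    free = expr.free_symbols
    shift = {}
    for u in model.inputs:
        for j in range(model.input_order + 1):
            uj = model.input_derivative(u, j)
            if uj in free:
                shift[uj] = model.input_derivative(u, j + 1)
    return shift


def lie_derivative(model: ODEModel, expr: sp.Expr, order: int = 1) -> sp.Expr:
    """Extended Lie derivative of ``expr`` along the model dynamics.

    Order ``k`` applies ``(grad_x expr) . f + sum_j d(expr)/d(u^(j)) u^(j+1)``
    recursively ``k`` times; parameters are constants.  Raises if the
    required input derivative order exceeds the model's declared bound.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    expr = sp.sympify(expr)
    for _ in range(order):
        shift = _input_derivative_map(model, expr)
        nxt = sp.Add(*(sp.diff(expr, x) * f
                       for x, f in zip(model.states, model.rhs)))
        nxt += sp.Add(*(sp.diff(expr, uj) * uj1
                        for uj, uj1 in shift.items()))
        expr = sp.expand(nxt)
    return expr


class _PolyOI:
    """OI rows in a fast multivariate polynomial ring (internal).

    Symbolic ``Expr`` differentiation is far too slow for the high
    Lie-derivative orders the rank condition needs; for polynomial
    dynamics all rows are built and evaluated with sparse polynomial
    arithmetic over Q instead.
    """

    def __init__(self, model: ODEModel, max_deriv: int):
        from sympy.polys.rings import ring

        self.symbols = list(model.states) + list(model.params)
        for u in model.inputs:
            self.symbols += [model.input_derivative(u, j)
                             for j in range(max_deriv + 1)]
        self.ring, *self.gens = ring(
            ",".join(s.name for s in self.symbols), sp.QQ)
        self.by_name = {s.name: g for s, g in zip(self.symbols, self.gens)}
        self.ncols = len(model.states) + len(model.params)
        self.nstates = len(model.states)
        self.model = model
        self.max_deriv = max_deriv
        self.f = [self.to_poly(e) for e in model.rhs]
        self.rows: list[list] = []

    def to_poly(self, expr: sp.Expr):
        return self.ring(sp.Poly(sp.expand(expr), *self.symbols).as_dict())

    def lie_step(self, p):
        nxt = self.ring.zero
        for i, fp in enumerate(self.f):
            nxt += p.diff(self.gens[i]) * fp
        # rows of order k involve input derivatives up to order k-1 < max_deriv
        for u in self.model.inputs:
            for j in range(self.max_deriv):
                d = p.diff(self.by_name[
                    self.model.input_derivative(u, j).name])
                if d:
                    nxt += d * self.by_name[
                        self.model.input_derivative(u, j + 1).name]
        return nxt

    def add_gradient_row(self, p) -> None:
        self.rows.append([p.diff(self.gens[c]) for c in range(self.ncols)])

    def eval_rows(self, point: dict, start: int = 0) -> list[list]:
        """Exact rational instantiation of rows ``start:`` at a sample point."""
        vals = [(g, sp.QQ.convert(point[s])) for s, g in
                zip(self.symbols, self.gens)]
        return [[sp.Rational(str(p.evaluate(vals))) if p else sp.Integer(0)
                 for p in row] for row in self.rows[start:]]

    def eval_matrix(self, point: dict) -> sp.Matrix:
        """Exact rational instantiation of the rows at a sample point."""
        return sp.Matrix(self.eval_rows(point))

    def expr_matrix(self) -> sp.Matrix:
        back = {sp.Symbol(s.name): s for s in self.symbols}
        return sp.Matrix([[p.as_expr().xreplace(back) for p in row]
                          for row in self.rows])


@dataclass
class OIMatrix:
    """Stacked gradients of output Lie derivatives.

    Row block ``k`` holds the gradients of the order-``k`` Lie derivatives
    of every output with respect to ``columns = [states; parameters]``.
    """

    model: ODEModel
    matrix: sp.Matrix
    columns: list[sp.Symbol]
    order: int
    _poly: "_PolyOI | None" = None

    @property
    def full_dim(self) -> int:
        return len(self.columns)


def _sample_points(oi_symbols, seed: int, trials: int):
    rng = random.Random(seed)
    return [_rational_point(oi_symbols, rng) for _ in range(trials)]


def _build_rows_expr(model: ODEModel, max_order: int, seed: int,
                     early_stop: bool):
    """Plain-Expr fallback for non-polynomial dynamics."""
    columns = list(model.states) + list(model.params)
    rows: list[list[sp.Expr]] = []
    lies = list(model.outputs)
    prev_rank = -1
    order_used = 0
    for k in range(max_order + 1):
        if k > 0:
            lies = [lie_derivative(model, h, 1) for h in lies]
        for h in lies:
            rows.append([sp.diff(h, c) for c in columns])
        order_used = k
        if early_stop and k >= 1:
            r = generic_rank(sp.Matrix(rows), seed=seed, trials=1)
            if r == prev_rank or r == len(columns):
                break
            prev_rank = r
    return sp.Matrix(rows), columns, order_used


def build_oi_matrix(model: ODEModel, max_order: int | None = None,
                    seed: int = 0, early_stop: bool = True) -> OIMatrix:
    """Build the observability-identifiability matrix up to ``max_order``.

    Defaults to the theoretical bound ``n_states + n_params - 1`` and stops
    early once the generic rank is unchanged between two consecutive
    orders (additional rows can no longer raise it).
    """
    if max_order is None:
        max_order = len(model.states) + len(model.params) - 1
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    if max_order > model.input_order and model.inputs:
        raise ValueError(
            f"max_order {max_order} exceeds the declared input derivative "
            f"bound {model.input_order}")
    try:
        poly = _PolyOI(model, max_deriv=max_order)
    except sp.PolynomialError:
        matrix, columns, order_used = _build_rows_expr(
            model, max_order, seed, early_stop)
        return OIMatrix(model=model, matrix=matrix, columns=columns,
                        order=order_used)

    point = _sample_points(poly.symbols, seed, 1)[0]
    lies = [poly.to_poly(h) for h in model.outputs]
    prev_rank = -1
    order_used = 0
    num_rows: list[list] = []
    for k in range(max_order + 1):
        if k > 0:
            lies = [poly.lie_step(h) for h in lies]
        for h in lies:
            poly.add_gradient_row(h)
        order_used = k
        if early_stop and k >= 1:
            num_rows += poly.eval_rows(point, start=len(num_rows))
            r = sp.Matrix(num_rows).rank()
            if r == prev_rank or r == poly.ncols:
                break
            prev_rank = r
    columns = list(model.states) + list(model.params)
    return OIMatrix(model=model, matrix=poly.expr_matrix(), columns=columns,
                    order=order_used, _poly=poly)


def _rational_point(symbols, rng: random.Random) -> dict:
    return {s: sp.Rational(rng.randint(1, 10 ** 4), rng.randint(1, 10 ** 4))
            for s in symbols}


def _numeric_instances(matrix: sp.Matrix, seed: int, trials: int):
    """Exact rational instantiations of a symbolic matrix at random points."""
    syms = sorted(matrix.free_symbols, key=lambda s: s.name)
    rng = random.Random(seed)
    out = []
    attempts = 0
    while len(out) < trials and attempts < 5 * trials:
        attempts += 1
        num = matrix.xreplace(_rational_point(syms, rng))
        if all(e.is_finite for e in num):
            out.append(num)
    if not out:
        raise DegenerateSampleError(
            "all random substitutions hit a pole; try a different seed")
    return out


def _clear_denominators(matrix: sp.Matrix) -> sp.Matrix:
    """Scale each row by the lcm of its denominators (rank-preserving).

    The scaling polynomial is not identically zero, so the generic rank is
    unchanged; the result has polynomial entries suitable for fraction-free
    elimination.
    """
    rows = []
    for i in range(matrix.rows):
        row = [sp.together(e) for e in matrix.row(i)]
        lcm = sp.lcm([sp.fraction(e)[1] for e in row]) if row else 1
        rows.append([sp.expand(sp.cancel(e * lcm)) for e in row])
    return sp.Matrix(rows)


def exact_rank(matrix: sp.Matrix) -> int:
    """Fully symbolic matrix rank via fraction-free exact elimination."""
    from sympy.polys.matrices import DomainMatrix

    if matrix.rows == 0 or matrix.cols == 0:
        return 0
    dm = DomainMatrix.from_Matrix(_clear_denominators(matrix))
    return len(dm.rref_den()[2])


def generic_rank(matrix: sp.Matrix, seed: int = 0, trials: int = 3,
                 exact: bool = False) -> int:
    """Generic (almost-everywhere) rank of a symbolic matrix.

    Random-rational evaluation never overestimates the generic rank, so the
    maximum over trials is a certified lower bound that is tight with
    probability one.  ``exact=True`` computes the fully symbolic rank
    instead (slow oracle).
    """
    if matrix.rows == 0 or matrix.cols == 0:
        return 0
    if exact:
        return exact_rank(matrix)
    if trials < 1:
        raise ValueError("trials must be >= 1")
    return max(n.rank() for n in _numeric_instances(matrix, seed, trials))


@dataclass
class RankResult:
    """Verdicts from the observability-identifiability rank condition."""

    model: ODEModel
    oi: OIMatrix
    rank: int
    verdicts: dict[str, str]
    deficient: list[str]

    @property
    def full_dim(self) -> int:
        return self.oi.full_dim

    @property
    def is_full_rank(self) -> bool:
        return self.rank == self.full_dim


def rank_classify(model: ODEModel, seed: int = 0,
                  max_order: int | None = None, trials: int = 3,
                  exact: bool = False) -> RankResult:
    """Classify every state and parameter by the rank condition.

    A variable is unobservable / unidentifiable iff deleting its column
    leaves the generic rank unchanged; the same set is recomputed from the
    support of the instantiated matrix's nullspace, and the two routes must
    agree (mutual bug trap in exact arithmetic).
    """
    oi = build_oi_matrix(model, max_order=max_order, seed=seed)
    if exact:
        r = generic_rank(oi.matrix, exact=True)
        instances = [oi.matrix]
    elif oi._poly is not None:
        points = _sample_points(oi._poly.symbols, seed + 1, trials)
        instances = [oi._poly.eval_matrix(p) for p in points]
        r = max(n.rank() for n in instances)
    else:
        instances = _numeric_instances(oi.matrix, seed, trials)
        r = max(n.rank() for n in instances)

    def _rank(m: sp.Matrix) -> int:
        return exact_rank(m) if exact else m.rank()

    def _nullspace_support(m: sp.Matrix) -> set[int]:
        if not exact:
            return {i for vec in m.nullspace()
                    for i in range(m.cols) if vec[i] != 0}
        from sympy.polys.matrices import DomainMatrix

        dm = DomainMatrix.from_Matrix(_clear_denominators(m))
        rref, _, pivots = dm.rref_den()
        rref = rref.to_Matrix()
        free = [j for j in range(m.cols) if j not in pivots]
        sup: set[int] = set()
        for j in free:
            sup.add(j)
            sup.update(p for i, p in enumerate(pivots) if rref[i, j] != 0)
        return sup

    ncols = len(oi.columns)
    # route 1: column-removal rank test
    removal = set()
    for j in range(ncols):
        kept = [c for c in range(ncols) if c != j]
        rj = max(_rank(n[:, kept]) for n in instances)
        if rj == r:
            removal.add(j)
    # route 2: union of nullspace supports
    support = set()
    for n in instances:
        if _rank(n) == r:
            support |= _nullspace_support(n)
    if removal != support:
        raise InternalInconsistencyError(
            f"column-removal set {sorted(removal)} disagrees with "
            f"nullspace support {sorted(support)}")

    state_set = set(model.states)
    verdicts = {}
    deficient = []
    for j, s in enumerate(oi.columns):
        bad = j in removal
        if s in state_set:
            verdicts[s.name] = V_UNOBS if bad else V_OBS
        else:
            verdicts[s.name] = V_UNIDENT if bad else V_IDENT
        if bad:
            deficient.append(s.name)
    return RankResult(model=model, oi=oi, rank=r, verdicts=verdicts,
                      deficient=deficient)
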