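"""Symbolic ODE model representation and a strict model-file parser.

A model is

    dx/dt = f(x, lambda, u),    y = h(x)

with states ``x``, unknown parameters ``lambda``, known inputs ``u`` and
measured outputs ``y``.  Everything is stored as exact sympy expressions:
rational constants stay rational, because the downstream scaling-invariance
and rank computations are exact.

Model files are YAML documents with keys ``name``, ``states``,
``parameters``, ``inputs``, ``odes`` (a map state -> infix expression),
``outputs`` and optionally ``known_ic``.  Example::

    name: decay
    states: [x1]
    parameters: [k]
    inputs: []
    odes:
      x1: -k*x1
    outputs: [x1]

Known inputs are generic analytic signals; their time derivatives are
materialized on demand as fresh independent symbols (``g_d1``, ``g_d2``, ...)
up to a per-input derivative-order bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import sympy as sp
import yaml
from sympy.parsing.sympy_parser import (
    parse_expr,
    rationalize,
    standard_transformations,
)

from .errors import ModelError, SIMEligibilityError

__all__ = ["ODEModel", "parse_model", "parse_expression", "model_to_text"]

# functions admitted in model expressions, beyond declared symbols
_ALLOWED_FUNCS = {
    name: getattr(sp, name)
    for name in ("sin", "cos", "tan", "exp", "log", "sqrt", "sinh", "cosh",
                 "tanh", "asin", "acos", "atan", "Abs")
}
_PARSE_TRANSFORMS = standard_transformations + (rationalize,)


def parse_expression(text: str, symbols: dict[str, sp.Symbol]) -> sp.Expr:
    """Parse an infix expression strictly over the declared ``symbols``.

    Rational literals are kept exact (``1/3`` stays ``Rational(1, 3)``;
    float literals are rationalized).  Any free symbol not declared raises
    :class:`ModelError` naming the offender.
    """
    local = dict(_ALLOWED_FUNCS)
    local.update(symbols)
    try:
        expr = parse_expr(str(text), local_dict=local,
                          transformations=_PARSE_TRANSFORMS, evaluate=True)
    except (SyntaxError, TypeError, ValueError) as exc:
        raise ModelError(f"cannot parse expression {text!r}: {exc}") from exc
    expr = sp.sympify(expr)
    extra = expr.free_symbols - set(symbols.values())
    if extra:
        names = ", ".join(sorted(s.name for s in extra))
        raise ModelError(f"undeclared symbol(s) {names} in expression {text!r}")
    return expr


def _make_symbol(name: str) -> sp.Symbol:
    return sp.Symbol(name, real=True)


@dataclass
class ODEModel:
    """An ODE model with unknown parameters, known inputs and measured outputs.

    Parameters
    ----------
    states, params, inputs
        Ordered, pairwise-disjoint symbol lists.  Inputs are known signals.
    rhs
        One expression per state, aligned with ``states``.
    outputs
        Non-empty list of measured output expressions.
    known_ic
        Per-state flag: is the initial condition known?  Defaults to True
        for directly measured states and False otherwise.
    input_order
        Maximum derivative order materialized per input (generic analytic
        signal: derivatives are independent symbols).  Defaults to
        ``len(states) + len(params)``.
    """

    states: list[sp.Symbol]
    params: list[sp.Symbol]
    inputs: list[sp.Symbol]
    rhs: list[sp.Expr]
    outputs: list[sp.Expr]
    known_ic: list[bool] = field(default=None)  # type: ignore[assignment]
    name: str = "model"
    input_order: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.states = [sp.Symbol(str(s), real=True) for s in self.states]
        self.params = [sp.Symbol(str(s), real=True) for s in self.params]
        self.inputs = [sp.Symbol(str(s), real=True) for s in self.inputs]
        self.rhs = [sp.sympify(e) for e in self.rhs]
        self.outputs = [sp.sympify(e) for e in self.outputs]
        names = [s.name for s in self.states + self.params + self.inputs]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ModelError(f"duplicate symbol(s): {', '.join(sorted(dupes))}")
        if len(self.rhs) != len(self.states):
            raise ModelError(
                f"{len(self.states)} states but {len(self.rhs)} equations")
        if not self.outputs:
            raise ModelError("outputs must be non-empty")
        declared = set(self.states) | set(self.params) | set(self.inputs)
        for label, exprs in (("ode", self.rhs), ("output", self.outputs)):
            for e in exprs:
                extra = e.free_symbols - declared
                if extra:
                    nm = ", ".join(sorted(s.name for s in extra))
                    raise ModelError(f"undeclared symbol(s) {nm} in {label} {e}")
        measured = self.measured_states()
        if self.known_ic is None:
            self.known_ic = [s in measured for s in self.states]
        if len(self.known_ic) != len(self.states):
            raise ModelError("known_ic length must match number of states")
        self.known_ic = [bool(b) for b in self.known_ic]
        if self.input_order is None:
            self.input_order = len(self.states) + len(self.params)

    # -- helpers -----------------------------------------------------------

    def measured_states(self) -> set[sp.Symbol]:
        """States that appear literally as outputs."""
        return {h for h in self.outputs if h in set(self.states)}

    def is_sim_eligible(self) -> bool:
        """True iff every output is exactly one state symbol."""
        return all(h in set(self.states) for h in self.outputs)

    def assert_sim_eligible(self) -> None:
        if not self.is_sim_eligible():
            raise SIMEligibilityError(
                f"model {self.name!r}: the scaling-invariance test requires "
                "every output to be a single state symbol")

    def input_derivative(self, inp: sp.Symbol | str, order: int) -> sp.Symbol:
        """Fresh independent symbol for the ``order``-th derivative of an input."""
        inp = sp.Symbol(str(inp), real=True)
        if inp not in self.inputs:
            raise ModelError(f"{inp} is not a declared input of {self.name!r}")
        if order < 0:
            raise ModelError("derivative order must be >= 0")
        if order > self.input_order:
            raise ModelError(
                f"derivative order {order} exceeds bound {self.input_order} "
                f"for input {inp}")
        if order == 0:
            return inp
        return _make_symbol(f"{inp.name}_d{order}")

    def copy(self) -> "ODEModel":
        """Deep, independent copy."""
        return ODEModel(
            states=list(self.states), params=list(self.params),
            inputs=list(self.inputs), rhs=list(self.rhs),
            outputs=list(self.outputs), known_ic=list(self.known_ic),
            name=self.name, input_order=self.input_order)

    def subs_params(self, mapping: dict) -> "ODEModel":
        """Substitute parameter values; substituted parameters are dropped."""
        mapping = {sp.Symbol(str(k), real=True): sp.sympify(v)
                   for k, v in mapping.items()}
        keep = [p for p in self.params if p not in mapping]
        return ODEModel(
            states=list(self.states), params=keep, inputs=list(self.inputs),
            rhs=[e.subs(mapping) for e in self.rhs],
            outputs=[e.subs(mapping) for e in self.outputs],
            known_ic=list(self.known_ic), name=self.name,
            input_order=self.input_order)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"ODEModel({self.name!r}: {len(self.states)} states, "
                f"{len(self.params)} parameters, {len(self.inputs)} inputs)")


def parse_model(text: str) -> ODEModel:
    """Parse a YAML model file into an :class:`ODEModel`.

    Raises :class:`ModelError` for undeclared or duplicate symbols, missing
    equations, or empty outputs.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ModelError(f"invalid model file: {exc}") from exc
    if not isinstance(doc, dict):
        raise ModelError("model file must be a YAML mapping")

    def _namelist(key: str) -> list[str]:
        raw = doc.get(key) or []
        if not isinstance(raw, list):
            raise ModelError(f"{key!r} must be a list of names")
        return [str(n) for n in raw]

    state_names = _namelist("states")
    param_names = _namelist("parameters")
    input_names = _namelist("inputs")
    names = state_names + param_names + input_names
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ModelError(f"duplicate symbol(s): {', '.join(sorted(dupes))}")
    symbols = {n: _make_symbol(n) for n in names}

    odes = doc.get("odes") or {}
    if set(odes) != set(state_names):
        missing = set(state_names) - set(odes)
        extra = set(odes) - set(state_names)
        parts = []
        if missing:
            parts.append(f"missing ODE for {', '.join(sorted(missing))}")
        if extra:
            parts.append(f"ODE for undeclared {', '.join(sorted(extra))}")
        raise ModelError("; ".join(parts))
    rhs = [parse_expression(odes[n], symbols) for n in state_names]

    out_raw = doc.get("outputs") or []
    if not out_raw:
        raise ModelError("outputs must be non-empty")
    outputs = [parse_expression(str(o), symbols) for o in out_raw]

    known_ic = doc.get("known_ic")
    if isinstance(known_ic, dict):
        measured = {str(o) for o in out_raw}
        known_ic = [bool(known_ic.get(n, n in measured)) for n in state_names]
    elif known_ic is not None:
        known_ic = [bool(b) for b in known_ic]

    kwargs = {}
    if "input_order" in doc:
        kwargs["input_order"] = int(doc["input_order"])
    return ODEModel(
        states=[symbols[n] for n in state_names],
        params=[symbols[n] for n in param_names],
        inputs=[symbols[n] for n in input_names],
        rhs=rhs, outputs=outputs, known_ic=known_ic,
        name=str(doc.get("name", "model")), **kwargs)


def model_to_text(model: ODEModel) -> str:
    """Serialize a model back to the YAML schema (round-trip stable)."""
    doc = {
        "name": model.name,
        "states": [s.name for s in model.states],
        "parameters": [p.name for p in model.params],
        "inputs": [u.name for u in model.inputs],
        "odes": {s.name: str(e) for s, e in zip(model.states, model.rhs)},
        "outputs": [str(h) for h in model.outputs],
        "known_ic": {s.name: bool(b)
                     for s, b in zip(model.states, model.known_ic)},
    }
    return yaml.safe_dump(doc, sort_keys=False)
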