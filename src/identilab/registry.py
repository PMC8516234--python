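"""Built-in model registry and synthetic fixture generator.

Ships the two published counter-example models for the scaling-invariance
test — the FitzHugh-Nagumo neuron model and a four-compartment linear
model (full ten-parameter form and its seven-parameter scaling-reduced
form) — plus small synthetic fixtures, and a seeded generator of random
sparse linear compartment models used for property testing.
"""

from __future__ import annotations

import random

from .errors import UnknownModelError
from .model import ODEModel, parse_model

__all__ = ["registry_get", "registry_names", "registry_text",
           "random_compartment_model"]

_MODEL_FILES: dict[str, str] = {
    # Excitable-membrane model: two states, four unknown parameters, the
    # membrane potential x1 is measured.  Carries an affine (non-scaling)
    # symmetry in (x2, a, d), so it is unidentifiable despite having no
    # scaling symmetry.
    "fhn": """
name: fhn
states: [x1, x2]
parameters: [a, b, c, d]
inputs: []
odes:
  x1: c*(x1 - x1**3/3 - x2 + d)
  x2: (x1 + a - b*x2)/c
outputs: [x1]
known_ic: {x1: true, x2: false}
""",
    # Four-compartment linear model with one measured compartment and one
    # known generic input; ten rate constants.  Has three independent
    # scaling symmetries plus one higher-order Lie symmetry.
    "lc_full": """
name: lc_full
states: [x1, x2, x3, x4]
parameters: [a11, a12, a21, a22, a23, a33, a34, a42, a43, a44]
inputs: [g]
odes:
  x1: a11*x1 + a12*x2 + g
  x2: a21*x1 + a22*x2 + a23*x3
  x3: a33*x3 + a34*x4
  x4: a42*x2 + a43*x3 + a44*x4
outputs: [x1]
known_ic: {x1: true, x2: false, x3: false, x4: false}
""",
    # The same model with its scaling symmetries normalized away
    # (a12 = a23 = a42 = 1): seven parameters, no scaling symmetry left,
    # but still one higher-order Lie symmetry in (x4, a33, a43, a44).
    "lc_reduced": """
name: lc_reduced
states: [x1, x2, x3, x4]
parameters: [a11, a21, a22, a33, a34, a43, a44]
inputs: [g]
odes:
  x1: a11*x1 + x2 + g
  x2: a21*x1 + a22*x2 + x3
  x3: a33*x3 + a34*x4
  x4: x2 + a43*x3 + a44*x4
outputs: [x1]
known_ic: {x1: true, x2: false, x3: false, x4: false}
""",
    # Synthetic fixture: a pure scaling symmetry
    # (x2 -> u*x2, k1 -> k1/u, k2 fixed) and nothing else.
    "scaling_pair": """
name: scaling_pair
states: [x1, x2]
parameters: [k1, k2]
inputs: []
odes:
  x1: k1*x2
  x2: k2*x2
outputs: [x1]
""",
    # Synthetic fixture: fully identifiable and observable
    # (no conserved quantity couples the two rates).
    "decay_chain": """
name: decay_chain
states: [x1, x2]
parameters: [k1, k2]
inputs: []
odes:
  x1: -k1*x1 + k2*x2
  x2: -k2*x2
outputs: [x1]
""",
}


def registry_names() -> list[str]:
    """Names of the built-in models."""
    return sorted(_MODEL_FILES)


def registry_text(name: str) -> str:
    """The raw model-file text of a built-in model."""
    try:
        return _MODEL_FILES[name].strip() + "\n"
    except KeyError:
        raise UnknownModelError(
            f"unknown model {name!r}; registered models: "
            f"{', '.join(registry_names())}") from None


def registry_get(name: str) -> ODEModel:
    """Return a deep, independent copy of a built-in model."""
    return parse_model(registry_text(name))


def random_compartment_model(seed: int, n_states: int = 3,
                             edge_prob: float = 0.4,
                             input_prob: float = 0.5) -> ODEModel:
    """Random sparse linear compartment model with ``y = x1``.

    Each directed transfer ``j -> i`` (and each self-loop) is present with
    probability ``edge_prob`` and carries its own unknown rate constant
    ``aij``; with probability ``input_prob`` a known input enters the
    measured compartment.  Every state is guaranteed at least one incoming
    term so no equation is identically zero.
    """
    import sympy as sp

    rng = random.Random(seed)
    states = [sp.Symbol(f"x{i + 1}", real=True) for i in range(n_states)]
    edges: list[tuple[int, int]] = []
    for i in range(n_states):
        row = [j for j in range(n_states) if rng.random() < edge_prob]
        if not row:
            row = [rng.randrange(n_states)]
        edges.extend((i, j) for j in row)
    params = [sp.Symbol(f"a{i + 1}{j + 1}", real=True) for i, j in edges]
    use_input = rng.random() < input_prob
    inputs = [sp.Symbol("g", real=True)] if use_input else []
    rhs = [sp.Integer(0)] * n_states
    for p, (i, j) in zip(params, edges):
        rhs[i] = rhs[i] + p * states[j]
    if use_input:
        rhs[0] = rhs[0] + inputs[0]
    return ODEModel(states=states, params=params, inputs=inputs, rhs=rhs,
                    outputs=[states[0]], name=f"random_lc_{seed}")
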