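# Methods

## Model class and assumptions

`identilab` analyses deterministic ODE models `dx/dt = f(x, λ, u)`,
`y = h(x)` with constant unknown parameters λ, known input signals u and
analytic right-hand sides. Structural identifiability and observability
are *generic* local properties: they hold for almost all parameter/state
values (outside a measure-zero set) and presume a sufficiently exciting
input. All verdicts in this package are therefore generic verdicts;
nothing is claimed about specific degenerate points (e.g. parameters equal
to zero) or about practical identifiability from noisy data, which are out
of scope.

Known inputs are modelled as generic analytic signals: their time
derivatives `u', u'', …` are materialized as algebraically independent
fresh symbols, up to a per-input derivative-order bound (default
`n_states + n_params`, the largest order any analysis here can request).
Initial-condition knowledge is recorded per state; a known IC on an
unmeasured state is stored but deliberately not exploited (neither
analysis here needs it, and exploiting known ICs is a different method).

Expressions are kept exact end to end: the model parser preserves rational
constants (floats are rationalized), and every verdict is produced by
rational linear algebra — no floating point enters any classification.

## Scaling-invariance test

The test decomposes each `f_i` into additive terms after full expansion.
Terms that are functionally dependent (joint Jacobian of generic rank < 2,
decided by exact evaluation at seeded random rational points in [1, 101))
are merged by summation first, so each remaining term carries independent
information. Each term is then required to be invariant under
`x_j → u_xj x_j` (unmeasured states), `λ_i → u_λi λ_i`, with the whole
equation of state i scaled by `1/u_xi`; measured states and known inputs
carry no factor.

Two term shapes are scalable in closed form and accepted:

* a monomial `c · Π s_k^{e_k}` with rational exponents over the scaled
  symbols — one log-linear row `Σ e_k w_k − w_xi = 0` (the `−w_xi` absent
  when state i is measured);
* `φ(m)` with φ a univariate function and m such a monomial — the
  argument must be invariant, contributing a row `Σ e_k w_k = 0`, with any
  monomial cofactor handled as above.

Anything else raises an explicit "unsupported term structure" error naming
the state and term: the procedure is defined by monomial balance, and a
loud failure is preferable to a silent wrong row. Terms with no scaled
symbols at all (e.g. a known input entering a measured state's equation)
impose no constraint and generate no row.

The admissible factor combinations form the exact rational nullspace of
the row matrix. A variable is classified identifiable/observable iff its
coordinate vanishes in every nullspace basis vector (factor forced to 1).
The test is **one-sided by construction**: a nontrivial nullspace is a
genuine scaling symmetry and proves unidentifiability, but a trivial
nullspace proves nothing — the package's comparison report exists to make
that asymmetry visible.

### Scaling reduction

For a d-dimensional nullspace the group orbit generically intersects the
slice where d suitably chosen parameters equal 1, so substituting 1 for
them yields an equivalent model with d fewer parameters. The chosen
parameters must have an invertible exponent submatrix across the echelon
basis of the nullspace (checked exactly); the default choice takes, per
echelon direction, the lowest-declared parameter with exponent ±1, and an
explicit `normalize=` list overrides it — the published seven-parameter
compartment form corresponds to normalizing `{a12, a23, a42}`, which is
what the tests and the worked examples use. `reduction_value_map` provides
the accompanying numeric change of variables so that reduced-model
trajectories can be compared against the original (used in the test
suite; agreement is at integration tolerance). A direction involving only
states (no parameter to normalize) is an error.

## Rank condition

The observability–identifiability matrix stacks the gradients of
`L_f^k h` for k = 0..K with respect to `[x; λ]`, with parameters treated
as constant states and input-derivative symbols shifting up under the
extended Lie derivative. K defaults to the theoretical sufficient bound
`n_states + n_params − 1`, with early termination once the generic rank
stalls between consecutive orders (further rows cannot raise it).

Generic rank is computed by substituting independent random rationals
(numerators/denominators in [1, 10⁴], seeded, 3 trials, pole-resampling)
and taking the exact rank over Q — a certified lower bound on the generic
rank that is tight outside a measure-zero set of sample points; the
maximum over trials guards against unlucky draws. Per-variable verdicts
use the column-removal test (rank unchanged without the variable's column
⇒ unidentifiable/unobservable) and are recomputed independently from
nullspace supports; any disagreement raises an internal error rather than
returning a verdict.

For polynomial dynamics the whole construction runs in sympy's sparse
polynomial rings (exact QQ coefficient arithmetic); plain symbolic
expressions are used otherwise. A fully symbolic rank
(`exact_rank`, fraction-free exact elimination after row-wise denominator
clearing) serves as the slow oracle; the test suite checks
oracle/sampling agreement on the matrices where symbolic elimination is
tractable (the neuron model and small fixtures at full order, the
compartment models truncated to derivative order 4 — beyond that the
polynomial entries make exact elimination impractically large, while the
sampled rank is unaffected).

## Lie symmetries

One-parameter symmetry candidates use a polynomial infinitesimal ansatz:
η for a state is a polynomial in states and parameters, η for a parameter
a polynomial in parameters only (so λ̇ = 0 is preserved), η ≡ 0 for
measured states (output invariance) and for known inputs. The linearized
symmetry condition

```
Σ_j (∂η_xi/∂x_j) f_j = Σ_j (∂f_i/∂x_j) η_xj + Σ_k (∂f_i/∂λ_k) η_λk
```

must hold identically; after clearing (generically nonzero) denominators
the coefficient of every monomial in states, parameters and input symbols
is equated to zero, giving a homogeneous linear system over the ansatz
coefficients. Generators are the integer-normalized rational nullspace
basis (denominators cleared, gcd 1, leading coefficient positive,
lexicographic order).

The default ansatz degree is 1. This is a deliberate choice: because the
determining system is solved over Q, any parameter-monomial multiple of a
generator is again a solution (parameters are constants of the motion), so
a degree-2 ansatz returns each degree-1 generator together with its
rescalings by `a`, `b`, … — the same symmetry with the group parameter ε
rescaled by a constant. Degree 1 recovers both counter-example symmetries
(and all scaling symmetries, whose generators are linear); higher degrees
remain available for models whose symmetries are genuinely nonlinear, with
the duplication caveat documented here.

Exponentiation solves `dz*/dε = η(z*)`, `z*(0) = z`. The Lie series is
computed first and kept when it terminates (nilpotent generators — both
published transforms, including the exact `−a34·ε²` term, arise this
way); otherwise an affine generator receives the exact
augmented-matrix-exponential flow (covers scaling groups,
`x* = e^ε x`); anything else falls back to a truncated Lie series of
order 6, recorded on the transform, and the invariance check then only
asserts vanishing through that order.

`check_transform` verifies invariance symbolically: for each state it
compares the chain-rule time derivative of the starred expression (along
the original dynamics) with the original RHS at starred variables, plus
output residuals; all residuals must simplify to zero identically in ε.
`numeric_validate` integrates the original and transformed systems
(LSODA, default rtol = atol = 1e−11, 200-point grid) and compares outputs;
the pass threshold is `10·(atol + rtol·scale)` with scale the largest
output magnitude seen, i.e. ten times the integrator's own error model.
Known inputs default to the generic signal `sin(t) + 2`.

## Comparison report

`compare` juxtaposes the three verdict sets. The scaling test can only err
in one direction; the report therefore flags variables that the scaling
test passes while the rank condition rejects (`sim_false_pass` overall
when the scaling nullspace is trivial but rank is deficient), and treats
the reverse pattern as an internal soundness error. Text reports always
carry the inconclusiveness warning when the scaling test finds nothing,
because that outcome is never evidence of identifiability.

## Synthetic fixtures

The registry ships, beyond the two published counter-examples, a
two-state cascade with a pure scaling symmetry (`scaling_pair`) and a
fully identifiable decay chain (`decay_chain`), plus a seeded generator of
random sparse linear compartment models (3 states by default, each
directed transfer present with probability 0.4 and carrying its own rate
constant, a known input on the measured compartment with probability 0.5,
`y = x1`). These fixtures exercise the soundness invariant — a nontrivial
scaling nullspace must always coincide with rank deficiency — across the
registry plus 20 seeded random models. They emulate the structure of the
published examples (linear sparse dynamics, single measured state); they
do not emulate nonlinear biochemical kinetics beyond the neuron model, so
passing tests demonstrate correctness of the symbolic machinery, not
coverage of every model family a user might analyse.

## Known limitations

* The scaling test's term-shape classes are monomial-based; genuinely
  non-monomial terms are a hard error, not an approximation.
* Symmetry search requires polynomial (or rational, after denominator
  clearing) dynamics and finds polynomial infinitesimals only; symmetries
  involving time reparameterization or non-polynomial infinitesimals are
  out of scope.
* Verdicts are structural and generic: a model can be structurally
  identifiable yet practically unidentifiable from realistic data.
* Global identifiability (distinguishing discrete parameter branches) is
  not addressed; all results are local.
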