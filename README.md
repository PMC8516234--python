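# identilab

Structural identifiability and observability workbench for symbolic ODE
models, built around a cautionary result: the popular hand-computable
**scaling-invariance test** is only a one-way test, and `identilab` both
implements it and mechanically constructs the counter-examples that refute
its converse.

## Who this is for

Modellers in systems biology and pharmacokinetics who need to know, before
fitting, whether the unknown parameters λ and unmeasured states of a model

```
dx/dt = f(x, λ, u),    y = h(x)
```

can even in principle be recovered from perfect input–output data
(*structural local identifiability* of λ, *observability* of x).

## The three analyses

1. **Scaling-invariance test** (`identilab.sim`). Each unknown parameter
   and unmeasured state is multiplied by a factor `u > 0` and every
   functionally independent additive term of the dynamics must satisfy
   `f_ik(x, λ) = (1/u_xi) f_ik(u_x x, u_λ λ)` (measured states and known
   inputs carry no factor). In log-factors `w = log u` this is an exact
   rational linear system `A w = 0`; variables whose factor is forced to 1
   in every solution are declared identifiable/observable. A nontrivial
   nullspace is a genuine scaling symmetry and *proves* unidentifiability —
   and `scaling_reduce` removes it, yielding an equivalent model with
   fewer parameters.

2. **Observability–identifiability rank condition** (`identilab.rank`).
   The gradients of successive extended Lie derivatives `L_f^k h` with
   respect to `[x; λ]` are stacked into the observability–identifiability
   matrix; generic (almost-everywhere) rank deficiency certifies
   unidentifiability/non-observability, with per-variable verdicts from an
   exact column-removal test cross-checked against nullspace supports.

3. **Lie symmetry analysis** (`identilab.symmetry`). Polynomial
   infinitesimals η (zero on measured states) are found from the linear
   determining equations, exponentiated into finite one-parameter
   transformations `z → z*(z; ε)` (matrix exponential or terminating Lie
   series), verified symbolically (`check_transform`) and numerically
   (`numeric_validate`). These symmetries *explain* every rank deficiency.

`identilab.report.compare` runs all three and flags each variable the
scaling test passes while the rank condition rejects it.

## Worked example

The registry ships the FitzHugh–Nagumo neuron model (`fhn`)

```
dx1/dt = c*(x1 - x1**3/3 - x2 + d)
dx2/dt = (x1 + a - b*x2)/c
y      = x1
```

and a four-state linear compartment model with ten rate constants
(`lc_full`), its seven-parameter scaling-reduced form (`lc_reduced`), and
two synthetic fixtures. Running

```
identilab compare fhn
```

prints

```
model: fhn
overall: sim_false_pass
rank: 5/6   scaling nullspace dim: 0   symmetry generators: 1
options: {'seed': 0, 'degree': 1, 'exact': False, 'max_order': None}

variable   scaling test             rank condition   symmetries
x1         sim_observable           observable       -
x2         sim_observable           unobservable     0  <-- false pass
a          sim_identifiable         unidentifiable   0  <-- false pass
b          sim_identifiable         identifiable     -
c          sim_identifiable         identifiable     -
d          sim_identifiable         unidentifiable   0  <-- false pass

WARNING: the scaling-invariance test found no scaling symmetry; this is inconclusive — non-scaling symmetries are invisible to it, double-check with the rank condition.

False passes of the scaling test: x2, a, d
```

Reading the table: the scaling constraint system has only the trivial
solution (`scaling nullspace dim: 0`), so the scaling test passes every
variable — yet the observability–identifiability matrix has generic rank 5
of 6, and the symmetry finder exhibits the affine one-parameter group

```
x2* = x2 + ε,    a* = a + b·ε,    d* = d + ε
```

under which the output is exactly invariant: `a`, `d` and `x2` are in fact
unidentifiable/unobservable (exit code 4 = false pass of the scaling
test). For the compartment model the same pipeline finds three scaling
symmetries (`identilab sim lc_full`), reduces them away
(`scaling_reduce`, ten → seven parameters), passes the reduced model by
the scaling test, and again refutes that verdict: only `a11, a21, a22,
a34` are identifiable, via the flow `x4* = x4 + x3·ε`,
`a33* = a33 − a34·ε`, `a43* = a43 + (a33 − a44)·ε − a34·ε²`,
`a44* = a44 + a34·ε`.

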