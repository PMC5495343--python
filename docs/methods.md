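# Methods

## The deduction engine

A Zsyntax deduction state is an *aggregate*: an ordered list of
*interactions*, each an ordered list of molecule tokens.  An EVF
(empirically valid formula) is a rewrite rule `reactants → products` whose
reactant side is a single interaction and whose product side is an
aggregate.  One engine round:

1. enumerate ordered index pairs (x, y) of the aggregate, x outer and y
   inner, both descending from `len(aggregate) − 1` (self-pairs x = y
   included);
2. form the candidate interaction by concatenating `agg[x] ++ agg[y]` and
   compare it against EVF reactants at indices `len(evfs) − 1` down to 0;
   equality is exact ordered-sequence equality — no permutation matching,
   because the Z-Interaction is not associative and rule authors are
   expected to order reactants consistently (the TP53 fixture illustrates
   this: `[Kinase, ATP]` forms the complex, `[ATP, Kinase, TP53]` fires
   phosphorylation);
3. on the first match, delete the consumed pair (higher index first, so
   the lower index stays valid), append the rule's products, and start the
   next round; if nothing matches, stop.

The default number of rounds equals the number of EVFs, mirroring the
recursion bound of the underlying definition scheme; because a rule may
fire more than once, a `"fixpoint"` mode iterates to quiescence with a
hard cap (default 1000 firings) and raises `fixpoint_not_reached` when the
cap is hit.  Self-pairs (x = y) are permitted by the literal deletion rule
— both occurrences are removed — but logged as a warning, since the
single-reaction law explicitly excludes them and their intended semantics
is unclear.  Empty EVF product lists are accepted by the engine (the
firing just removes the reactants) but rejected by the problem validator.

Target checking applies Z-Conjunction elimination: if the target
interaction occurs in the final aggregate the result collapses to
`[target]`, otherwise the aggregate is returned unchanged.

**Oracle.** `brute_force_fixpoint_oracle` exhaustively explores every
firing order (any pair, any rule) up to a depth bound and returns the set
of reachable aggregates on which nothing fires.  It is deliberately
independent of the engine's enumeration order and is used to check that
the engine's terminal state is always a reachable fixpoint.

## Kinetics

A kinetic model is an ordered species list plus reactions carrying one
(stoichiometry, concentration) term per species on each side.  Mass-action
flux, stoichiometric matrix and `d[X]/dt = N v` assembly follow the
standard definitions; the matrix is stored reaction-major (the transpose
of the m×n matrix N) and the assembly applies the transpose.  The
arithmetic is type-generic (plain Python operations), which lets the same
assembly code run on floats (simulation), sympy symbols (pretty-printing
the rate equations) and mpmath high-precision numbers (verification).

**Residual verification.** A closed-form solution is a per-species sympy
expression in time and parameters, or — for terminal pools that feed back
into nothing, like the dead-cell compartment M — a directly stated
derivative.  The verifier checks the stated validity assumptions
(positivity of rates; denominators bounded away from zero, with a
near-singularity guard `|denominator| ≥ 1e-6 × parameter scale`), then at
each grid time evaluates the state from the solution, builds the model at
that state and compares the structural derivative of each entry against
the corresponding component of `N v`.  Derivative-only species are
assigned concentration zero when building the state, which is sound
because they never appear as reactants.

Numerical choices:

* grid: t = 0 plus 50 log-spaced points on [1e-3, 10];
* residual tolerance 1e-8 (absolute);
* evaluation in mpmath at 80 significant digits.  This matters: with rates
  drawn up to 10, the growing tumor solutions reach magnitudes around
  e^100 on the grid, where float64 cancellation alone would leave
  residuals around 1e27.  At 80 digits the evaluation error is ~scale ×
  1e-80, so a correct solution verifies to 1e-8 while a 1% perturbation of
  any single species' expression fails by dozens of orders of magnitude.
  Parameters are converted to mpf before evaluation so that no
  subexpression is rounded in double precision.
* compiled (lambdified) solution templates are cached per catalog entry,
  keeping 100-draw verification sweeps over all six models to a few
  seconds.

**Simulation.** `scipy.integrate.solve_ivp` with LSODA, default rtol 1e-6
and atol 1e-9 (the acceptance checks use rtol 1e-10 / atol 1e-12 and
compare against the closed forms at rtol 1e-6 with an absolute floor of
1e-9 of the trajectory scale).  Trajectories are deterministic given
solver settings.

## The model catalog

Schemes over species (A, B, C) with A(0) = A0, B(0) = C(0) = 0:

| id | reactions | auxiliary rates |
|----|-----------|-----------------|
| scheme_01 | A→B (k1), B→C (k2) | — |
| scheme_02 | A→B (k1), B⇄C (k2, k3) | r1 = k1, r2 = k2 + k3 |
| scheme_03 | A⇄B (k1, k2), B→C (k3) | r1 r2 = k1 k3, r1 + r2 = k1 + k2 + k3 |
| scheme_04 | A⇄B (k1, k2), A→C (k3) | r1 r2 = k2 k3, r1 + r2 = k1 + k2 + k3 |

The auxiliary rates r1, r2 are the decay eigenvalues of the linear
subsystem.  They are stored in `SchemeParams` and validated against their
defining constraints rather than silently recomputed; when omitted, the
quadratic is solved with the tie-break r1 < r2 (the discriminant
`(k1+k2+k3)² − 4·product` is non-negative for positive rates).  Each
scheme's solution carries its singularity assumptions (k2 ≠ k1 for
scheme_01; r1 ≠ r2, and r1, r2 ≠ 0 where they appear in denominators).
All four schemes move one molecule per reaction, so every stoichiometric
column sums to zero and A(t) + B(t) + C(t) = A0 identically — checked on
both closed forms and trajectories.

Tumor models under the cancer-stem-cell hypothesis:

* **tumor_full**, species (CSC, P, D, M): CSC→2CSC (k1), CSC→CSC+P (k2),
  CSC→2P (k3), P→2P (k4), P→D (k5), CSC→M (k6), P→M (k7), D→M (k8).  With
  a = k1 − k3 − k6 and b = k4 − k5 − k7 the closed forms are
  CSC(t) = e^{a t} (unit initial stem-cell population),
  P(t) = (k2 + 2k3)(e^{a t} − e^{b t})/(a − b), and D(t) in the
  equivalent partial-fraction form
  `k5 (k2+2k3)/(a−b) · [(e^{at} − e^{−k8 t})/(a+k8) − (e^{bt} − e^{−k8 t})/(b+k8)]`,
  whose denominators (a − b)(a + k8)(b + k8) are exactly the stated
  non-singularity assumptions.  M is derivative-only:
  dM/dt = k6 CSC + k7 P + k8 D.
* **tumor_reduced**, species (CSC, P, M): CSC→CSC+P (k1), CSC→M (k2),
  P→M (k3).  CSC(t) = e^{−k2 t},
  P(t) = ((k3 − k2 − k1) e^{−k3 t} + k1 e^{−k2 t})/(k3 − k2), requiring
  k3 ≠ k2.  Note this P(t) has P(0) = 1: the model starts with one stem
  cell *and* one progenitor, so the total N(0) = CSC(0) + P(0) = 2.  The
  identity dCSC/dt + dP/dt + dM/dt = k1 · CSC(t) (net production comes
  only from asymmetric division) is checked at all grid points.

Total population N(t) sums the living compartments (M excluded); tumor
volume is `V = 4.18e-6 mm³/cell × N`, the per-cell effective volume of a
spherically shaped cell in a spherical tumor; the constant is
configurable.

All six catalog solutions were cross-checked symbolically (sympy
`simplify(diff(solution) − rhs) == 0`) before being frozen, independently
of the numerical verifier.

## Synthetic generators

Deduction-instance generators (deterministic in an explicit seed; sizes
capped at 8 molecules, 6 initial interactions, 4 EVFs):

* *no_reaction*: EVF reactants are rejection-sampled so that none equals
  any pair-concatenation of the initial aggregate (self-pairs included) —
  the condition under which the deduction must be the identity;
* *single_reaction*: single-molecule initial interactions over distinct
  molecules; one EVF reactant is the concatenation of a chosen pair
  (x' ≠ y'), products are fresh distinct interactions, other reactants are
  rejection-sampled to never match; the construction is then checked
  computationally (exactly one possible firing before, none after), so the
  deduction must equal the one-step closed form;
* *free*: reactants are biased (probability 0.6) toward actual
  pair-concatenations so firings are common; instances whose firing graph
  is cyclic or whose chains outrun the oracle depth are rejected, so the
  bounded exhaustive oracle is complete on every emitted instance.

Kinetic parameters are drawn log-uniform on [1e-2, 1e1] per rate, with
draws violating a scheme's validity assumptions rejected (up to 1000
resamples).  The range spans slow and fast kinetics and, for the tumor
models, both growing and collapsing populations.

What the generators do **not** emulate: real pathway databases (molecule
alphabets are abstract tokens; EVF structure is random rather than
curated), measurement noise, or rate constants estimated from data.
Passing the property suite therefore demonstrates correctness of the
deduction/kinetics machinery on the stated model class, not biological
validity of any particular network.

## Problem sizes in the standard checks

Exact pathway reproductions run in milliseconds.  The law checks use 1000
seeded instances per mode; oracle agreement uses 200 free-mode instances
at depth 6; solution verification uses 100 parameter draws per model on
the 51-point grid; simulation agreement uses 20 draws per model with 25
output points on [0, 10].  The full suite runs in well under a minute on
one CPU.

## Known limitations

* Strictly mass-action: no Michaelis–Menten or Hill rate laws, no
  stochastic (Gillespie) kinetics, no parameter estimation, no SBML.
* The deduction engine implements the recursion scheme's enumeration
  order literally; whether the default round bound (the number of EVFs)
  suffices for every network is configuration, not something the engine
  decides — fixpoint mode exists for networks where rules fire repeatedly.
* Interaction equality is strictly ordered; rule sets written with
  inconsistent reactant ordering will not fire.
* The closed-form catalog covers the six models listed above; arbitrary
  models can be simulated and their solutions verified, but users must
  supply the expressions and assumptions themselves.
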