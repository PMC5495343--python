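# biodeduce

Executable reasoning tools for molecular pathways and reaction kinetics:

* a **Zsyntax deduction engine** — Zsyntax is a deductive language for
  molecular biology in which molecules combine through the non-associative
  *Z-Interaction*, co-present complexes form a *Z-Conjunction* (an
  aggregate), and lab-validated rewrite rules, the *Empirically Valid
  Formulae* (EVFs), map a reactant interaction to a product aggregate.  The
  engine repeatedly concatenates ordered pairs of aggregate members, fires
  the first EVF whose reactant equals the candidate exactly, consumes the
  reactants and appends the products, until no rule applies (or a round
  bound is reached);
* a **mass-action kinetics framework** — reaction networks of m species and
  n reactions, flux vectors `v_j = k_j ∏_i [X_i]^{s_ij}` (minus the reverse
  term for reversible reactions), stoichiometric matrices
  `n_ij = s'_ij − s_ij`, assembly of the reaction rate equations
  `d[X]/dt = N v`, numerical simulation, and a high-precision **residual
  verifier** that checks a closed-form solution against the assembled ODEs
  point by point;
* a **model catalog** — four consecutive/reversible reaction schemes with
  their analytical solutions, two cancer-stem-cell tumor-growth
  compartment models (CSC / progenitor P / differentiated D / dead M), and
  the classic TP53-phosphorylation and CSC-death pathway deductions.

It is aimed at systems-biology practitioners who want the symbolic
bookkeeping of pathway deduction and rate-equation derivation to be
executable and mechanically checked rather than done by hand.

## Worked example

Deduce the TP53 phosphorylation pathway (initial aggregate
`[[TP53], [ATP], [Kinase]]`, rules `Kinase*ATP → ATP-Kinase` and
`ATP-Kinase*TP53 → Kinase & pTP53 & ADP`):

```sh
$ biodeduce fixtures --emit tp53 --out tp53.json
$ biodeduce deduce --problem tp53.json --trace
round 0: pair (x=2, y=1) fired EVF 0: [['TP53'], ['ATP'], ['Kinase']] -> [['TP53'], ['ATP', 'Kinase']]
round 1: pair (x=1, y=0) fired EVF 1: [['TP53'], ['ATP', 'Kinase']] -> [['Kinase'], ['pTP53'], ['ADP']]
{
  "final_aggregate": [["Kinase"], ["pTP53"], ["ADP"]],
  "after_elimination": [["pTP53"]],
  "target_reached": true
}
```

(JSON shown compacted.)  The two firings consume the free kinase, ATP and
TP53 and leave phosphorylated TP53 in the final aggregate; Z-Conjunction
elimination confirms the target.

Assemble and verify kinetics — here the reduced tumor model
(`CSC → CSC+P` at rate k1 = 1, `CSC → M` at k2 = 0.5, `P → M` at k3 = 0.25):

```sh
$ biodeduce fixtures --emit tumor_reduced --out tr.json
$ biodeduce build-odes --model tr.json
d[CSC]/dt = -[CSC]/2
d[P]/dt = [CSC] - [P]/4
d[M]/dt = [CSC]/2 + [P]/4

$ echo '{"k1": 1.0, "k2": 2.0}' > p.json
$ biodeduce verify-solution --model-id scheme_01 --params p.json
verification PASS (tol=1e-08, grid=51 points)
  A: max |residual| = 0.000e+00
  B: max |residual| = 2.636e-82
  C: max |residual| = 0.000e+00
  assumption 0 < k1: ok
  assumption 0 < k2: ok
  assumption k2 - k1 != 0: ok
```

The verifier evaluates the structural time derivative of each catalog
expression (here `A(t) = A0 e^{−k1 t}`,
`B(t) = A0 k1 (e^{−k1 t} − e^{−k2 t})/(k2 − k1)`, and the complementary
`C(t)`) and compares it against `N v` at 51 grid points; residuals at the
reported magnitude mean the solution satisfies the rate equations
identically to working precision.  `biodeduce simulate` integrates the
same models numerically and writes a CSV trajectory.

From Python:

```python
from biodeduce import (SchemeParams, deduce_and_check, scheme_builder,
                       scheme_solution, tp53_fixture, verify_solution)

assert deduce_and_check(tp53_fixture()) == (("pTP53",),)
params = SchemeParams({"k1": 1.0, "k2": 2.0})
report = verify_solution(scheme_builder("scheme_01", params),
                         scheme_solution("scheme_01", params))
assert report.passed
```

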