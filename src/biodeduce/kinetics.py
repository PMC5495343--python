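"""Mass-action reaction kinetics: flux vectors, stoichiometric matrices,
ODE assembly, numerical simulation and residual verification of
closed-form solutions.

A kinetic model is a set of m species X1..Xm and n reactions R1..Rn.  Each
reaction carries one term (stoichiometry, concentration) per species, in
model species order, on both its reactant and product side.  Under the law
of mass action the flux of reaction j is

    v_j = k_j * prod_i [X_i]^{s_ij}           (irreversible)
    v_j = k_j^f * prod_i [X_i]^{s_ij} - k_j^r * prod_i [X_i]^{s'_ij}

and the species balance is d[X]/dt = N v with N the m-by-n stoichiometric
matrix, n_ij = s'_ij - s_ij.  The matrix is *stored* reaction-major (one
row per reaction, i.e. N transposed); the ODE assembly applies the
transpose, so the assembled system is exactly d[X]/dt = N v.

Numeric genericity: the flux / rhs functions use plain Python arithmetic,
so concentrations may be floats or ``mpmath.mpf``.  The solution verifier
exploits this — residuals of the tumor-growth solutions reach magnitudes
around e^100 on the default grid, far beyond what float64 can cancel to
1e-8, so it evaluates both sides in mpmath at high working precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Iterable, NamedTuple, Optional, Sequence, Tuple

import mpmath
import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from .errors import (
    EmptyModelError,
    IntegrationFailedError,
    InvalidReactionError,
    NegativeRateError,
    SingularParametersError,
    SpeciesMismatchError,
    UnboundParameterError,
)

IRREVERSIBLE = "irreversible"
REVERSIBLE = "reversible"

T = sp.Symbol("t", nonnegative=True)  # the shared time symbol


class ReactionTerm(NamedTuple):
    """One species' role in a reaction: stoichiometry and current concentration."""

    stoich: int
    conc: float


@dataclass(frozen=True)
class Reaction:
    """A typed reaction spanning the full species list of its model.

    ``kind`` is ``"irreversible"`` or ``"reversible"``; for irreversible
    reactions the reverse constant must be zero (a zero reverse rate is the
    irreversibility convention).
    """

    kind: str
    reactants: Tuple[ReactionTerm, ...]
    products: Tuple[ReactionTerm, ...]
    k_f: float
    k_r: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "reactants",
                           tuple(ReactionTerm(*t) for t in self.reactants))
        object.__setattr__(self, "products",
                           tuple(ReactionTerm(*t) for t in self.products))
        if self.kind not in (IRREVERSIBLE, REVERSIBLE):
            raise InvalidReactionError(f"unknown reaction kind {self.kind!r}")
        if self.k_f < 0 or self.k_r < 0:
            raise NegativeRateError(
                f"rate constants must be non-negative (kf={self.k_f}, kr={self.k_r})"
            )
        if self.kind == IRREVERSIBLE and self.k_r != 0:
            raise InvalidReactionError(
                "irreversible reaction must have a zero reverse rate"
            )
        if len(self.reactants) != len(self.products):
            raise SpeciesMismatchError(
                "reactant and product term lists differ in length"
            )
        for term in self.reactants + self.products:
            if term.stoich < 0:
                raise InvalidReactionError("stoichiometries must be non-negative")


@dataclass(frozen=True)
class KineticModel:
    """An ordered species list plus reactions spanning it, at one state."""

    species: Tuple[str, ...]
    reactions: Tuple[Reaction, ...]

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        if not self.species:
            raise EmptyModelError("model has no species")
        m = len(self.species)
        for j, rxn in enumerate(self.reactions):
            if len(rxn.reactants) != m:
                raise SpeciesMismatchError(
                    f"reaction {j} spans {len(rxn.reactants)} species, model has {m}"
                )

    def state(self) -> Tuple[float, ...]:
        """Concentration vector read off the reactant terms (all reactions of
        a model share the same state, so the first reaction suffices)."""
        if not self.reactions:
            raise EmptyModelError("model has no reactions")
        return tuple(t.conc for t in self.reactions[0].reactants)


def with_state(model: KineticModel, state: Sequence[float]) -> KineticModel:
    """The same reaction network with every concentration rebound to ``state``."""
    state = tuple(state)
    if len(state) != len(model.species):
        raise SpeciesMismatchError(
            f"state length {len(state)} != species count {len(model.species)}"
        )
    def rebind(terms):
        return tuple(ReactionTerm(t.stoich, c) for t, c in zip(terms, state))
    return KineticModel(
        model.species,
        tuple(replace(r, reactants=rebind(r.reactants), products=rebind(r.products))
              for r in model.reactions),
    )


# --------------------------------------------------------------------------
# Fluxes
# --------------------------------------------------------------------------

def mass_action_product(terms: Iterable[ReactionTerm]):
    """prod conc^stoich over terms with positive stoichiometry (empty -> 1)."""
    out = 1
    for term in terms:
        s, c = term[0], term[1]
        if s != 0:
            out = out * c ** s
    return out


def flux_irreversible(reactants, products, k_f):
    """k_f times the mass-action product of the reactants.  ``products`` is
    accepted but unused (signature symmetry with the reversible case)."""
    if k_f < 0:
        raise NegativeRateError(f"negative rate {k_f}")
    return k_f * mass_action_product(reactants)


def flux_reversible(reactants, products, k_f, k_r):
    """Forward minus reverse mass-action flux."""
    if k_f < 0 or k_r < 0:
        raise NegativeRateError(f"negative rate (kf={k_f}, kr={k_r})")
    return k_f * mass_action_product(reactants) - k_r * mass_action_product(products)


def reaction_flux(rxn: Reaction):
    """Flux of a single reaction, dispatching on its kind."""
    if rxn.kind == IRREVERSIBLE:
        return flux_irreversible(rxn.reactants, rxn.products, rxn.k_f)
    return flux_reversible(rxn.reactants, rxn.products, rxn.k_f, rxn.k_r)


def flux_vector(model: KineticModel):
    """v = (v_1, ..., v_n): one mass-action flux per reaction."""
    if not model.reactions:
        raise EmptyModelError("flux vector of a model with no reactions")
    return [reaction_flux(r) for r in model.reactions]


# --------------------------------------------------------------------------
# Stoichiometry and ODE assembly
# --------------------------------------------------------------------------

def stoich_column(reactants: Sequence[ReactionTerm],
                  products: Sequence[ReactionTerm]):
    """Net production per species: s'_i - s_i."""
    if len(reactants) != len(products):
        raise SpeciesMismatchError("term lists differ in length")
    return [p[0] - r[0] for r, p in zip(reactants, products)]


def stoich_matrix(model: KineticModel):
    """Reaction-major storage (row j = column j of the m-by-n matrix N)."""
    return [stoich_column(r.reactants, r.products) for r in model.reactions]


def ode_rhs(model: KineticModel):
    """d[X]/dt = N v, component i = sum_j n_ij v_j (type-generic)."""
    rows = stoich_matrix(model)
    v = flux_vector(model)
    out = [0] * len(model.species)
    for col, vj in zip(rows, v):
        for i, n in enumerate(col):
            if n:
                out[i] = out[i] + n * vj
    return out


# --------------------------------------------------------------------------
# Closed-form solutions
# --------------------------------------------------------------------------

CONCENTRATION = "concentration"
DERIVATIVE = "derivative"

POSITIVE = "positive"
NONZERO = "nonzero"

#: Near-singularity guard: a "nonzero" assumption fails when the magnitude
#: of its expression drops below this fraction of the parameter scale.
SINGULARITY_GUARD = 1e-6


@dataclass(frozen=True)
class SolutionEntry:
    """One species' entry: either its concentration as a function of time,
    or (``derivative`` kind) its time derivative given directly."""

    kind: str
    expr: sp.Expr


@dataclass(frozen=True)
class Assumption:
    """A validity predicate on the parameters: ``expr`` must be strictly
    positive (kind ``positive``) or bounded away from zero (kind
    ``nonzero``, guarded against near-singularity)."""

    name: str
    kind: str
    expr: sp.Expr

    def holds(self, params: Dict[str, float], guard: float = SINGULARITY_GUARD) -> bool:
        value = float(self.expr.subs({sp.Symbol(k, positive=True): v
                                      for k, v in params.items()}).subs(
            {sp.Symbol(k): v for k, v in params.items()}))
        if self.kind == POSITIVE:
            return value > 0
        scale = max(1.0, sum(abs(v) for v in params.values()))
        return abs(value) >= guard * scale


@dataclass(frozen=True)
class ClosedFormSolution:
    """Per-species time expressions (or direct derivatives) with the
    parameter values bound and the validity assumptions attached.

    ``cache_key`` identifies solutions sharing one symbolic template so the
    verifier can compile (lambdify) the template once per catalog entry.
    """

    species: Tuple[str, ...]
    entries: Dict[str, SolutionEntry]
    assumptions: Tuple[Assumption, ...]
    params: Dict[str, float]
    cache_key: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        missing = [s for s in self.species if s not in self.entries]
        if missing:
            raise SpeciesMismatchError(f"no solution entry for species {missing}")
        allowed = {T} | {sp.Symbol(p) for p in self.params} | {
            sp.Symbol(p, positive=True) for p in self.params}
        for name, entry in self.entries.items():
            free = entry.expr.free_symbols - allowed
            if free:
                raise UnboundParameterError(
                    f"entry for {name} has unbound symbols {sorted(map(str, free))}"
                )

    def assumption_checks(self) -> Dict[str, bool]:
        return {a.name: a.holds(self.params) for a in self.assumptions}

    def require_assumptions(self) -> None:
        for name, ok in self.assumption_checks().items():
            if not ok:
                raise SingularParametersError(
                    f"assumption failed: {name}", assumption=name
                )


def perturbed(sol: ClosedFormSolution, species: str,
              factor: float = 1.01) -> ClosedFormSolution:
    """Copy of ``sol`` with one species' expression scaled by ``factor`` —
    used to confirm the verifier rejects wrong solutions."""
    entries = dict(sol.entries)
    e = entries[species]
    entries[species] = SolutionEntry(e.kind, e.expr * factor)
    key = (f"{sol.cache_key}|perturbed:{species}:{factor}"
           if sol.cache_key else None)
    return replace(sol, entries=entries, cache_key=key)


class _Compiled(NamedTuple):
    param_names: Tuple[str, ...]
    conc: Dict[str, Callable]    # species -> f(t, *params); absent if derivative-only
    deriv: Dict[str, Callable]   # species -> f(t, *params)


_COMPILE_CACHE: Dict[str, _Compiled] = {}


def _compile(sol: ClosedFormSolution) -> _Compiled:
    if sol.cache_key is not None and sol.cache_key in _COMPILE_CACHE:
        return _COMPILE_CACHE[sol.cache_key]
    names = tuple(sorted(sol.params))
    args = (T,) + tuple(sp.Symbol(n, positive=True) for n in names)
    # entries may use plain or assumption-tagged symbols; normalise to tagged
    norm = {sp.Symbol(n): sp.Symbol(n, positive=True) for n in names}
    conc, deriv = {}, {}
    for name, entry in sol.entries.items():
        expr = entry.expr.subs(norm)
        if entry.kind == CONCENTRATION:
            conc[name] = sp.lambdify(args, expr, modules="mpmath")
            deriv[name] = sp.lambdify(args, sp.diff(expr, T), modules="mpmath")
        else:
            deriv[name] = sp.lambdify(args, expr, modules="mpmath")
    out = _Compiled(names, conc, deriv)
    if sol.cache_key is not None:
        _COMPILE_CACHE[sol.cache_key] = out
    return out


def default_grid(n: int = 50, t_min: float = 1e-3, t_max: float = 10.0):
    """t = 0 plus ``n`` log-spaced points on [t_min, t_max]."""
    return np.concatenate([[0.0], np.geomspace(t_min, t_max, n)])


def evaluate_solution(sol: ClosedFormSolution, t: float,
                      dps: int = 80) -> Dict[str, float]:
    """Concentrations at time ``t`` (derivative-only species excluded)."""
    c = _compile(sol)
    pvals = [mpmath.mpf(sol.params[n]) for n in c.param_names]
    with mpmath.workdps(dps):
        return {name: fn(mpmath.mpf(t), *pvals) for name, fn in c.conc.items()}


def differentiate_solutions(sol: ClosedFormSolution, t: float,
                            dps: int = 80):
    """d/dt of each entry at ``t``, in species order: structural derivative
    for concentration entries, the given expression for derivative-only
    entries."""
    c = _compile(sol)
    pvals = [mpmath.mpf(sol.params[n]) for n in c.param_names]
    with mpmath.workdps(dps):
        tt = mpmath.mpf(t)
        return [c.deriv[name](tt, *pvals) for name in sol.species]


@dataclass(frozen=True)
class VerificationReport:
    """Outcome of checking d[X]/dt = N v against a closed-form solution."""

    species: Tuple[str, ...]
    max_abs_residual: Dict[str, float]
    grid: Tuple[float, ...]
    tol: float
    assumption_checks: Dict[str, bool]
    passed: bool

    def __str__(self):
        lines = [f"verification {'PASS' if self.passed else 'FAIL'} "
                 f"(tol={self.tol:g}, grid={len(self.grid)} points)"]
        for s in self.species:
            lines.append(f"  {s}: max |residual| = {self.max_abs_residual[s]:.3e}")
        for name, ok in self.assumption_checks.items():
            lines.append(f"  assumption {name}: {'ok' if ok else 'VIOLATED'}")
        return "\n".join(lines)


def verify_solution(model_builder: Callable[[Sequence[float]], KineticModel],
                    sol: ClosedFormSolution,
                    grid: Optional[Sequence[float]] = None,
                    tol: float = 1e-8,
                    dps: int = 80) -> VerificationReport:
    """Residual check of a closed-form solution against the assembled ODEs.

    For every grid time: evaluate the state from the solution, build the
    model at that state, and compare the structural derivative of each
    entry against the corresponding component of N v.  Assumptions are
    checked first; a violated one raises ``singular_parameters``.

    Derivative-only species (those whose balance is stated as d[X]/dt
    directly) are assigned concentration zero when building the state; this
    is sound only if they appear in no reactant term, which holds for the
    terminal dead-cell compartments this form exists for.
    """
    sol.require_assumptions()
    if grid is None:
        grid = default_grid()
    grid = tuple(float(t) for t in grid)
    if not grid:
        raise SpeciesMismatchError("empty verification grid")

    compiled = _compile(sol)
    # mpf parameters: float-float subexpressions would otherwise round in
    # double precision before promotion
    pvals = [mpmath.mpf(sol.params[n]) for n in compiled.param_names]
    worst = {s: 0.0 for s in sol.species}
    with mpmath.workdps(dps):
        zero = mpmath.mpf(0)
        for t in grid:
            tt = mpmath.mpf(t)
            conc = {name: fn(tt, *pvals) for name, fn in compiled.conc.items()}
            state = [conc.get(s, zero) for s in sol.species]
            model = model_builder(state)
            if tuple(model.species) != tuple(sol.species):
                raise SpeciesMismatchError(
                    "model and solution disagree on the species list"
                )
            rhs = ode_rhs(model)
            for i, s in enumerate(sol.species):
                lhs = compiled.deriv[s](tt, *pvals)
                res = abs(lhs - rhs[i])
                if res > worst[s]:
                    worst[s] = float(res)
    checks = sol.assumption_checks()
    passed = all(r <= tol for r in worst.values()) and all(checks.values())
    return VerificationReport(tuple(sol.species), worst, grid, tol, checks, passed)


# --------------------------------------------------------------------------
# Numerical simulation
# --------------------------------------------------------------------------

class Trajectory(NamedTuple):
    t: np.ndarray          # shape (n_out,)
    y: np.ndarray          # shape (n_out, m)
    species: Tuple[str, ...]


def simulate(model_builder: Callable[[Sequence[float]], KineticModel],
             initial: Sequence[float],
             t_max: float,
             rtol: float = 1e-6,
             atol: float = 1e-9,
             n_out: int = 100,
             method: str = "LSODA") -> Trajectory:
    """Integrate d[X]/dt = N v from ``initial`` over [0, t_max].

    Deterministic given solver settings; raises ``integration_failed``
    with the solver's diagnostics otherwise.
    """
    if t_max <= 0:
        raise IntegrationFailedError(f"t_max must be positive, got {t_max}")
    initial = np.asarray(initial, dtype=float)
    if not np.all(np.isfinite(initial)) or np.any(initial < 0):
        raise IntegrationFailedError("initial state must be finite and non-negative")
    species = tuple(model_builder(initial).species)
    if len(initial) != len(species):
        raise SpeciesMismatchError("initial state length != species count")

    def rhs(_t, y):
        return np.asarray(ode_rhs(model_builder(y)), dtype=float)

    t_eval = np.linspace(0.0, t_max, n_out)
    result = solve_ivp(rhs, (0.0, t_max), initial, method=method,
                       rtol=rtol, atol=atol, t_eval=t_eval)
    if not result.success:
        raise IntegrationFailedError(result.message)
    return Trajectory(result.t, result.y.T.copy(), species)
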