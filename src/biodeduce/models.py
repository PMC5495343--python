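"""Catalog of concrete models: four generic reaction schemes, the two
cancer-stem-cell tumor-growth models, and the TP53 / CSC-death pathway
deduction fixtures.

Reaction schemes (species order A, B, C, initial A(0)=A0, B(0)=C(0)=0):

  scheme_01   A -> B -> C, both irreversible (k1, k2)
  scheme_02   A -> B (k1), B <-> C (k2 forward, k3 reverse)
  scheme_03   A <-> B (k1, k2), B -> C (k3)
  scheme_04   A <-> B (k1, k2), A -> C (k3)

Tumor models (cell compartments: cancer stem cells CSC, progenitors P,
terminally differentiated D, dead M; unit initial CSC):

  tumor_full     CSC->2CSC (k1), CSC->CSC+P (k2), CSC->2P (k3), P->2P (k4),
                 P->D (k5), CSC->M (k6), P->M (k7), D->M (k8)
  tumor_reduced  CSC->CSC+P (k1), CSC->M (k2), P->M (k3)

Each scheme has a closed-form solution entry whose correctness is what the
residual verifier in :mod:`biodeduce.kinetics` checks: the structural time
derivative of every expression must equal the corresponding component of
N v at every grid point.  Schemes 2-4 express their solutions through
auxiliary decay rates r1, r2 (the eigenvalues of the linear subsystem),
defined by product/sum constraints on the k's; ``resolve_params`` solves
the quadratic and takes r1 < r2.

The dead-cell compartment M of both tumor models is a *derivative-only*
entry: its balance d[M]/dt = sum of the death fluxes is stated directly
rather than integrated, since M feeds back into nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Optional, Sequence, Tuple

import sympy as sp

from .errors import (
    NegativeCountError,
    SingularParametersError,
    UnknownSchemeError,
)
from .kinetics import (
    CONCENTRATION,
    DERIVATIVE,
    IRREVERSIBLE,
    REVERSIBLE,
    Assumption,
    ClosedFormSolution,
    KineticModel,
    NONZERO,
    POSITIVE,
    Reaction,
    ReactionTerm,
    SolutionEntry,
    T,
    evaluate_solution,
)
from .zsyntax import EVF, ZsyntaxProblem

SCHEME_IDS = ("scheme_01", "scheme_02", "scheme_03", "scheme_04",
              "tumor_full", "tumor_reduced")

#: Effective volume of one spherically shaped cell in a spherical tumor.
CELL_VOLUME_MM3 = 4.18e-6

_SPECIES = {
    "scheme_01": ("A", "B", "C"),
    "scheme_02": ("A", "B", "C"),
    "scheme_03": ("A", "B", "C"),
    "scheme_04": ("A", "B", "C"),
    "tumor_full": ("CSC", "P", "D", "M"),
    "tumor_reduced": ("CSC", "P", "M"),
}

_REQUIRED_RATES = {
    "scheme_01": ("k1", "k2"),
    "scheme_02": ("k1", "k2", "k3"),
    "scheme_03": ("k1", "k2", "k3"),
    "scheme_04": ("k1", "k2", "k3"),
    "tumor_full": ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8"),
    "tumor_reduced": ("k1", "k2", "k3"),
}

# reaction tables: (kind, {species: reactant stoich}, {species: product stoich},
#                   forward rate name, reverse rate name or None)
_REACTIONS = {
    "scheme_01": [
        (IRREVERSIBLE, {"A": 1}, {"B": 1}, "k1", None),
        (IRREVERSIBLE, {"B": 1}, {"C": 1}, "k2", None),
    ],
    "scheme_02": [
        (IRREVERSIBLE, {"A": 1}, {"B": 1}, "k1", None),
        (REVERSIBLE, {"B": 1}, {"C": 1}, "k2", "k3"),
    ],
    "scheme_03": [
        (REVERSIBLE, {"A": 1}, {"B": 1}, "k1", "k2"),
        (IRREVERSIBLE, {"B": 1}, {"C": 1}, "k3", None),
    ],
    "scheme_04": [
        (REVERSIBLE, {"A": 1}, {"B": 1}, "k1", "k2"),
        (IRREVERSIBLE, {"A": 1}, {"C": 1}, "k3", None),
    ],
    "tumor_full": [
        (IRREVERSIBLE, {"CSC": 1}, {"CSC": 2}, "k1", None),
        (IRREVERSIBLE, {"CSC": 1}, {"CSC": 1, "P": 1}, "k2", None),
        (IRREVERSIBLE, {"CSC": 1}, {"P": 2}, "k3", None),
        (IRREVERSIBLE, {"P": 1}, {"P": 2}, "k4", None),
        (IRREVERSIBLE, {"P": 1}, {"D": 1}, "k5", None),
        (IRREVERSIBLE, {"CSC": 1}, {"M": 1}, "k6", None),
        (IRREVERSIBLE, {"P": 1}, {"M": 1}, "k7", None),
        (IRREVERSIBLE, {"D": 1}, {"M": 1}, "k8", None),
    ],
    "tumor_reduced": [
        (IRREVERSIBLE, {"CSC": 1}, {"CSC": 1, "P": 1}, "k1", None),
        (IRREVERSIBLE, {"CSC": 1}, {"M": 1}, "k2", None),
        (IRREVERSIBLE, {"P": 1}, {"M": 1}, "k3", None),
    ],
}


@dataclass(frozen=True)
class SchemeParams:
    """Rate constants (k1..k8 as the scheme requires), the initial amount
    A0 of the first species, and — for schemes 2-4 — the auxiliary decay
    rates r1, r2 (filled in by :func:`resolve_params` when omitted)."""

    rates: Dict[str, float]
    a0: float = 1.0
    r1: Optional[float] = None
    r2: Optional[float] = None

    def as_dict(self) -> Dict[str, float]:
        out = dict(self.rates)
        out["A0"] = self.a0
        if self.r1 is not None:
            out["r1"] = self.r1
        if self.r2 is not None:
            out["r2"] = self.r2
        return out


def _check_scheme(scheme_id: str) -> None:
    if scheme_id not in SCHEME_IDS:
        raise UnknownSchemeError(f"unknown scheme {scheme_id!r}")


def scheme_species(scheme_id: str) -> Tuple[str, ...]:
    _check_scheme(scheme_id)
    return _SPECIES[scheme_id]


def auxiliary_roots(scheme_id: str, rates: Dict[str, float]) -> Tuple[float, float]:
    """(r1, r2) with r1 < r2 from the scheme's defining constraints:
    scheme_02: r1 = k1, r2 = k2 + k3;
    scheme_03: r1 r2 = k1 k3, r1 + r2 = k1 + k2 + k3;
    scheme_04: r1 r2 = k2 k3, r1 + r2 = k1 + k2 + k3."""
    k1, k2, k3 = rates["k1"], rates["k2"], rates["k3"]
    if scheme_id == "scheme_02":
        pair = (k1, k2 + k3)
        return (min(pair), max(pair))
    prod = k1 * k3 if scheme_id == "scheme_03" else k2 * k3
    s = k1 + k2 + k3
    disc = s * s - 4.0 * prod  # >= (k1+k3)^2 - 4 k1 k3 >= 0 for positive rates
    root = math.sqrt(max(disc, 0.0))
    return ((s - root) / 2.0, (s + root) / 2.0)


def resolve_params(scheme_id: str, params: SchemeParams,
                   rel_tol: float = 1e-9) -> SchemeParams:
    """Validate the rate set and fill in (or cross-check) r1, r2."""
    _check_scheme(scheme_id)
    missing = [k for k in _REQUIRED_RATES[scheme_id] if k not in params.rates]
    if missing:
        raise SingularParametersError(
            f"scheme {scheme_id} needs rates {missing}", missing=missing
        )
    for name in _REQUIRED_RATES[scheme_id]:
        if params.rates[name] <= 0:
            raise SingularParametersError(
                f"rate {name} must be positive", assumption=f"0 < {name}"
            )
    if scheme_id in ("scheme_01", "tumor_full", "tumor_reduced"):
        return params
    r1, r2 = auxiliary_roots(scheme_id, params.rates)
    if params.r1 is not None or params.r2 is not None:
        given = sorted(v for v in (params.r1, params.r2) if v is not None)
        want = [r1, r2][:len(given)] if len(given) < 2 else [r1, r2]
        scale = max(abs(r1), abs(r2), 1.0)
        if len(given) != 2 or any(abs(g - w) > rel_tol * scale
                                  for g, w in zip(given, want)):
            raise SingularParametersError(
                "supplied (r1, r2) violate the scheme's defining constraints",
                assumption="r1 r2 / r1 + r2 constraints",
            )
    return replace(params, r1=r1, r2=r2)


def build_scheme(scheme_id: str, params: SchemeParams,
                 state: Sequence[float]) -> KineticModel:
    """The scheme's reaction list instantiated at the given state."""
    _check_scheme(scheme_id)
    params = resolve_params(scheme_id, params)
    species = _SPECIES[scheme_id]
    if len(state) != len(species):
        raise SingularParametersError(
            f"state length {len(state)} != species count {len(species)}"
        )
    conc = dict(zip(species, state))
    reactions = []
    for kind, reac, prod, kf, kr in _REACTIONS[scheme_id]:
        reactants = tuple(ReactionTerm(reac.get(s, 0), conc[s]) for s in species)
        products = tuple(ReactionTerm(prod.get(s, 0), conc[s]) for s in species)
        reactions.append(Reaction(kind, reactants, products,
                                  params.rates[kf],
                                  params.rates[kr] if kr else 0.0))
    return KineticModel(species, tuple(reactions))


def scheme_builder(scheme_id: str, params: SchemeParams
                   ) -> Callable[[Sequence[float]], KineticModel]:
    """state -> model closure for the simulator and the verifier."""
    _check_scheme(scheme_id)
    params = resolve_params(scheme_id, params)
    return lambda state: build_scheme(scheme_id, params, state)


def initial_state(scheme_id: str, params: SchemeParams) -> Tuple[float, ...]:
    """The catalog initial condition: (A0, 0, 0) for the schemes, unit CSC
    for the tumor models (the reduced model also starts with one P cell,
    as its closed form requires)."""
    _check_scheme(scheme_id)
    if scheme_id.startswith("scheme"):
        return (params.a0, 0.0, 0.0)
    if scheme_id == "tumor_full":
        return (1.0, 0.0, 0.0, 0.0)
    return (1.0, 1.0, 0.0)  # tumor_reduced: P(0) = 1 per its closed form


# --------------------------------------------------------------------------
# Closed-form solution catalog
# --------------------------------------------------------------------------

def _sym(name):
    return sp.Symbol(name, positive=True)

_K = {i: _sym(f"k{i}") for i in range(1, 9)}
_A0, _R1, _R2 = _sym("A0"), _sym("r1"), _sym("r2")


def _catalog() -> Dict[str, Tuple[Dict[str, SolutionEntry], Tuple[Assumption, ...]]]:
    k1, k2, k3, k4, k5, k6, k7, k8 = (_K[i] for i in range(1, 9))
    A0, r1, r2, t = _A0, _R1, _R2, T
    e = sp.exp

    pos = lambda *ks: tuple(
        Assumption(f"0 < {k}", POSITIVE, _sym(str(k))) for k in ks)
    nz = lambda name, expr: Assumption(name, NONZERO, expr)
    C = lambda expr: SolutionEntry(CONCENTRATION, expr)
    Dv = lambda expr: SolutionEntry(DERIVATIVE, expr)

    cat: Dict[str, Tuple[Dict[str, SolutionEntry], Tuple[Assumption, ...]]] = {}

    # -- scheme 1: A -> B -> C
    A = A0 * e(-k1 * t)
    B = A0 * k1 / (k2 - k1) * (e(-k1 * t) - e(-k2 * t))
    Cc = A0 * (1 - k2 / (k2 - k1) * e(-k1 * t) - k1 / (k1 - k2) * e(-k2 * t))
    cat["scheme_01"] = (
        {"A": C(A), "B": C(B), "C": C(Cc)},
        pos("k1", "k2") + (nz("k2 - k1 != 0", k2 - k1),),
    )

    # -- scheme 2: A -> B, B <-> C; r1 = k1, r2 = k2 + k3
    B = k1 * A0 * (k3 / (r1 * r2)
                   + (r2 - k3) / (r2 * (r1 - r2)) * e(-r2 * t)
                   + (k3 - r1) / (r1 * (r1 - r2)) * e(-r1 * t))
    Cc = k1 * k2 * A0 * (1 / (r1 * r2)
                         + e(-r1 * t) / (r1 * (r1 - r2))
                         + e(-r2 * t) / (r2 * (r2 - r1)))
    cat["scheme_02"] = (
        {"A": C(A), "B": C(B), "C": C(Cc)},
        pos("k1", "k2", "k3") + (nz("r1 != r2", r1 - r2),),
    )

    # -- scheme 3: A <-> B, B -> C; r1 r2 = k1 k3, r1 + r2 = k1 + k2 + k3
    A3 = A0 / (r2 - r1) * ((k2 + k3 - r1) * e(-r1 * t)
                           - (k2 + k3 - r2) * e(-r2 * t))
    B3 = A0 * k1 / (r2 - r1) * (e(-r1 * t) - e(-r2 * t))
    C3 = A0 * (1 + k1 * k3 / (r1 * (r1 - r2)) * e(-r1 * t)
               + k1 * k3 / (r2 * (r2 - r1)) * e(-r2 * t))
    cat["scheme_03"] = (
        {"A": C(A3), "B": C(B3), "C": C(C3)},
        pos("k1", "k2", "k3") + (nz("r1 != 0", r1), nz("r2 != 0", r2),
                                 nz("r1 != r2", r1 - r2)),
    )

    # -- scheme 4: A <-> B, A -> C; r1 r2 = k2 k3, r1 + r2 = k1 + k2 + k3
    A4 = A0 * ((k2 - r1) / (r2 - r1) * e(-r1 * t)
               - (k2 - r2) / (r2 - r1) * e(-r2 * t))
    B4 = k1 * A0 / (r2 - r1) * (e(-r1 * t) - e(-r2 * t))
    C4 = A0 * (1 + k3 * (k2 - r1) / (r1 * (r1 - r2)) * e(-r1 * t)
               + k3 * (k2 - r2) / (r2 * (r2 - r1)) * e(-r2 * t))
    cat["scheme_04"] = (
        {"A": C(A4), "B": C(B4), "C": C(C4)},
        pos("k1", "k2", "k3") + (nz("r1 != 0", r1), nz("r2 != 0", r2),
                                 nz("r1 != r2", r1 - r2)),
    )

    # -- full tumor model; a, b are the net CSC and P growth exponents
    a = k1 - k3 - k6
    b = k4 - k5 - k7
    CSC = e(a * t)
    P = (k2 + 2 * k3) * (e(a * t) - e(b * t)) / (a - b)
    Dd = (k5 * (k2 + 2 * k3) / (a - b)
          * ((e(a * t) - e(-k8 * t)) / (a + k8)
             - (e(b * t) - e(-k8 * t)) / (b + k8)))
    cat["tumor_full"] = (
        {"CSC": C(CSC), "P": C(P), "D": C(Dd),
         "M": Dv(k6 * CSC + k7 * P + k8 * Dd)},
        pos(*[f"k{i}" for i in range(1, 9)]) + (
            nz("k1 - k3 - k4 + k5 - k6 + k7 != 0", a - b),
            nz("-k1 + k3 + k6 - k8 != 0", -a - k8),
            nz("-k4 + k5 + k7 - k8 != 0", -b - k8),
        ),
    )

    # -- reduced tumor model
    CSCr = e(-k2 * t)
    Pr = ((k3 - k2 - k1) * e(-k3 * t) + k1 * e(-k2 * t)) / (k3 - k2)
    cat["tumor_reduced"] = (
        {"CSC": C(CSCr), "P": C(Pr), "M": Dv(k2 * CSCr + k3 * Pr)},
        pos("k1", "k2", "k3") + (nz("k3 - k2 != 0", k3 - k2),),
    )
    return cat


_CATALOG = _catalog()


def scheme_solution(scheme_id: str, params: SchemeParams) -> ClosedFormSolution:
    """The catalog closed-form solution with parameters bound; raises
    ``singular_parameters`` when the validity assumptions fail."""
    _check_scheme(scheme_id)
    params = resolve_params(scheme_id, params)
    entries, assumptions = _CATALOG[scheme_id]
    bound = {k: v for k, v in params.as_dict().items()}
    sol = ClosedFormSolution(
        species=_SPECIES[scheme_id],
        entries=entries,
        assumptions=assumptions,
        params=bound,
        cache_key=scheme_id,
    )
    sol.require_assumptions()
    return sol


# --------------------------------------------------------------------------
# Tumor bookkeeping
# --------------------------------------------------------------------------

def total_cells(sol: ClosedFormSolution, t: float) -> float:
    """N(t): the sum of the living compartments' closed forms at ``t``
    (derivative-only entries — the dead pool M — are excluded)."""
    if t < 0:
        raise NegativeCountError(f"time must be non-negative, got {t}")
    return float(sum(evaluate_solution(sol, t).values()))


def tumor_volume(n_cells: float, per_cell_mm3: float = CELL_VOLUME_MM3) -> float:
    """Tumor volume in mm^3 from a cell count, at the per-cell effective
    volume of a spherically shaped cell in a spherical tumor."""
    if n_cells < 0:
        raise NegativeCountError(f"cell count must be non-negative, got {n_cells}")
    return n_cells * per_cell_mm3


# --------------------------------------------------------------------------
# Pathway deduction fixtures
# --------------------------------------------------------------------------

def tp53_fixture() -> ZsyntaxProblem:
    """Phosphorylation of the tumor suppressor TP53: from free TP53, ATP
    and a kinase, deduce phosphorylated TP53 (pTP53).

    The first rule binds kinase and ATP into a complex; the second
    phosphorylates TP53, releasing the kinase, pTP53 and ADP.  Note the
    rule reactants are *ordered*: [Kinase, ATP] is a different candidate
    than [ATP, Kinase]."""
    return ZsyntaxProblem(
        initial=[["TP53"], ["ATP"], ["Kinase"]],
        evfs=[
            EVF(("Kinase", "ATP"), (("ATP", "Kinase"),)),
            EVF(("ATP", "Kinase", "TP53"), (("Kinase",), ("pTP53",), ("ADP",))),
        ],
        target=("pTP53",),
        molecules=("TP53", "ATP", "Kinase", "ADP", "pTP53"),
    )


def csc_death_fixture() -> ZsyntaxProblem:
    """Pathway leading to the death (M) of a cancer stem cell: a CSC
    recruits a progenitor cell P and the complex dies."""
    return ZsyntaxProblem(
        initial=[["CSC"], ["P"]],
        evfs=[
            EVF(("CSC",), (("CSC", "P"),)),
            EVF(("CSC", "P"), (("M",),)),
        ],
        target=("M",),
        molecules=("CSC", "P", "M"),
    )


#: Default rate constants used when emitting kinetic fixture files.
DEFAULT_FIXTURE_PARAMS: Dict[str, SchemeParams] = {
    "scheme_01": SchemeParams({"k1": 1.0, "k2": 2.0}),
    "scheme_02": SchemeParams({"k1": 1.0, "k2": 2.0, "k3": 3.0}),
    "scheme_03": SchemeParams({"k1": 1.0, "k2": 2.0, "k3": 3.0}),
    "scheme_04": SchemeParams({"k1": 1.0, "k2": 2.0, "k3": 3.0}),
    "tumor_full": SchemeParams({"k1": 0.8, "k2": 0.4, "k3": 0.2, "k4": 0.5,
                                "k5": 0.3, "k6": 0.1, "k7": 0.15, "k8": 0.05}),
    "tumor_reduced": SchemeParams({"k1": 1.0, "k2": 0.5, "k3": 0.25}),
}
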