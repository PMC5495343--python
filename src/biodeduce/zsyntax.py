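"""Zsyntax pathway-deduction engine.

Zsyntax is a deductive language for molecular biology: molecules combine
through the (non-associative) Z-Interaction, co-present complexes form a
Z-Conjunction (an *aggregate*), and lab-validated rewrite rules — the
Empirically Valid Formulae (EVFs) — map a reactant interaction to a product
aggregate.  A deduction repeatedly picks an ordered pair of aggregate
members, concatenates them into a candidate interaction, and fires the
first EVF whose reactant equals that candidate exactly; the reactants are
consumed (stoichiometry) and the products appended.  The engine below is a
literal executable port of that recursion scheme.

Representation: a molecule is a case-sensitive token (``str``), an
interaction an ordered tuple of tokens, an aggregate an ordered tuple of
interactions.  Order is always significant — there is no implicit sorting,
deduplication or permutation matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, FrozenSet, Iterable, NamedTuple, Optional, Sequence, Union

from .errors import (
    DistinctnessViolationError,
    EmptyAggregateError,
    EmptyEvfListError,
    FixpointNotReachedError,
    IndexOutOfRangeError,
    NoTargetError,
    OracleTooLargeError,
)

logger = logging.getLogger(__name__)

Molecule = str
Interaction = tuple  # tuple[Molecule, ...]
Aggregate = tuple  # tuple[Interaction, ...]

#: Hard cap on firings in "fixpoint" mode (an EVF may fire arbitrarily often,
#: e.g. autocatalytic rules, so termination is not guaranteed).
DEFAULT_FIXPOINT_LIMIT = 1000


def as_interaction(molecules: Iterable[Molecule]) -> Interaction:
    return tuple(molecules)


def as_aggregate(interactions: Iterable[Iterable[Molecule]]) -> Aggregate:
    return tuple(tuple(i) for i in interactions)


@dataclass(frozen=True)
class EVF:
    """One empirically valid formula: ``reactants -> products``.

    ``reactants`` is a single interaction (the exact ordered candidate it
    matches); ``products`` is the aggregate appended when it fires.
    """

    reactants: Interaction
    products: Aggregate

    def __post_init__(self):
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", as_aggregate(self.products))


class DeductionOutcome(NamedTuple):
    matched: bool
    aggregate: Aggregate


class Firing(NamedTuple):
    """Trace record of one successful EVF application."""

    round: int
    x: int
    y: int
    evf_index: int
    before: Aggregate
    after: Aggregate


@dataclass
class ZsyntaxProblem:
    """A deduction problem: initial aggregate, EVFs, optional target.

    ``max_rounds`` bounds the number of firing rounds; the default
    ``len(evfs)`` mirrors the recursion bound of the formal definition,
    while ``"fixpoint"`` iterates until no EVF can fire (hard-capped by
    ``fixpoint_limit``).
    """

    initial: Aggregate
    evfs: tuple  # tuple[EVF, ...]
    target: Optional[Interaction] = None
    max_rounds: Union[int, str, None] = None
    molecules: Optional[tuple] = None  # declared molecule universe
    fixpoint_limit: int = DEFAULT_FIXPOINT_LIMIT

    def __post_init__(self):
        self.initial = as_aggregate(self.initial)
        self.evfs = tuple(
            e if isinstance(e, EVF) else EVF(e[0], e[1]) for e in self.evfs
        )
        if self.target is not None:
            self.target = tuple(self.target)
        if self.molecules is not None:
            self.molecules = tuple(self.molecules)

    def declared_molecules(self) -> tuple:
        if self.molecules is not None:
            return self.molecules
        seen: dict = {}
        for inter in self.initial:
            for m in inter:
                seen[m] = None
        for evf in self.evfs:
            for m in evf.reactants:
                seen[m] = None
            for inter in evf.products:
                for m in inter:
                    seen[m] = None
        return tuple(seen)

    def validate(self) -> None:
        """Strict validation: distinct declared molecules, known tokens,
        non-empty initial/EVF list, non-empty EVF products."""
        declared = self.declared_molecules()
        if len(set(declared)) != len(declared):
            dupes = sorted({m for m in declared if declared.count(m) > 1})
            raise DistinctnessViolationError(
                f"duplicate declared molecules: {dupes}", molecules=dupes
            )
        universe = set(declared)
        def _check(inter, where):
            for m in inter:
                if m not in universe:
                    raise DistinctnessViolationError(
                        f"undeclared molecule {m!r} in {where}", molecule=m
                    )
        if not self.initial:
            raise EmptyAggregateError("initial aggregate is empty")
        if not self.evfs:
            raise EmptyEvfListError("EVF list is empty")
        for inter in self.initial:
            _check(inter, "initial aggregate")
        for i, evf in enumerate(self.evfs):
            if not evf.reactants:
                raise EmptyAggregateError(f"EVF {i} has an empty reactant")
            if not evf.products:
                raise EmptyAggregateError(f"EVF {i} has empty products")
            _check(evf.reactants, f"EVF {i} reactants")
            for inter in evf.products:
                _check(inter, f"EVF {i} products")
        if self.target is not None:
            _check(self.target, "target")


# --------------------------------------------------------------------------
# Primitive list operations
# --------------------------------------------------------------------------

def delete_at(agg: Sequence, i: int) -> Aggregate:
    """Remove position ``i`` (0-based); relative order elsewhere preserved."""
    agg = as_aggregate(agg)
    if not 0 <= i < len(agg):
        raise IndexOutOfRangeError(f"index {i} out of range for length {len(agg)}")
    return agg[:i] + agg[i + 1:]


def delete_reactant_pair(agg: Sequence, x: int, y: int) -> Aggregate:
    """Remove positions ``x`` and ``y``, higher index first so the lower one
    stays valid.  ``x == y`` applies the literal else-branch (removing two
    elements) and logs a warning — the single-reaction law excludes it."""
    agg = as_aggregate(agg)
    n = len(agg)
    if not (0 <= x < n and 0 <= y < n):
        raise IndexOutOfRangeError(f"indices ({x}, {y}) out of range for length {n}")
    if x == y:
        logger.warning("delete_reactant_pair called with x == y == %d", x)
    if x > y:
        return delete_at(delete_at(agg, x), y)
    return delete_at(delete_at(agg, y), x)


def introduce_conjunction(agg: Sequence, x: int, y: int) -> Aggregate:
    """Prepend the concatenation of ``agg[x]`` and ``agg[y]`` as a new head."""
    agg = as_aggregate(agg)
    n = len(agg)
    if not (0 <= x < n and 0 <= y < n):
        raise IndexOutOfRangeError(f"indices ({x}, {y}) out of range for length {n}")
    return (agg[x] + agg[y],) + agg


def eliminate_conjunction(agg: Sequence, target: Iterable[Molecule]) -> Aggregate:
    """If ``target`` occurs in ``agg`` return ``(target,)``, else ``agg``."""
    agg = as_aggregate(agg)
    target = tuple(target)
    return (target,) if target in agg else agg


# --------------------------------------------------------------------------
# EVF matching and the deduction recursion
# --------------------------------------------------------------------------

def match_evf(agg_with_head: Sequence, evfs: Sequence[EVF], p: int,
              x: int, y: int) -> DeductionOutcome:
    """Match the head of ``agg_with_head`` against EVF indices p, p-1, ..., 0.

    On the first exact (order-sensitive) reactant match, the head is
    dropped, the EVF's products are appended to the tail, and the consumed
    pair (positions ``x``, ``y`` of the tail-with-products) is deleted.  If
    no index matches, returns ``(False, tail)``.
    """
    agg = as_aggregate(agg_with_head)
    if not agg:
        raise EmptyAggregateError("match_evf needs a candidate head")
    evfs = tuple(evfs)
    if not evfs:
        raise EmptyEvfListError("match_evf needs at least one EVF")
    if not 0 <= p < len(evfs):
        raise IndexOutOfRangeError(f"EVF index {p} out of range for {len(evfs)}")
    head, tail = agg[0], agg[1:]
    for idx in range(p, -1, -1):
        if evfs[idx].reactants == head:
            return DeductionOutcome(
                True, delete_reactant_pair(tail + evfs[idx].products, x, y)
            )
    return DeductionOutcome(False, tail)


def find_firing(agg: Sequence, evfs: Sequence[EVF]):
    """First firable (x, y, evf_index) in engine order, or None.

    Engine order: x descending from len(agg)-1, then y descending, EVF
    index descending (ties resolved by the *highest* matching EVF index,
    matching the recursion's initial instantiation at LENGTH-1).
    """
    agg = as_aggregate(agg)
    evfs = tuple(evfs)
    n = len(agg)
    for x in range(n - 1, -1, -1):
        for y in range(n - 1, -1, -1):
            head = agg[x] + agg[y]
            for z in range(len(evfs) - 1, -1, -1):
                if evfs[z].reactants == head:
                    return x, y, z
    return None


def scan_pairs(agg: Sequence, evfs: Sequence[EVF]) -> DeductionOutcome:
    """One round: enumerate candidate pairs (x, y) in engine order and fire
    the first EVF match; ``(False, agg)`` if no pair matches."""
    agg = as_aggregate(agg)
    if not agg:
        raise EmptyAggregateError("scan_pairs needs a non-empty aggregate")
    evfs = tuple(evfs)
    if not evfs:
        raise EmptyEvfListError("scan_pairs needs at least one EVF")
    hit = find_firing(agg, evfs)
    if hit is None:
        return DeductionOutcome(False, agg)
    x, y, _z = hit
    return match_evf(introduce_conjunction(agg, x, y), evfs, len(evfs) - 1, x, y)


def deduce(problem: ZsyntaxProblem,
           on_firing: Optional[Callable[[Firing], None]] = None) -> Aggregate:
    """Run the deduction: repeat ``scan_pairs`` until no EVF fires or the
    round bound is exhausted; returns the final aggregate.

    The default bound is ``len(evfs)``; ``max_rounds="fixpoint"`` iterates
    to quiescence (hard-capped by ``problem.fixpoint_limit``).  A warning is
    logged if the bound ran out while a further firing was still possible.
    """
    agg = as_aggregate(problem.initial)
    evfs = tuple(problem.evfs)
    if not agg:
        raise EmptyAggregateError("initial aggregate is empty")
    if not evfs:
        raise EmptyEvfListError("EVF list is empty")

    fixpoint = problem.max_rounds == "fixpoint"
    bound = problem.fixpoint_limit if fixpoint else (
        problem.max_rounds if problem.max_rounds is not None else len(evfs)
    )
    for rnd in range(bound):
        hit = find_firing(agg, evfs)
        if hit is None:
            return agg
        x, y, z = hit
        before = agg
        agg = match_evf(introduce_conjunction(agg, x, y), evfs,
                        len(evfs) - 1, x, y).aggregate
        if on_firing is not None:
            on_firing(Firing(rnd, x, y, z, before, agg))
        if not agg:
            return agg  # nothing left to pair
    if agg and find_firing(agg, evfs) is not None:
        if fixpoint:
            raise FixpointNotReachedError(
                f"no fixpoint within {bound} firings", partial=agg
            )
        logger.warning(
            "round bound %d exhausted with a firing still possible", bound
        )
    return agg


def deduce_and_check(problem: ZsyntaxProblem,
                     on_firing: Optional[Callable[[Firing], None]] = None
                     ) -> Aggregate:
    """Deduce, then apply Z-Conjunction elimination with the problem target;
    the caller checks whether the result equals ``[target]``."""
    if problem.target is None:
        raise NoTargetError("problem has no target interaction")
    return eliminate_conjunction(deduce(problem, on_firing), problem.target)


# --------------------------------------------------------------------------
# Exhaustive small-scale oracle
# --------------------------------------------------------------------------

def possible_firings(agg: Aggregate, evfs: Sequence[EVF]):
    """All (x, y, z) triples that could fire on ``agg`` (any order)."""
    evfs = tuple(evfs)
    n = len(agg)
    out = []
    for x in range(n):
        for y in range(n):
            head = agg[x] + agg[y]
            for z, evf in enumerate(evfs):
                if evf.reactants == head:
                    out.append((x, y, z))
    return out


def apply_firing(agg: Aggregate, evfs: Sequence[EVF], x: int, y: int,
                 z: int) -> Aggregate:
    """Aggregate after firing EVF ``z`` on the pair (x, y)."""
    return delete_reactant_pair(as_aggregate(agg) + tuple(evfs)[z].products, x, y)


def brute_force_fixpoint_oracle(agg: Sequence, evfs: Sequence[EVF],
                                depth: int,
                                max_states: int = 20000,
                                require_complete: bool = False
                                ) -> FrozenSet[Aggregate]:
    """Exhaustively explore every firing sequence up to ``depth`` and return
    the set of reachable aggregates on which no EVF can fire.

    Test-scale only (aggregate <= 6, EVFs <= 4, depth <= 8); raises
    ``oracle_too_large`` beyond those bounds or if the state frontier
    explodes past ``max_states``.  With ``require_complete`` the same error
    is raised when some firing chain is still live at the depth limit, i.e.
    when the returned set might miss reachable fixpoints.
    """
    agg = as_aggregate(agg)
    evfs = tuple(evfs)
    if len(agg) > 6 or len(evfs) > 4 or depth > 8:
        raise OracleTooLargeError(
            f"oracle bounds exceeded: |agg|={len(agg)}, |evfs|={len(evfs)}, "
            f"depth={depth}"
        )
    fixpoints = set()
    frontier = {agg}
    seen = {agg}
    for _ in range(depth + 1):
        nxt = set()
        for state in frontier:
            firings = possible_firings(state, evfs)
            if not firings:
                fixpoints.add(state)
                continue
            for x, y, z in firings:
                succ = apply_firing(state, evfs, x, y, z)
                if succ not in seen:
                    seen.add(succ)
                    nxt.add(succ)
                if len(seen) > max_states:
                    raise OracleTooLargeError("state space exceeds max_states")
        frontier = nxt
        if not frontier:
            break
    if frontier and require_complete:
        raise OracleTooLargeError(
            f"exploration incomplete at depth {depth}"
        )
    return frozenset(fixpoints)
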