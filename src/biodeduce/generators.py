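"""Seeded random instance generators for property testing.

Deduction instances come in three modes:

* ``no_reaction`` — no EVF reactant equals any pair-concatenation of the
  initial aggregate (including self-pairs), so the deduction is the
  identity;
* ``single_reaction`` — exactly one ordered pair (x', y'), x' != y',
  matches exactly one EVF, nothing can fire afterwards, and the
  distinctness side conditions hold, so the deduction equals the one-step
  closed form delete_reactant_pair(initial ++ products, x', y');
* ``free`` — unconstrained apart from requiring that the bounded
  exhaustive exploration of all firing orders terminates, so the
  brute-force fixpoint oracle is complete on the instance.

Everything is deterministic in the seed.  Kinetic parameters are drawn
log-uniform from [1e-2, 1e1] with assumption-violating draws rejected.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .errors import GenerationFailedError
from .models import _REQUIRED_RATES, SchemeParams, resolve_params, scheme_solution
from .zsyntax import (
    EVF,
    ZsyntaxProblem,
    as_aggregate,
    apply_firing,
    possible_firings,
)

RATE_LOW, RATE_HIGH = 1e-2, 1e1
_MAX_TRIES = 1000


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _pair_concats(agg):
    return {agg[x] + agg[y] for x in range(len(agg)) for y in range(len(agg))}


def _random_interaction(rng, pool, max_len=2):
    length = int(rng.integers(1, max_len + 1))
    return tuple(pool[i] for i in rng.integers(0, len(pool), size=length))


def _check_scale(n_molecules, n_initial, n_evfs):
    if not (1 <= n_molecules <= 8 and 1 <= n_initial <= 6 and 1 <= n_evfs <= 4):
        raise GenerationFailedError(
            "instance sizes outside test scale "
            f"({n_molecules} molecules, {n_initial} initial, {n_evfs} EVFs)"
        )


def random_zsyntax_instance(seed, n_molecules=6, n_initial=4, n_evfs=3,
                            mode="free") -> ZsyntaxProblem:
    """A deterministic random deduction problem in the given mode."""
    _check_scale(n_molecules, n_initial, n_evfs)
    rng = _rng(seed)
    pool = tuple(f"M{i}" for i in range(n_molecules))
    if mode == "no_reaction":
        return _no_reaction(rng, pool, n_initial, n_evfs)
    if mode == "single_reaction":
        return _single_reaction(rng, pool, n_initial, n_evfs)
    if mode == "free":
        return _free(rng, pool, n_initial, n_evfs)
    raise GenerationFailedError(f"unknown mode {mode!r}")


def _no_reaction(rng, pool, n_initial, n_evfs) -> ZsyntaxProblem:
    initial = as_aggregate(_random_interaction(rng, pool)
                           for _ in range(n_initial))
    forbidden = _pair_concats(initial)
    evfs = []
    for _ in range(n_evfs):
        for _try in range(_MAX_TRIES):
            reactant = _random_interaction(rng, pool, max_len=3)
            if reactant not in forbidden:
                break
        else:
            raise GenerationFailedError("no non-matching reactant found")
        products = as_aggregate(_random_interaction(rng, pool)
                                for _ in range(int(rng.integers(1, 3))))
        evfs.append(EVF(reactant, products))
    return ZsyntaxProblem(initial, tuple(evfs), molecules=pool)


def _single_reaction(rng, pool, n_initial, n_evfs) -> ZsyntaxProblem:
    """Rejection-sample until the one-firing structure holds exactly."""
    for _try in range(_MAX_TRIES):
        # distinct interactions over distinct molecules (ALL_DISTINCT side condition)
        perm = [pool[i] for i in rng.permutation(len(pool))]
        if len(perm) < n_initial + 1:
            raise GenerationFailedError("not enough molecules for distinctness")
        initial = as_aggregate([m] for m in perm[:n_initial])
        leftovers = perm[n_initial:]
        x, y = rng.choice(n_initial, size=2, replace=False)
        x, y = int(x), int(y)
        matched_reactant = initial[x] + initial[y]
        products = as_aggregate([[m] for m in leftovers[:1 + int(rng.integers(0, min(2, len(leftovers))))]])
        z = int(rng.integers(0, n_evfs))
        evfs: list = []
        ok = True
        for j in range(n_evfs):
            if j == z:
                evfs.append(EVF(matched_reactant, products))
                continue
            for _inner in range(_MAX_TRIES):
                reactant = _random_interaction(rng, pool, max_len=3)
                if reactant != matched_reactant and all(
                        e.reactants != reactant for e in evfs if e is not None):
                    break
            else:
                ok = False
                break
            evfs.append(EVF(reactant, products))
        if not ok:
            continue
        # distinct EVF reactants (A9)
        if len({e.reactants for e in evfs}) != n_evfs:
            continue
        # exactly one firing on the initial aggregate, at (x, y, z)
        if possible_firings(initial, evfs) != [(x, y, z)]:
            continue
        # nothing fires afterwards
        after = apply_firing(initial, evfs, x, y, z)
        if possible_firings(after, evfs):
            continue
        return ZsyntaxProblem(initial, tuple(evfs), molecules=pool)
    raise GenerationFailedError("single_reaction generation budget exhausted")


def _firing_graph_terminates(initial, evfs, depth) -> bool:
    """True when every firing sequence from ``initial`` reaches a fixpoint
    within ``depth`` steps — i.e. the reachable firing graph is acyclic and
    no chain outruns the depth (cycles hide from a plain frontier check
    because revisited states are deduplicated)."""
    safe = set()       # states from which all chains terminate within budget
    on_path = set()

    def visit(state, budget):
        if state in safe:
            return True
        if budget < 0 or state in on_path:
            return False
        firings = possible_firings(state, evfs)
        if firings:
            on_path.add(state)
            try:
                for x, y, z in firings:
                    if not visit(apply_firing(state, evfs, x, y, z), budget - 1):
                        return False
            finally:
                on_path.discard(state)
        safe.add(state)
        return True

    return visit(initial, depth)


def _free(rng, pool, n_initial, n_evfs, depth=6) -> ZsyntaxProblem:
    for _try in range(_MAX_TRIES):
        initial = as_aggregate(_random_interaction(rng, pool)
                               for _ in range(n_initial))
        concats = sorted(_pair_concats(initial))
        evfs = []
        for _ in range(n_evfs):
            if concats and rng.random() < 0.6:
                reactant = concats[int(rng.integers(0, len(concats)))]
            else:
                reactant = _random_interaction(rng, pool, max_len=3)
            products = as_aggregate(_random_interaction(rng, pool)
                                    for _ in range(int(rng.integers(1, 3))))
            evfs.append(EVF(reactant, products))
        if not _firing_graph_terminates(initial, evfs, depth):
            continue
        return ZsyntaxProblem(initial, tuple(evfs), molecules=pool)
    raise GenerationFailedError("free-mode generation budget exhausted")


def random_kinetic_params(seed, scheme_id) -> SchemeParams:
    """Log-uniform rate draw on [1e-2, 1e1]; draws violating the scheme's
    validity assumptions are rejected and resampled (up to 1000 times)."""
    rng = _rng(seed)
    names = _REQUIRED_RATES.get(scheme_id)
    if names is None:
        from .errors import UnknownSchemeError
        raise UnknownSchemeError(f"unknown scheme {scheme_id!r}")
    lo, hi = np.log10(RATE_LOW), np.log10(RATE_HIGH)
    for _try in range(_MAX_TRIES):
        rates = {n: float(10.0 ** rng.uniform(lo, hi)) for n in names}
        params = SchemeParams(rates)
        try:
            params = resolve_params(scheme_id, params)
            scheme_solution(scheme_id, params)  # assumption check
        except Exception:
            continue
        return params
    raise GenerationFailedError("kinetic parameter rejection budget exhausted")
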