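"""Strict readers/writers for the JSON problem/model dialects and CSV
trajectories.

Both dialects carry ``"format_version": 1``.  Validation is strict:
unknown keys, unknown molecule/species tokens and malformed entries are
errors, with a JSON-pointer-style path in the message.  Writers use a
canonical key order and UNIX newlines so that write/read round-trips are
byte-identical.
"""

from __future__ import annotations

import csv
import json
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import (
    InvalidProblemFileError,
    InvalidReactionError,
    IoError,
    UnknownSpeciesError,
)
from .kinetics import (
    IRREVERSIBLE,
    REVERSIBLE,
    KineticModel,
    Reaction,
    ReactionTerm,
    Trajectory,
)
from .zsyntax import EVF, ZsyntaxProblem

FORMAT_VERSION = 1


def _fail(pointer: str, message: str):
    raise InvalidProblemFileError(f"{pointer}: {message}", pointer=pointer)


def _expect_keys(obj: dict, allowed, required, pointer: str):
    unknown = set(obj) - set(allowed)
    if unknown:
        _fail(pointer, f"unknown keys {sorted(unknown)}")
    missing = set(required) - set(obj)
    if missing:
        _fail(pointer, f"missing keys {sorted(missing)}")


def _string_list(value, pointer: str) -> List[str]:
    if not isinstance(value, list) or not all(
            isinstance(s, str) and s for s in value):
        _fail(pointer, "expected an array of non-empty strings")
    return list(value)


def _check_version(obj: dict, pointer: str):
    if "format_version" in obj and obj["format_version"] != FORMAT_VERSION:
        _fail(pointer + "/format_version",
              f"unsupported version {obj['format_version']!r}")


# --------------------------------------------------------------------------
# Zsyntax problems
# --------------------------------------------------------------------------

def read_zsyntax_problem(path) -> ZsyntaxProblem:
    try:
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
    except OSError as exc:
        raise IoError(str(exc)) from exc
    except json.JSONDecodeError as exc:
        raise InvalidProblemFileError(f"not valid JSON: {exc}") from exc
    if not isinstance(obj, dict):
        _fail("", "top level must be an object")
    _expect_keys(obj, {"format_version", "molecules", "initial", "evfs",
                       "target", "max_rounds"},
                 {"molecules", "initial", "evfs"}, "")
    _check_version(obj, "")
    molecules = _string_list(obj["molecules"], "/molecules")

    def aggregate(value, pointer):
        if not isinstance(value, list):
            _fail(pointer, "expected an array of interactions")
        return tuple(tuple(_string_list(inter, f"{pointer}/{i}"))
                     for i, inter in enumerate(value))

    initial = aggregate(obj["initial"], "/initial")
    if not isinstance(obj["evfs"], list):
        _fail("/evfs", "expected an array")
    evfs = []
    for i, entry in enumerate(obj["evfs"]):
        if not isinstance(entry, dict):
            _fail(f"/evfs/{i}", "expected an object")
        _expect_keys(entry, {"reactants", "products"},
                     {"reactants", "products"}, f"/evfs/{i}")
        reactants = tuple(_string_list(entry["reactants"], f"/evfs/{i}/reactants"))
        products = aggregate(entry["products"], f"/evfs/{i}/products")
        if not products:
            _fail(f"/evfs/{i}/products", "must be non-empty")
        evfs.append(EVF(reactants, products))

    target = None
    if obj.get("target") is not None:
        target = tuple(_string_list(obj["target"], "/target"))
    max_rounds = obj.get("max_rounds")
    if max_rounds is not None and max_rounds != "fixpoint" and not (
            isinstance(max_rounds, int) and max_rounds > 0):
        _fail("/max_rounds", 'expected a positive integer or "fixpoint"')

    problem = ZsyntaxProblem(initial, tuple(evfs), target=target,
                             max_rounds=max_rounds, molecules=tuple(molecules))
    problem.validate()  # distinctness + token universe
    return problem


def write_zsyntax_problem(problem: ZsyntaxProblem, path) -> None:
    obj = {
        "format_version": FORMAT_VERSION,
        "molecules": list(problem.declared_molecules()),
        "initial": [list(i) for i in problem.initial],
        "evfs": [{"reactants": list(e.reactants),
                  "products": [list(i) for i in e.products]}
                 for e in problem.evfs],
    }
    if problem.target is not None:
        obj["target"] = list(problem.target)
    if problem.max_rounds is not None:
        obj["max_rounds"] = problem.max_rounds
    _dump_json(obj, path)


# --------------------------------------------------------------------------
# Kinetic models
# --------------------------------------------------------------------------

def read_kinetic_model(path) -> KineticModel:
    """Read a kinetic model file; sparse reaction terms are expanded to
    full species-order vectors and concentrations bound from "initial"."""
    try:
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
    except OSError as exc:
        raise IoError(str(exc)) from exc
    except json.JSONDecodeError as exc:
        raise InvalidProblemFileError(f"not valid JSON: {exc}") from exc
    if not isinstance(obj, dict):
        _fail("", "top level must be an object")
    _expect_keys(obj, {"format_version", "species", "reactions", "initial"},
                 {"species", "reactions", "initial"}, "")
    _check_version(obj, "")
    species = _string_list(obj["species"], "/species")
    if len(set(species)) != len(species):
        _fail("/species", "duplicate species names")
    index = {s: i for i, s in enumerate(species)}

    if not isinstance(obj["initial"], dict):
        _fail("/initial", "expected an object mapping species to floats")
    initial = [0.0] * len(species)
    for name, value in obj["initial"].items():
        if name not in index:
            raise UnknownSpeciesError(f"/initial: unknown species {name!r}")
        if not isinstance(value, (int, float)):
            _fail(f"/initial/{name}", "expected a number")
        initial[index[name]] = float(value)

    def terms(entries, pointer):
        stoich = [0] * len(species)
        if not isinstance(entries, list):
            _fail(pointer, "expected an array of {species, stoich}")
        for j, term in enumerate(entries):
            if not isinstance(term, dict):
                _fail(f"{pointer}/{j}", "expected an object")
            _expect_keys(term, {"species", "stoich"},
                         {"species", "stoich"}, f"{pointer}/{j}")
            name = term["species"]
            if name not in index:
                raise UnknownSpeciesError(
                    f"{pointer}/{j}: unknown species {name!r}")
            if not isinstance(term["stoich"], int) or term["stoich"] < 0:
                _fail(f"{pointer}/{j}/stoich", "expected a non-negative integer")
            stoich[index[name]] = term["stoich"]
        return tuple(ReactionTerm(s, c) for s, c in zip(stoich, initial))

    if not isinstance(obj["reactions"], list) or not obj["reactions"]:
        _fail("/reactions", "expected a non-empty array")
    reactions = []
    for i, entry in enumerate(obj["reactions"]):
        if not isinstance(entry, dict):
            _fail(f"/reactions/{i}", "expected an object")
        _expect_keys(entry, {"type", "reactants", "products", "kf", "kr"},
                     {"type", "reactants", "products", "kf"}, f"/reactions/{i}")
        kind = entry["type"]
        if kind not in (IRREVERSIBLE, REVERSIBLE):
            _fail(f"/reactions/{i}/type",
                  f'expected "{IRREVERSIBLE}" or "{REVERSIBLE}"')
        kr = entry.get("kr", 0.0)
        if kind == IRREVERSIBLE and kr != 0:
            raise InvalidReactionError(
                f"/reactions/{i}: irreversible reaction with kr != 0")
        reactions.append(Reaction(
            kind,
            terms(entry["reactants"], f"/reactions/{i}/reactants"),
            terms(entry["products"], f"/reactions/{i}/products"),
            float(entry["kf"]), float(kr),
        ))
    return KineticModel(tuple(species), tuple(reactions))


def write_kinetic_model(model: KineticModel, path) -> None:
    """Emit the sparse dialect (zero-stoich terms omitted)."""
    def sparse(terms):
        return [{"species": s, "stoich": t.stoich}
                for s, t in zip(model.species, terms) if t.stoich]
    obj = {
        "format_version": FORMAT_VERSION,
        "species": list(model.species),
        "reactions": [{"type": r.kind,
                       "reactants": sparse(r.reactants),
                       "products": sparse(r.products),
                       "kf": r.k_f,
                       "kr": r.k_r}
                      for r in model.reactions],
        "initial": {s: c for s, c in zip(model.species, model.state())},
    }
    _dump_json(obj, path)


# --------------------------------------------------------------------------
# Trajectories
# --------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    """CSV with header ``t,<species...>``; ``repr`` floats (round-trip to
    <= 1 ulp), UNIX newlines."""
    try:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["t", *traj.species])
            for t, row in zip(traj.t, traj.y):
                writer.writerow([repr(float(t)), *(repr(float(v)) for v in row)])
    except OSError as exc:
        raise IoError(str(exc)) from exc


def read_trajectory(path) -> Trajectory:
    try:
        with open(path, encoding="utf-8", newline="") as fh:
            rows = list(csv.reader(fh))
    except OSError as exc:
        raise IoError(str(exc)) from exc
    if not rows or rows[0][:1] != ["t"]:
        raise InvalidProblemFileError("trajectory CSV must start with a 't' header")
    species = tuple(rows[0][1:])
    data = [[float(v) for v in row] for row in rows[1:]]
    arr = np.array(data, dtype=float).reshape(-1, len(species) + 1)
    return Trajectory(arr[:, 0], arr[:, 1:], species)


def _dump_json(obj, path) -> None:
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(obj, fh, indent=2)
            fh.write("\n")
    except OSError as exc:
        raise IoError(str(exc)) from exc
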