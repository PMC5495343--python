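"""Unit and property tests for the pathway-deduction engine."""

import logging

import pytest
from hypothesis import given, settings, strategies as st

from biodeduce import (
    EVF,
    ZsyntaxProblem,
    brute_force_fixpoint_oracle,
    deduce,
    deduce_and_check,
    delete_at,
    delete_reactant_pair,
    eliminate_conjunction,
    introduce_conjunction,
    match_evf,
    scan_pairs,
)
from biodeduce.errors import (
    DistinctnessViolationError,
    EmptyAggregateError,
    EmptyEvfListError,
    FixpointNotReachedError,
    IndexOutOfRangeError,
    NoTargetError,
    OracleTooLargeError,
)
from biodeduce.zsyntax import as_aggregate, find_firing

A = as_aggregate


# ------------------------------------------------------------- primitives

@pytest.mark.parametrize("agg, i, expected", [
    ([["A"], ["B"], ["C"]], 0, [["B"], ["C"]]),          # head removal = tail
    ([["A"]], 0, []),
    ([["A"], ["B"], ["C"]], 1, [["A"], ["C"]]),
])
def test_delete_at(agg, i, expected):
    assert delete_at(agg, i) == A(expected)


def test_delete_at_out_of_range():
    with pytest.raises(IndexOutOfRangeError):
        delete_at([["A"]], 1)
    with pytest.raises(IndexOutOfRangeError):
        delete_at([["A"]], -1)


@pytest.mark.parametrize("agg, x, y, expected", [
    ([["A"], ["B"], ["C"]], 2, 0, [["B"]]),
    ([["A"], ["B"], ["C"]], 0, 2, [["B"]]),
    ([["TP53"], ["ATP"], ["Kinase"], ["ATP", "Kinase"]], 2, 1,
     [["TP53"], ["ATP", "Kinase"]]),
])
def test_delete_reactant_pair(agg, x, y, expected):
    assert delete_reactant_pair(agg, x, y) == A(expected)


def test_delete_reactant_pair_self_pair_warns(caplog):
    # the literal else-branch removes two elements even when x == y
    logging.getLogger("biodeduce.zsyntax").setLevel(logging.WARNING)
    with caplog.at_level(logging.WARNING, logger="biodeduce.zsyntax"):
        out = delete_reactant_pair([["A"], ["B"], ["C"]], 1, 1)
    assert out == A([["A"]])
    assert any("x == y" in r.message for r in caplog.records)


@pytest.mark.parametrize("agg, x, y, expected", [
    ([["Kinase"], ["ATP"]], 0, 1, [["Kinase", "ATP"], ["Kinase"], ["ATP"]]),
    ([["A"]], 0, 0, [["A", "A"], ["A"]]),
    ([["TP53"], ["ATP"], ["Kinase"]], 2, 1,
     [["Kinase", "ATP"], ["TP53"], ["ATP"], ["Kinase"]]),
])
def test_introduce_conjunction(agg, x, y, expected):
    assert introduce_conjunction(agg, x, y) == A(expected)


@pytest.mark.parametrize("agg, target, expected", [
    ([["Kinase"], ["pTP53"], ["ADP"]], ["pTP53"], [["pTP53"]]),
    ([["A"], ["B"]], ["C"], [["A"], ["B"]]),
    ([["M"]], ["M"], [["M"]]),
])
def test_eliminate_conjunction(agg, target, expected):
    assert eliminate_conjunction(agg, target) == A(expected)


@given(st.lists(st.lists(st.sampled_from("abcd"), min_size=1, max_size=3),
                min_size=1, max_size=5),
       st.data())
@settings(derandomize=True, max_examples=60, deadline=None)
def test_delete_at_keeps_other_elements(agg, data):
    agg = A(agg)
    i = data.draw(st.integers(0, len(agg) - 1))
    out = delete_at(agg, i)
    assert len(out) == len(agg) - 1
    assert out == agg[:i] + agg[i + 1:]


@given(st.lists(st.lists(st.sampled_from("abcd"), min_size=1, max_size=3),
                min_size=1, max_size=5),
       st.data())
@settings(derandomize=True, max_examples=60, deadline=None)
def test_introduce_conjunction_head_and_shift(agg, data):
    agg = A(agg)
    x = data.draw(st.integers(0, len(agg) - 1))
    y = data.draw(st.integers(0, len(agg) - 1))
    out = introduce_conjunction(agg, x, y)
    assert out[0] == agg[x] + agg[y]
    assert out[1:] == agg


# ----------------------------------------------------------- EVF matching

TP53_EVFS = (
    EVF(("Kinase", "ATP"), (("ATP", "Kinase"),)),
    EVF(("ATP", "Kinase", "TP53"), (("Kinase",), ("pTP53",), ("ADP",))),
)
CSC_EVFS = (
    EVF(("CSC",), (("CSC", "P"),)),
    EVF(("CSC", "P"), (("M",),)),
)


def test_match_evf_firing_consumes_reactants():
    # head [Kinase, ATP] matches the complex-formation rule; the consumed
    # free kinase and ATP (tail positions 2 and 1) are deleted
    out = match_evf(A([["Kinase", "ATP"], ["TP53"], ["ATP"], ["Kinase"]]),
                    TP53_EVFS, 1, 2, 1)
    assert out.matched is True
    assert out.aggregate == A([["TP53"], ["ATP", "Kinase"]])


def test_match_evf_failure_returns_tail():
    out = match_evf(A([["P", "P"], ["CSC"], ["P"]]), CSC_EVFS, 1, 1, 1)
    assert out == (False, A([["CSC"], ["P"]]))
    out = match_evf(A([["X"]]), CSC_EVFS, 0, 0, 0)
    assert out == (False, ())


def test_match_evf_errors():
    with pytest.raises(EmptyAggregateError):
        match_evf([], TP53_EVFS, 0, 0, 0)
    with pytest.raises(EmptyEvfListError):
        match_evf([["X"]], [], 0, 0, 0)
    with pytest.raises(IndexOutOfRangeError):
        match_evf([["X"]], TP53_EVFS, 5, 0, 0)


def test_scan_pairs_first_match_in_descending_order():
    out = scan_pairs(A([["TP53"], ["ATP"], ["Kinase"]]), TP53_EVFS)
    assert out == (True, A([["TP53"], ["ATP", "Kinase"]]))
    out = scan_pairs(A([["CSC"], ["P"]]), CSC_EVFS)
    assert out == (True, A([["M"]]))


def test_scan_pairs_no_match_is_identity():
    agg = A([["A"], ["B"]])
    assert scan_pairs(agg, CSC_EVFS) == (False, agg)


# -------------------------------------------------------------- deduction

def test_deduce_tp53_two_firings(tp53_problem):
    firings = []
    final = deduce(tp53_problem, on_firing=firings.append)
    assert final == A([["Kinase"], ["pTP53"], ["ADP"]])
    assert len(firings) == 2
    # stoichiometric bookkeeping: each firing changes length by |products| - 2
    for f in firings:
        delta = len(f.after) - len(f.before)
        assert delta == len(tp53_problem.evfs[f.evf_index].products) - 2


def test_deduce_and_check_reaches_targets(tp53_problem, csc_problem):
    assert deduce_and_check(tp53_problem) == A([["pTP53"]])
    assert deduce_and_check(csc_problem) == A([["M"]])


def test_deduce_without_match_is_identity():
    problem = ZsyntaxProblem([["A"], ["B"]], CSC_EVFS)
    assert deduce(problem) == A([["A"], ["B"]])


def test_deduce_and_check_requires_target():
    problem = ZsyntaxProblem([["A"], ["B"]], CSC_EVFS)
    with pytest.raises(NoTargetError):
        deduce_and_check(problem)


def test_deduce_fixpoint_mode_detects_divergence():
    # [A] + [A] -> regenerates two copies of [A]: fires forever
    evfs = (EVF(("A", "A"), (("A",), ("A",))),)
    problem = ZsyntaxProblem([["A"], ["A"]], evfs, max_rounds="fixpoint",
                             fixpoint_limit=10)
    with pytest.raises(FixpointNotReachedError) as exc:
        deduce(problem)
    assert exc.value.partial is not None


def test_deduce_fixpoint_result_admits_no_firing(tp53_problem):
    tp53_problem.max_rounds = "fixpoint"
    final = deduce(tp53_problem)
    assert find_firing(final, tp53_problem.evfs) is None
    assert scan_pairs(final, tp53_problem.evfs).matched is False


# ----------------------------------------------------------------- oracle

def test_oracle_unique_fixpoints(tp53_problem, csc_problem):
    assert brute_force_fixpoint_oracle(tp53_problem.initial,
                                       tp53_problem.evfs, 5) == \
        frozenset({A([["Kinase"], ["pTP53"], ["ADP"]])})
    assert A([["M"]]) in brute_force_fixpoint_oracle(
        csc_problem.initial, csc_problem.evfs, 5)


def test_oracle_no_firings_returns_input():
    agg = A([["A"], ["B"]])
    assert brute_force_fixpoint_oracle(agg, CSC_EVFS, 4) == frozenset({agg})


def test_oracle_rejects_large_instances():
    agg = A([["A"]] * 7)
    with pytest.raises(OracleTooLargeError):
        brute_force_fixpoint_oracle(agg, CSC_EVFS, 4)


# ------------------------------------------------------------- validation

def test_validate_rejects_duplicate_molecules():
    problem = ZsyntaxProblem([["A"]], CSC_EVFS, molecules=("A", "CSC", "CSC",
                                                           "P", "M"))
    with pytest.raises(DistinctnessViolationError):
        problem.validate()


def test_validate_rejects_undeclared_tokens():
    problem = ZsyntaxProblem([["A"], ["X"]], CSC_EVFS,
                             molecules=("A", "CSC", "P", "M"))
    with pytest.raises(DistinctnessViolationError):
        problem.validate()


def test_validate_rejects_empty_products():
    problem = ZsyntaxProblem([["A"]], (EVF(("A",), ()),), molecules=("A",))
    with pytest.raises(EmptyAggregateError):
        problem.validate()


def test_fixtures_pass_validation(tp53_problem, csc_problem):
    tp53_problem.validate()
    csc_problem.validate()
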