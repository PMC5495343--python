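"""Unit and property tests for the mass-action kinetics machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biodeduce import (
    KineticModel,
    Reaction,
    ReactionTerm,
    SchemeParams,
    build_scheme,
    default_grid,
    differentiate_solutions,
    evaluate_solution,
    flux_irreversible,
    flux_reversible,
    flux_vector,
    mass_action_product,
    ode_rhs,
    perturbed,
    reaction_flux,
    scheme_builder,
    scheme_solution,
    simulate,
    stoich_column,
    stoich_matrix,
    verify_solution,
    with_state,
)
from biodeduce.errors import (
    InvalidReactionError,
    NegativeRateError,
    SingularParametersError,
    SpeciesMismatchError,
    UnboundParameterError,
)

RT = ReactionTerm


# ----------------------------------------------------------------- fluxes

@pytest.mark.parametrize("terms, expected", [
    ([], 1.0),
    ([RT(1, 2.0), RT(0, 99.0)], 2.0),
    ([RT(2, 3.0), RT(1, 4.0)], 36.0),
])
def test_mass_action_product(terms, expected):
    assert mass_action_product(terms) == pytest.approx(expected)


@given(st.lists(st.tuples(st.integers(0, 3),
                          st.floats(0.01, 10.0)), max_size=4),
       st.lists(st.tuples(st.integers(0, 3),
                          st.floats(0.01, 10.0)), max_size=4))
@settings(derandomize=True, max_examples=60, deadline=None)
def test_mass_action_product_multiplicative(a, b):
    a = [RT(*t) for t in a]
    b = [RT(*t) for t in b]
    assert mass_action_product(a + b) == pytest.approx(
        mass_action_product(a) * mass_action_product(b), rel=1e-12)


def test_flux_irreversible_first_order():
    assert flux_irreversible([RT(1, 2.0)], [RT(1, 0.0)], 0.5) == pytest.approx(1.0)
    assert flux_irreversible([RT(0, 5.0)], [], 3.0) == pytest.approx(3.0)
    assert flux_irreversible([RT(1, 3.0)], [], 0.0) == 0.0
    with pytest.raises(NegativeRateError):
        flux_irreversible([RT(1, 1.0)], [], -1.0)


def test_flux_reversible_net():
    assert flux_reversible([RT(1, 3.0)], [RT(1, 4.0)], 2.0, 1.0) == pytest.approx(2.0)
    assert flux_reversible([RT(1, 3.0)], [RT(1, 4.0)], 2.0, 0.0) == \
        flux_irreversible([RT(1, 3.0)], [RT(1, 4.0)], 2.0)
    # detailed balance at equal concentrations, equal rates
    assert flux_reversible([RT(1, 5.0)], [RT(1, 5.0)], 2.0, 2.0) == pytest.approx(0.0)


def test_reaction_flux_dispatch():
    irr = Reaction("irreversible", (RT(1, 1.0), RT(0, 0.0)),
                   (RT(0, 1.0), RT(1, 0.0)), 1.0)
    assert reaction_flux(irr) == pytest.approx(1.0)
    rev = Reaction("reversible", (RT(1, 1.0), RT(0, 0.0)),
                   (RT(0, 1.0), RT(1, 0.0)), 2.0, 3.0)
    assert reaction_flux(rev) == pytest.approx(2.0)  # product side at zero
    with pytest.raises(InvalidReactionError):
        Reaction("irreversible", (RT(1, 1.0),), (RT(1, 1.0),), 1.0, 0.5)


def test_flux_vector_matches_hand_assembly():
    params = SchemeParams({"k1": 1.0, "k2": 2.0})
    model = build_scheme("scheme_01", params, (0.5, 0.25, 0.0))
    assert flux_vector(model) == pytest.approx([1.0 * 0.5, 2.0 * 0.25])
    tr = build_scheme("tumor_reduced", SchemeParams({"k1": 1.0, "k2": 0.5,
                                                     "k3": 0.25}),
                      (2.0, 4.0, 0.0))
    assert flux_vector(tr) == pytest.approx([2.0, 1.0, 1.0])


# ---------------------------------------------------------- stoichiometry

def test_stoich_column_examples():
    # A -> B over species (A, B, C)
    assert stoich_column([RT(1, 0), RT(0, 0), RT(0, 0)],
                         [RT(0, 0), RT(1, 0), RT(0, 0)]) == [-1, 1, 0]
    # CSC -> 2 CSC over (CSC, P, D, M)
    assert stoich_column([RT(1, 0), RT(0, 0), RT(0, 0), RT(0, 0)],
                         [RT(2, 0), RT(0, 0), RT(0, 0), RT(0, 0)]) == [1, 0, 0, 0]
    assert stoich_column([RT(1, 0)], [RT(1, 0)]) == [0]
    with pytest.raises(SpeciesMismatchError):
        stoich_column([RT(1, 0)], [RT(1, 0), RT(0, 0)])


def test_stoich_matrix_reaction_major():
    model = build_scheme("scheme_01", SchemeParams({"k1": 1.0, "k2": 2.0}),
                         (1.0, 0.0, 0.0))
    assert stoich_matrix(model) == [[-1, 1, 0], [0, -1, 1]]
    tr = build_scheme("tumor_reduced", SchemeParams({"k1": 1.0, "k2": 0.5,
                                                     "k3": 0.25}),
                      (1.0, 0.0, 0.0))
    assert stoich_matrix(tr) == [[0, 1, 0], [-1, 0, 1], [0, -1, 1]]


def test_self_loop_column_is_zero():
    loop = KineticModel(("X",), (Reaction("irreversible",
                                          (RT(1, 1.0),), (RT(1, 1.0),), 1.0),))
    assert stoich_matrix(loop) == [[0]]
    assert ode_rhs(loop) == [0]


# ----------------------------------------------------------- ODE assembly

def test_ode_rhs_scheme_01():
    a, b = 0.7, 0.3
    model = build_scheme("scheme_01", SchemeParams({"k1": 1.0, "k2": 2.0}),
                         (a, b, 0.1))
    assert ode_rhs(model) == pytest.approx([-a, a - 2 * b, 2 * b])


def test_ode_rhs_zero_state_vanishes():
    model = build_scheme("tumor_full",
                         SchemeParams({f"k{i}": 0.5 for i in range(1, 9)}),
                         (0.0, 0.0, 0.0, 0.0))
    assert ode_rhs(model) == pytest.approx([0.0] * 4)


def test_ode_rhs_linear_in_rates():
    state = (0.4, 0.3, 0.2)
    p1 = SchemeParams({"k1": 1.0, "k2": 2.0})
    p2 = SchemeParams({"k1": 3.0, "k2": 6.0})
    r1 = ode_rhs(build_scheme("scheme_01", p1, state))
    r2 = ode_rhs(build_scheme("scheme_01", p2, state))
    assert r2 == pytest.approx([3 * v for v in r1])


def test_with_state_rebinds_all_terms():
    model = build_scheme("scheme_01", SchemeParams({"k1": 1.0, "k2": 2.0}),
                         (1.0, 0.0, 0.0))
    moved = with_state(model, (0.0, 1.0, 0.0))
    assert moved.state() == (0.0, 1.0, 0.0)
    assert flux_vector(moved) == pytest.approx([0.0, 2.0])


# ------------------------------------------------- closed-form machinery

def test_differentiate_solutions_structural():
    sol = scheme_solution("scheme_01", SchemeParams({"k1": 2.0, "k2": 5.0}))
    dA = differentiate_solutions(sol, 0.0)[0]
    assert float(dA) == pytest.approx(-2.0)  # d/dt A0 e^{-k1 t} at 0 = -k1 A0


def test_differentiate_solutions_derivative_only_entry():
    # dead-cell balance at t = 0 with unit CSC and empty P, D pools: k6
    params = SchemeParams({"k1": 0.8, "k2": 0.4, "k3": 0.2, "k4": 0.5,
                           "k5": 0.3, "k6": 0.1, "k7": 0.15, "k8": 0.05})
    sol = scheme_solution("tumor_full", params)
    dM = differentiate_solutions(sol, 0.0)[-1]
    assert float(dM) == pytest.approx(0.1)


def test_verify_solution_passes_and_is_sensitive():
    params = SchemeParams({"k1": 1.0, "k2": 2.0})
    builder = scheme_builder("scheme_01", params)
    sol = scheme_solution("scheme_01", params)
    report = verify_solution(builder, sol, tol=1e-8)
    assert report.passed
    assert max(report.max_abs_residual.values()) <= 1e-8
    bad = verify_solution(builder, perturbed(sol, "B"), tol=1e-8)
    assert not bad.passed


def test_verify_solution_rejects_singular_parameters():
    with pytest.raises(SingularParametersError):
        scheme_solution("scheme_01", SchemeParams({"k1": 1.0, "k2": 1.0}))
    with pytest.raises(SingularParametersError):
        scheme_solution("tumor_reduced",
                        SchemeParams({"k1": 1.0, "k2": 0.5, "k3": 0.5}))


def test_unbound_parameter_is_rejected():
    import sympy as sp
    from biodeduce.kinetics import (CONCENTRATION, ClosedFormSolution,
                                    SolutionEntry, T)
    with pytest.raises(UnboundParameterError):
        ClosedFormSolution(("X",),
                           {"X": SolutionEntry(CONCENTRATION,
                                               sp.Symbol("mystery") * T)},
                           (), {})


# ------------------------------------------------------------- simulation

def test_simulate_matches_closed_form_scheme_01():
    params = SchemeParams({"k1": 1.0, "k2": 2.0})
    sol = scheme_solution("scheme_01", params)
    traj = simulate(scheme_builder("scheme_01", params), (1.0, 0.0, 0.0),
                    10.0, rtol=1e-10, atol=1e-12, n_out=40)
    for i, t in enumerate(traj.t):
        ref = {k: float(v) for k, v in evaluate_solution(sol, float(t)).items()}
        for j, s in enumerate(traj.species):
            assert traj.y[i, j] == pytest.approx(ref[s], rel=1e-6, abs=1e-9)


def test_simulate_conserves_total_for_consecutive_schemes():
    params = SchemeParams({"k1": 1.0, "k2": 2.0, "k3": 3.0})
    traj = simulate(scheme_builder("scheme_03", params), (1.0, 0.0, 0.0),
                    10.0, rtol=1e-10, atol=1e-12)
    totals = traj.y.sum(axis=1)
    assert np.allclose(totals, 1.0, atol=1e-8)


def test_simulate_zero_initial_stays_zero():
    params = SchemeParams({"k1": 1.0, "k2": 2.0})
    traj = simulate(scheme_builder("scheme_01", params), (0.0, 0.0, 0.0), 5.0)
    assert np.allclose(traj.y, 0.0)
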