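"""Unit and property tests for the mass-action engine."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings, strategies as st

from coagsim import (
    CompartmentParams,
    MassActionReaction,
    NetworkError,
    ReactionNetwork,
    SpeciesDecl,
    SteadyStateError,
    build_compartment_network,
    build_rhs,
    conserved_totals,
    find_steady_state,
    integrate,
)
from coagsim.compartment import SPECIES_ORDER
from coagsim.synthetic import ToyBindingSpec, make_toy_binding


def test_single_reaction_rhs_hand_value():
    """C + TFPIα at (4, 2.5, 0) nM loses concizumab at 0.0448 nM/s."""
    net = ReactionNetwork(
        [SpeciesDecl("C", initial_conc=4.0),
         SpeciesDecl("TFPIa", initial_conc=2.5),
         SpeciesDecl("C:TFPIa")],
        [MassActionReaction.from_molar(
            "C1", [("C", 1), ("TFPIa", 1)], [("C:TFPIa", 1)], 4.48e6, 1e-4)],
    )
    rhs = build_rhs(net)
    dy = rhs(0.0, np.array([4.0, 2.5, 0.0]))
    assert dy[0] == pytest.approx(-4.48e-2, rel=1e-12)
    assert dy[2] == pytest.approx(+4.48e-2, rel=1e-12)


def test_empty_network_zero_derivative():
    net = ReactionNetwork([SpeciesDecl("X", initial_conc=3.0)], [])
    rhs = build_rhs(net)
    assert np.allclose(rhs(0.0, np.array([7.0])), 0.0)


def test_undeclared_species_raises_with_name():
    with pytest.raises(NetworkError, match="ghost"):
        ReactionNetwork(
            [SpeciesDecl("A")],
            [MassActionReaction("r", (("A", 1),), (("ghost", 1),), 1.0)],
        )


def test_compartment_rhs_matches_symbolic_oracle():
    """Full five-reaction network against independently written sympy ODEs.

    The symbolic system is constructed directly from the reaction
    semantics (not via the package), including the concizumab balance with
    its two loss and two gain terms.
    """
    ka, kb, koff = 4.48e6 * 1e-9, 8.21e5 * 1e-9, 1e-4
    C, Ta, Tb, CTa, TaCTa, CTb, TaCTb = sp.symbols(
        "C Ta Tb CTa TaCTa CTb TaCTb", nonnegative=True)
    r1 = ka * C * Ta - koff * CTa
    r2 = ka * CTa * Ta - koff * TaCTa
    r3 = kb * C * Tb - koff * CTb
    r4 = kb * CTa * Tb - koff * TaCTb
    r5 = ka * Ta * CTb - koff * TaCTb
    exprs = [-r1 - r3, -r1 - r2 - r5, -r3 - r4, r1 - r2 - r4, r2, r3 - r5, r4 + r5]
    # the concizumab balance has exactly 2 loss and 2 gain terms
    dC = sp.expand(exprs[0])
    assert len(dC.args) == 4
    f = sp.lambdify((C, Ta, Tb, CTa, TaCTa, CTb, TaCTb), exprs, "numpy")

    net = build_compartment_network(CompartmentParams(dose=21.5))
    rhs = build_rhs(net)
    rng = np.random.default_rng(42)
    for _ in range(20):
        y = rng.uniform(0.0, 20.0, size=7)
        np.testing.assert_allclose(rhs(0.0, y), f(*y), rtol=1e-10, atol=1e-16)


def test_toy_binding_equilibrium_matches_quadratic():
    spec = ToyBindingSpec(k_on=2e-3, k_off=5e-3, A0=8.0, B0=3.0)
    net, analytic = make_toy_binding(spec)
    state, _ = find_steady_state(net, rel_tol=1e-9, horizon=48 * 3600, dt=30.0)
    assert state[2] == pytest.approx(analytic, rel=1e-6)


def test_detailed_balance_equilibrium_ratio():
    """[AB]/([A][B]) equals k_on/k_off at equilibrium."""
    spec = ToyBindingSpec(k_on=1e-3, k_off=2e-2, A0=5.0, B0=7.0)
    net, _ = make_toy_binding(spec)
    state, _ = find_steady_state(net, rel_tol=1e-9)
    ratio = state[2] / (state[0] * state[1])
    assert ratio == pytest.approx(spec.k_on / spec.k_off, rel=1e-6)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    k_on=st.floats(1e-4, 1e-1),
    k_off=st.floats(1e-4, 1e-1),
    A0=st.floats(0.1, 50.0),
    B0=st.floats(0.1, 50.0),
)
def test_toy_equilibrium_property(k_on, k_off, A0, B0):
    """Integrated steady state matches the binding quadratic for any rates."""
    spec = ToyBindingSpec(k_on=k_on, k_off=k_off, A0=A0, B0=B0)
    net, analytic = make_toy_binding(spec)
    state, _ = find_steady_state(net, rel_tol=1e-9, horizon=2e6, dt=100.0)
    assert state[2] == pytest.approx(analytic, rel=1e-5, abs=1e-10)


def test_conservation_along_compartment_trajectory():
    net = build_compartment_network(CompartmentParams(dose=21.5))
    t = np.linspace(0.0, 3600.0, 50)
    traj = integrate(net, t_grid=t, rtol=1e-10, atol=1e-13)
    totals0 = conserved_totals(net, traj.states[0])
    for row in traj.states:
        totals = conserved_totals(net, row)
        for pool, v0 in totals0.items():
            assert totals[pool] == pytest.approx(v0, rel=1e-6)


def test_nonnegativity_and_zero_state():
    net = build_compartment_network(CompartmentParams(dose=21.5))
    traj = integrate(net, t_grid=np.linspace(0, 7200, 100))
    assert traj.states.min() >= -1e-9
    zero = integrate(net, state0=np.zeros(7), t_grid=np.linspace(0, 100, 5))
    assert np.all(zero.states == 0.0)


def test_integrate_validates_inputs():
    net = build_compartment_network(CompartmentParams(dose=1.0))
    with pytest.raises(NetworkError):
        integrate(net, t_grid=[3.0, 2.0, 1.0])
    with pytest.raises(NetworkError):
        integrate(net, state0=np.array([-1.0, 0, 0, 0, 0, 0, 0]))


def test_conserved_totals_against_bruteforce_moiety_count():
    """Pool totals equal an independently enumerated moiety dot product."""
    net = build_compartment_network(CompartmentParams(dose=5.0))
    # moiety counts per species, enumerated by hand from the complex names
    counts = {
        "concizumab": [1, 0, 0, 1, 1, 1, 1],
        "TFPIa": [0, 1, 0, 1, 2, 0, 1],
        "TFPIb": [0, 0, 1, 0, 0, 1, 1],
    }
    rng = np.random.default_rng(7)
    state = rng.uniform(0, 10, size=7)
    totals = conserved_totals(net, state)
    for pool, vec in counts.items():
        assert totals[pool] == pytest.approx(float(np.dot(vec, state)), rel=1e-12)
    with pytest.raises(NetworkError):
        conserved_totals(net, state[:-1])


def test_steady_state_nonconvergence_reports_residual():
    """A constant-source network never settles and must say so."""
    net = ReactionNetwork(
        [SpeciesDecl("X")],
        [MassActionReaction("src", (), (("X", 1),), k_forward=1e-3, tags=("sink",))],
    )
    with pytest.raises(SteadyStateError) as err:
        find_steady_state(net, horizon=3600.0, abs_tol=1e-6)
    assert err.value.residual is not None and err.value.residual > 0


def test_species_decl_invariants():
    with pytest.raises(NetworkError):
        SpeciesDecl("X", initial_conc=-1.0)
    with pytest.raises(NetworkError):
        SpeciesDecl("X", phase="endothelium", transported=True)
    with pytest.raises(NetworkError):
        ReactionNetwork([SpeciesDecl("A"), SpeciesDecl("A")], [])


def test_pool_balance_checked_at_construction():
    """A declared pool not conserved by the reactions is rejected."""
    with pytest.raises(NetworkError, match="pool"):
        ReactionNetwork(
            [SpeciesDecl("A"), SpeciesDecl("B")],
            [MassActionReaction("r", (("A", 1),), (("B", 1),), 1.0)],
            conserved_pools={"bad": {"A": 1, "B": 2}},
        )
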