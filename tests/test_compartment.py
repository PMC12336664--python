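"""Compartment-model tests: printed partitions, conservation, dose logic."""

import numpy as np
import pytest
from scipy.optimize import fsolve

from coagsim import (
    CompartmentParams,
    build_compartment_network,
    dose_sweep,
    find_dose_for_plasma_target,
    find_steady_state,
    flow_inputs_from_partition,
    steady_state_partition,
)


def test_network_shape_and_printed_rates():
    net = build_compartment_network(CompartmentParams(dose=1.0))
    assert len(net.species) == 7 and len(net.reactions) == 5
    c4 = net.reaction("C4")
    assert c4.k_forward == pytest.approx(8.21e5 * 1e-9)
    assert c4.k_reverse == pytest.approx(1e-4)
    c5 = net.reaction("C5")
    assert c5.k_forward == pytest.approx(4.48e6 * 1e-9)
    # ternary complex carries one count in each moiety pool
    for pool in ("concizumab", "TFPIa", "TFPIb"):
        assert net.conserved_pools[pool]["TFPIa:C:TFPIb"] == 1


def test_partition_reproduces_reported_steady_state(partition_21p5):
    """Dose 21.5 nM with TFPIβ: the published pool partition."""
    p = partition_21p5
    assert p.C_TFPIb == pytest.approx(15.52, abs=0.02)
    assert p.TFPIa_C_TFPIb == pytest.approx(1.85, abs=0.02)
    assert p.C_bound_plasma_TFPIa == pytest.approx(0.55, abs=0.02)
    assert p.total_plasma_C == pytest.approx(4.0, abs=0.2)
    assert p.sequestered_TFPIa_fraction == pytest.approx(0.74, abs=0.01)
    # the plasma TFPIα-containing pool that seeds the flow model
    assert p.free_TFPIa + p.C_TFPIa == pytest.approx(0.4328, abs=0.01)


def test_partition_conservation_laws(partition_21p5):
    p = partition_21p5
    assert (p.free_TFPIa + p.C_TFPIa + 2 * p.TFPIa_C_TFPIa + p.TFPIa_C_TFPIb
            == pytest.approx(2.5, rel=1e-6))
    assert (p.free_TFPIb + p.C_TFPIb + p.TFPIa_C_TFPIb
            == pytest.approx(18.0, rel=1e-6))
    assert (p.free_C + p.C_TFPIa + p.TFPIa_C_TFPIa + p.C_TFPIb + p.TFPIa_C_TFPIb
            == pytest.approx(21.5, rel=1e-6))


def test_zero_dose_is_trivial():
    p = steady_state_partition(CompartmentParams(dose=0.0))
    assert p.free_TFPIa == pytest.approx(2.5, rel=1e-9)
    assert p.free_TFPIb == pytest.approx(18.0, rel=1e-9)
    for v in (p.C_TFPIa, p.TFPIa_C_TFPIa, p.C_TFPIb, p.TFPIa_C_TFPIb, p.free_C):
        assert v == pytest.approx(0.0, abs=1e-12)


def test_no_tfpib_species_remain_zero_and_plasma_equals_dose():
    p = steady_state_partition(CompartmentParams(dose=10.0, total_TFPIb=0.0))
    assert p.C_TFPIb == pytest.approx(0.0, abs=1e-12)
    assert p.TFPIa_C_TFPIb == pytest.approx(0.0, abs=1e-12)
    assert p.total_plasma_C == pytest.approx(10.0, rel=1e-6)


def test_equilibrium_against_algebraic_rootfinder():
    """Long-horizon steady state vs an independent equilibrium solver.

    With TFPIβ absent the equilibrium satisfies two conservation laws plus
    mass-action ratios; solved here with fsolve on those equations,
    independently of the ODE path.
    """
    params = CompartmentParams(dose=10.0, total_TFPIb=0.0)
    kd = params.ka_off / params.ka_on / 1e-9  # nM

    def eqs(x):
        c, ta = x
        cta = c * ta / kd
        tacta = cta * ta / kd
        return [c + cta + tacta - 10.0, ta + cta + 2 * tacta - 2.5]

    c, ta = fsolve(eqs, [8.0, 0.01], xtol=1e-13)
    cta = c * ta / kd
    tacta = cta * ta / kd

    net = build_compartment_network(params)
    state, _ = find_steady_state(net, rel_tol=1e-8)
    vals = dict(zip([s.name for s in net.species], state))
    assert vals["C"] == pytest.approx(c, rel=1e-5)
    assert vals["C:TFPIa"] == pytest.approx(cta, rel=1e-5)
    assert vals["TFPIa:C:TFPIa"] == pytest.approx(tacta, rel=1e-5)


def test_steady_state_independent_of_initial_distribution():
    """All-free versus pre-bound concizumab converge to the same equilibrium."""
    params = CompartmentParams(dose=6.0)
    net = build_compartment_network(params)
    free0 = net.initial_state()
    bound0 = free0.copy()
    # start with 2 nM pre-formed C:TFPIb instead of free species
    bound0[0] -= 2.0
    bound0[2] -= 2.0
    bound0[5] += 2.0
    s1, _ = find_steady_state(net, state0=free0, rel_tol=1e-8)
    s2, _ = find_steady_state(net, state0=bound0, rel_tol=1e-8)
    np.testing.assert_allclose(s1, s2, rtol=1e-5, atol=1e-9)


def test_dose_sweep_monotonicity():
    doses = np.arange(0.0, 30.1, 2.0)
    table = dose_sweep(CompartmentParams(), doses)
    assert len(table) == len(doses)
    assert np.all(np.diff(table["total_plasma_C"]) >= -1e-9)
    assert np.all(np.diff(table["free_TFPIa"]) <= 1e-9)
    depleted = table[table["dose"] > 4.0]
    assert (depleted["free_TFPIa"] < 0.05 * 2.5).all()


def test_find_dose_with_and_without_tfpib():
    dose_no_b = find_dose_for_plasma_target(
        CompartmentParams(total_TFPIb=0.0), target=4.0)
    assert dose_no_b == pytest.approx(4.0, abs=0.02)
    dose_b = find_dose_for_plasma_target(CompartmentParams(), target=4.0)
    # published value 21.5; the quasi-steady plasma pool puts it slightly lower
    assert 21.0 < dose_b < 22.0
    plasma = steady_state_partition(
        CompartmentParams(dose=dose_b)).total_plasma_C
    assert plasma == pytest.approx(4.0, abs=0.05)
    assert find_dose_for_plasma_target(CompartmentParams(), target=0.0) == 0.0


def test_find_dose_unreachable_target_raises():
    with pytest.raises(ValueError, match="not bracketed"):
        find_dose_for_plasma_target(CompartmentParams(), target=50.0)


def test_flow_inputs_scaling(partition_21p5):
    inp = flow_inputs_from_partition(partition_21p5)
    assert inp["TFPIa"] == pytest.approx(0.2 * partition_21p5.free_TFPIa)
    assert inp["C:TFPIa"] == pytest.approx(0.09, abs=0.01)  # 20% of ~0.43
    assert inp["C"] == pytest.approx(partition_21p5.free_C)  # unscaled
    ident = flow_inputs_from_partition(partition_21p5, free_fraction=1.0)
    assert ident["C:TFPIa"] == pytest.approx(partition_21p5.C_TFPIa)


def test_flow_inputs_no_tfpib_ctfpia_pool():
    """Without TFPIβ the 4 nM dose leaves ~0.26 nM scaled C:TFPIα in plasma."""
    p = steady_state_partition(CompartmentParams(dose=4.0, total_TFPIb=0.0))
    inp = flow_inputs_from_partition(p)
    assert inp["C:TFPIa"] == pytest.approx(0.26, abs=0.02)


def test_kd_helpers_roundtrip():
    base = CompartmentParams()
    assert base.kd_alpha_pm == pytest.approx(22.321, rel=1e-3)
    assert base.kd_beta_pm == pytest.approx(121.8, rel=1e-3)
    same = base.with_kd(base.kd_alpha_pm, base.kd_beta_pm, mode="on")
    assert same.ka_on == pytest.approx(base.ka_on, rel=1e-12)
    off_mode = base.with_kd(50.0, mode="off")
    assert off_mode.ka_off / off_mode.ka_on * 1e12 == pytest.approx(50.0)


def test_params_validation():
    with pytest.raises(ValueError):
        CompartmentParams(ka_on=0.0)
    with pytest.raises(ValueError):
        CompartmentParams(dose=-1.0)
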