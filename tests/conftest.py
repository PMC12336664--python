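"""Shared fixtures.

Expensive simulations (flow runs, scenario tables) are session-scoped so
that unit tests and the acceptance tests share one computation.
"""

import numpy as np
import pytest

from coagsim import (
    CompartmentParams,
    FlowParams,
    ScenarioSpec,
    apply_scenario,
    flow_inputs_from_partition,
    simulate_injury,
    steady_state_partition,
)


@pytest.fixture(scope="session")
def partition_21p5():
    """Compartment steady state at the 21.5 nM intravascular dose."""
    return steady_state_partition(CompartmentParams(dose=21.5))


@pytest.fixture(scope="session")
def concizumab_inputs(partition_21p5):
    """Flow-model plasma initial conditions with concizumab present."""
    return flow_inputs_from_partition(partition_21p5)


def _run(tf, fviii, inputs=None, duration=40.0):
    return simulate_injury(
        FlowParams(TF_density=tf, FVIII_level=fviii, plasma_inputs=inputs,
                   duration_min=duration)
    )


@pytest.fixture(scope="session")
def fig3_runs(concizumab_inputs):
    """Injury simulations for the TF x FVIII x concizumab grid."""
    runs = {}
    for tf in (4.0, 9.0, 20.0):
        runs[(tf, "hemA", "noC")] = _run(tf, 0.01)
        runs[(tf, "hemA", "C")] = _run(tf, 0.01, concizumab_inputs)
        runs[(tf, "normal", "noC")] = _run(tf, 1.0)
    return runs


@pytest.fixture(scope="session")
def six_scenario_table():
    from coagsim import run_six_scenarios

    return run_six_scenarios(9.0, 0.01)
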