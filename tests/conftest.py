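import numpy as np
import pandas as pd
import pytest

from m1beta import cells, circuit, drive, engine


@pytest.fixture(scope="session")
def it_cell():
    return cells.build_cell("IT", "control")


@pytest.fixture(scope="session")
def pt5b_control():
    return cells.build_cell("PT5B", "control")


@pytest.fixture(scope="session")
def pt5b_parkinsonian():
    return cells.build_cell("PT5B", "parkinsonian")


@pytest.fixture(scope="session")
def pt5b_amplitudes(pt5b_control):
    return cells.default_step_amplitudes(pt5b_control)


@pytest.fixture(scope="session")
def all_models():
    return {c: cells.build_cell(c, "control") for c in cells.CELL_CLASSES}


@pytest.fixture(scope="session")
def small_network(all_models):
    """Scale-0.05 default circuit (no simulation)."""
    geo = circuit.Geometry()
    pops = circuit.default_populations()
    rules = circuit.default_rules()
    neurons = circuit.place_neurons(geo, pops, scale=0.05, seed=11)
    edges = circuit.build_edges(neurons, rules, all_models, seed=12, scale=0.05)
    return circuit.NetworkInstance(neurons, edges, geo, 0.05, 12)


@pytest.fixture(scope="session")
def kernel_test_network(all_models):
    """Single dense population for connectivity-kernel statistics."""
    geo = circuit.Geometry()
    pop = [circuit.PopulationSpec("IT5B", "IT", "L5B", 900)]
    neurons = circuit.place_neurons(geo, pop, scale=1.0, seed=5)
    rule = circuit.ConnectionRule("IT5B", "IT5B", p_con=0.5, v_con_mv=0.5, kind="E")
    return geo, neurons, rule
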