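import numpy as np
import pytest

from digitoids.engine import SimConfig, run
from digitoids.neuron import MembraneParams, MetabolicParams


@pytest.fixture(scope="session")
def mp() -> MetabolicParams:
    return MetabolicParams()


@pytest.fixture(scope="session")
def mb() -> MembraneParams:
    return MembraneParams()


@pytest.fixture(scope="session")
def oxygenated_run():
    """Well-oxygenated single neuron, 8 s: fires a multi-second train."""
    return run(SimConfig(mode="single_neuron", h=1e-4, c0=0.2, duration=8.0))


@pytest.fixture(scope="session")
def quiescent_run():
    """Same oxygen conditions without drive: no spiking."""
    return run(SimConfig(mode="single_neuron", h=1e-4, c0=0.2, duration=8.0,
                         I_ext=0.0))


@pytest.fixture(scope="session")
def anoxic_run():
    """Zero boundary oxygen: the pump starves."""
    return run(SimConfig(mode="single_neuron", h=1e-4, c0=0.0, duration=8.0))
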