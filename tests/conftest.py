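import numpy as np
import pytest

from spheroflow import (FlowModel, GridSpec, SimConfig, flow_pattern_field)


@pytest.fixture(scope="session")
def model():
    """Default channel with the 208-um aggregate at the origin."""
    return FlowModel()


@pytest.fixture(scope="session")
def grid_spec():
    """20x20 boxes of 103 um centered on the origin."""
    return GridSpec.centered((0.0, 0.0), nx=20, ny=20)


@pytest.fixture(scope="session")
def zone_field(grid_spec):
    """Idealized flow-derived field for a 150-um spheroid."""
    return flow_pattern_field(grid_spec, spheroid_radius=150.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
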