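import numpy as np
import pytest

from intmm import DesignSpec, KineticParameters, default_grid, simulate_design


@pytest.fixture(scope="session")
def unit_params() -> KineticParameters:
    """V = Km = 1 in arbitrary units: the reference simulation conditions."""
    return KineticParameters(V=1.0, Km=1.0)


@pytest.fixture(scope="session")
def grid() -> tuple:
    return tuple(default_grid())


@pytest.fixture()
def constant_time_dataset(unit_params, grid):
    """Factory for noiseless constant-time datasets at a given conversion."""

    def make(fraction: float, s0_grid=None, strategy: str = "constant_time"):
        spec = DesignSpec(strategy, s0_grid or grid, fraction, unit_params)
        return simulate_design(spec)

    return make
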