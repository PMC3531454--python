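import numpy as np
import pytest

from puffspike.dyk import CellParams, build_dyk_generator, fit_parameter_maps


@pytest.fixture(scope="session")
def std_cell():
    return CellParams()


@pytest.fixture(scope="session")
def dyk_base(std_cell):
    """Lumped channel CTMC at base-level Ca (puff regime)."""
    return build_dyk_generator(std_cell, ca=std_cell.ca_base)


@pytest.fixture(scope="session")
def dyk_open(std_cell):
    """Lumped channel CTMC at the elevated (CICR) Ca level."""
    return build_dyk_generator(std_cell, ca=std_cell.ca_open)


@pytest.fixture(scope="session")
def param_map():
    """DYK parameter map fitted once per session (moderate sample size)."""
    return fit_parameter_maps(n_samples=2000, seed=11, method="spectral")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
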