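import numpy as np
import pytest

from lamsim import bold_sim, design, neural_model as nm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_design():
    return design.make_default_design()


@pytest.fixture
def small_design():
    """Four-block design for fast GLM tests."""
    return design.DesignSpec(blocks_per_run=4, n_taskdplus_runs=1, n_taskdminus_runs=1)


@pytest.fixture
def kernel(default_design):
    return bold_sim.hrf_kernel(tr=default_design.tr)


@pytest.fixture
def small_population(rng):
    return nm.sample_voxels(30, 1.1, 0.5, rng)
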