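import numpy as np
import pytest

from vcbm_abc.simulator import SimConfig, TissueState, init_tissue


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_config():
    """A minimal but geometrically valid tissue: radius-2 tumour, width-3
    annulus, short horizon."""
    return SimConfig(
        dt=3.0, damping=30.0, n_days=4.0, measure_every=2.0,
        init_cancer_radius=2.0, domain_pad=3.0, max_cells=500,
    )


@pytest.fixture
def tiny_state(tiny_config, rng) -> TissueState:
    return init_tissue(tiny_config, rng)
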