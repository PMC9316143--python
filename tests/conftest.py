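import numpy as np
import pytest

import iimdepth as iim


@pytest.fixture(scope="session")
def plane_scene():
    """Constant-disparity d=0.5 bandlimited-noise scene, 9x9 views of 32x32."""
    return iim.make_plane_lightfield(
        "bandlimited-noise", 0.5, 9, 9, 32, 32, seed=7
    )


@pytest.fixture(scope="session")
def tiny_model():
    """Channel-narrowed untrained network for shape/inference tests."""
    return iim.build_network(iim.NetworkConfig().scaled(0.125), seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def zero_model(cfg=None):
    """Network with every weight and bias zeroed (predicts identically 0)."""
    model = iim.build_network(cfg or iim.NetworkConfig().scaled(0.125), seed=0)
    for p in model.params():
        p.value[...] = 0.0
    return model
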