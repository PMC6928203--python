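import numpy as np
import pytest

from renaldwi import (
    IVIMParams,
    ProtocolConfig,
    generate_kidney_phantom,
    generate_tube_phantom,
)

# Healthy per-layer slow diffusion medians (10⁻³ mm²/s) used as phantom
# ground truth throughout the suite.
LAYER_D = {"COR": 1.61, "OM": 1.78, "IM": 1.88}


@pytest.fixture(scope="session")
def protocol():
    return ProtocolConfig()  # b = 0,200,300,500,700; 3 directions; 96×96


@pytest.fixture(scope="session")
def protocol_1dir():
    return ProtocolConfig(n_directions=1)


@pytest.fixture(scope="session")
def tube_phantom(protocol_1dir):
    return generate_tube_phantom(protocol_1dir)


@pytest.fixture(scope="session")
def kidney_phantom_pure(protocol):
    """Noiseless kidney phantom with f = 0: mono-exponential in every
    pixel, so fits must recover the layer D values exactly."""
    params = {
        lay: IVIMParams(S0=1000.0, D=d) for lay, d in LAYER_D.items()
    }
    return generate_kidney_phantom(params, protocol)


@pytest.fixture(scope="session")
def kidney_phantom_ivim(protocol):
    """Noiseless kidney phantom with a perfusing compartment."""
    params = {
        "COR": IVIMParams(S0=1000.0, D=LAYER_D["COR"], Dp=50.0, f=0.20),
        "OM": IVIMParams(S0=1000.0, D=LAYER_D["OM"], Dp=50.0, f=0.15),
        "IM": IVIMParams(S0=1000.0, D=LAYER_D["IM"], Dp=50.0, f=0.10),
    }
    return generate_kidney_phantom(params, protocol)


def disk_mask(r, shape=None, center=None):
    if shape is None:
        pad = 2 * r + 21
        shape = (pad, pad)
    if center is None:
        center = (shape[0] // 2, shape[1] // 2)
    rr, cc = np.indices(shape)
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= r * r
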