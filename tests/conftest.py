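import numpy as np
import pytest

from holocyte import (CellPhantom, OpticalConfig, center_phantom,
                      render_phase_image, synthesize_hologram)

LYMPH_R = 3.675
MONO_R = 4.533
N_CELL = 1.3497


@pytest.fixture(scope="session")
def config():
    return OpticalConfig()


@pytest.fixture()
def lymph_phantom(config):
    ph = CellPhantom((0.0, 0.0), LYMPH_R, N_CELL)
    return center_phantom(ph, config)


@pytest.fixture()
def lymph_phase(lymph_phantom, config):
    return render_phase_image(lymph_phantom, config)


@pytest.fixture()
def lymph_hologram(lymph_phase, config):
    return synthesize_hologram(lymph_phase, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
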