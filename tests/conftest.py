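import numpy as np
import pytest

from filotrack import SimConfig, CellGeometry, Filopodium


@pytest.fixture
def config():
    """Default imaging calibration on a small field (fast to render)."""
    return SimConfig(field_w_px=48, field_h_px=48)


@pytest.fixture
def filo_config():
    """Wide shallow field holding a single horizontal filopodium."""
    return SimConfig(field_w_px=80, field_h_px=24)


@pytest.fixture
def filopodium():
    return Filopodium(np.array([[1.0, 1.2], [6.0, 1.2]]))


@pytest.fixture
def geometry(config):
    return CellGeometry(config.field_w_um, config.field_h_um,
                        cytosol_height_um=1.0)
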