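import numpy as np
import pytest

from srclassify.grn_circuit import IntegrationSettings, build_toggle_classifier


@pytest.fixture(scope="session")
def unit_topology():
    """Toggle-switch classifier with unit input weights."""
    return build_toggle_classifier(1.0, 1.0)


@pytest.fixture(scope="session")
def fast_settings():
    """Integration settings tuned for small test grids."""
    return IntegrationSettings(duration=120.0, dt=0.01, check_interval=5.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
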