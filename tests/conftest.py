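import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hmdcal.presets import preset_path
from hmdcal.virtual_display import load_display_model, run_protocol

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230614)


@pytest.fixture(scope="session")
def display_model():
    return load_display_model(preset_path("aurora-amoled"))


@pytest.fixture(scope="session")
def clipped_model():
    """Preset whose green channel saturates below full drive in selective mode."""
    return load_display_model(preset_path("budget-oled"))


@pytest.fixture(scope="session")
def bimodal_model():
    return load_display_model(preset_path("twin-panel"))


@pytest.fixture(scope="session")
def sessions(display_model):
    """Noiseless protocol runs for all three rendering configurations."""
    return {
        mode: run_protocol(display_model, mode, seed=7)
        for mode in ("default", "tonemap_disabled", "selective")
    }
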