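import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thetagamma.pipeline import analyze_lfp
from thetagamma.synth import SyntheticConfig, simulate_session

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_session():
    """120 s wake session used by unit tests."""
    return simulate_session(SyntheticConfig(duration=120.0, seed=5))


@pytest.fixture(scope="session")
def wake_session_600():
    """Full-length wake session with the reference presets planted."""
    return simulate_session(SyntheticConfig(duration=600.0, seed=0))


@pytest.fixture(scope="session")
def analyzed_600(wake_session_600):
    """Full pipeline (k = 4) on the 600 s session."""
    s = wake_session_600
    return analyze_lfp(s.lfp, s.fs, seed=0, k=4)


@pytest.fixture(scope="session")
def planted_by_label(wake_session_600):
    """Planted (freq, phase) per state label for the reference presets."""
    return {p.name: (p.burst_freq, p.burst_phase) for p in wake_session_600.config.presets}


def circular_error(a, b):
    return float(np.abs(np.angle(np.exp(1j * (a - b)))))
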