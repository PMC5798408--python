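import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20170614)


@pytest.fixture
def six_tmd_states():
    """A 6-TMD state string starting cytoplasmic (loops 10, TMDs 20)."""
    parts = []
    side = "i"
    for _ in range(6):
        parts.append(side * 10)
        parts.append("M" * 20)
        side = "o" if side == "i" else "i"
    parts.append(side * 10)
    return "".join(parts)
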