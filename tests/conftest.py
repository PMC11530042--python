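import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def bone_plate_test_result():
    """One shared bone-plate run at test resolution (read-only)."""
    from vancoelute.scenarios import default_config, run_human_bone_plate

    return run_human_bone_plate(default_config("human_bone_plate", "test"))
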