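import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_session():
    from refback.task_design import SessionDesign, generate_session

    return generate_session(SessionDesign(n_blocks=2, trials_per_block=40, seed=7))


@pytest.fixture
def full_session():
    from refback.task_design import SessionDesign, generate_session

    return generate_session(SessionDesign(seed=1))
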