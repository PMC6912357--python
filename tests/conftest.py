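import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_scene():
    """One rendered default scene with its ground truth and seed points."""
    from bluesclera import EyeSceneParams, default_seeds, render_eye_scene

    params = EyeSceneParams()
    stack, truth = render_eye_scene(params)
    return params, stack, truth, default_seeds(params)
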