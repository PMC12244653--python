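import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """Tiny two-dataset study used by several integration tests."""
    from flywake import SynthConfig, generate_study

    cfg = SynthConfig(
        n_flies_per_dataset={"discovery": 3, "evaluation": 2},
        seed=7,
    )
    return cfg, generate_study(cfg)
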