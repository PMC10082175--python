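import numpy as np
import pytest

from densicount import ModelConfig, build_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_net():
    """One shared reduced-width network for inference-only tests."""
    return build_network(ModelConfig.tiny(seed=7))


@pytest.fixture(scope="session")
def tiny_net_factory():
    def make(seed=7, **kw):
        return build_network(ModelConfig.tiny(seed=seed, **kw))

    return make
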