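import numpy as np
import pytest

from widelearn.synthetic import GeneratorConfig, generate_event_stream


@pytest.fixture(scope="session")
def default_tokens():
    """Encoded default synthetic corpus (vocab 20, 4 speakers, 15
    tokens/type/speaker), shuffled into one training order."""
    return generate_event_stream(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_tokens():
    """A small encoded corpus for cheap structural checks."""
    cfg = GeneratorConfig(
        vocab_size=6, speakers=2, tokens_per_type_per_speaker=5,
        reduction_p=0.0, seed=3,
    )
    return generate_event_stream(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
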