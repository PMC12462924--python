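import numpy as np
import pytest

from crossdti.encoder import EncoderConfig
from crossdti.synthetic import SyntheticConfig, fixture_mini, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default planted-rule benchmark (shared across tests; read-only)."""
    return generate_dataset(SyntheticConfig())


@pytest.fixture(scope="session")
def mini_tables():
    return fixture_mini()


@pytest.fixture
def small_encoder_config():
    return EncoderConfig(embed_dim=8, protein_channels=[8, 8, 8],
                         protein_kernel_sizes=[3, 5, 7],
                         drug_hidden_dims=[8, 8, 8], fusion_dim=12,
                         attention_rank=3, cls_hidden=6, l_max=40)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
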