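import numpy as np
import pytest

from gemmomics import synthdata as sd


@pytest.fixture
def small_cfg() -> sd.SynthConfig:
    """Small, fast cohort: 3 classes x 6 samples, 60 genes."""
    return sd.SynthConfig(
        seed=123,
        n_genes=60,
        n_samples_per_class={"microacinar": 6, "squamous": 6, "EMT": 6},
        noise_sd=0.5,
        n_informative=12,
        cn_block_size=4,
        n_cn_varying=10,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
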