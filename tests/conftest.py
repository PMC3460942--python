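import numpy as np
import pytest

from ccprog import MixtureSpec, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def study_dataset():
    """One seeded dataset at the training-study scale (130 samples, 60 genes)."""
    cfg = SyntheticConfig(seed=42, n_genes=60, frac_tumor_de=5 / 60, frac_stroma_de=3 / 60)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def spec():
    return MixtureSpec(seed=11)
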