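import numpy as np
import pytest

from edmnet.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_survey():
    """A small multi-site synthetic survey shared by quantification tests."""
    df, truth = simulate_dataset(
        n_species=8, n_sites=3, n_steps=30, connectance=0.15,
        gamma_scale=0.3, seed=42,
    )
    return df, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
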