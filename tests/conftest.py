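import numpy as np
import pytest

import rkcca


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture(scope="session")
def example_halves():
    """One draw of the two-latent example, split into train/test halves."""
    blocks, latents = rkcca.generate_example(rkcca.SyntheticSpec(seed=7))
    train = [rkcca.split_halves(b)[0] for b in blocks]
    test = [rkcca.split_halves(b)[1] for b in blocks]
    return train, test, latents


@pytest.fixture(scope="session")
def fitted_model(example_halves):
    """Unregularized primal CCA fit on the training halves (4 components)."""
    train, _, _ = example_halves
    return rkcca.fit_cca(train, reg=0.0, n_components=4, kernel=None)
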