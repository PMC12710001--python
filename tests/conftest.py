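import numpy as np
import pytest
from hypothesis import settings

import leafgen as lg

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from leafgen.generator import (
    GeneratorConfig,
    build_training_pairs,
    init_model,
    train,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def beet_params():
    """One fixed, representative sugar-beet parameter draw."""
    return lg.sample_skeleton_params(lg.SUGAR_BEET, np.random.default_rng(0))


@pytest.fixture(scope="session")
def small_corpus():
    """A small noise-free-ish pseudo-real sugar-beet corpus."""
    records, manifest = lg.generate_corpus(
        8, lg.SUGAR_BEET, lg.NoiseConfig(gaussian_sigma=0.002), patches=2, seed=11
    )
    return records, manifest


@pytest.fixture(scope="session")
def smoke_trained():
    """The reference smoke-training run: 20 sugar-beet pairs, 200 epochs.

    Session-scoped because training takes about a minute and several tests
    (loss decrease, skeleton anchoring, trait preservation, end-to-end trait
    recovery) probe the same trained model.
    """
    rng = np.random.default_rng(42)
    records, _ = lg.generate_corpus(
        20, lg.SUGAR_BEET, lg.NoiseConfig(gaussian_sigma=0.002, points_per_leaf=600),
        seed=7,
    )
    pairs = build_training_pairs(
        [r.cloud for r in records], lg.SUGAR_BEET.gmm_modes, rng
    )
    cfg = GeneratorConfig(epochs=200, seed=1)
    model = init_model(cfg)
    history = train(model, pairs, cfg)
    return model, history, cfg
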