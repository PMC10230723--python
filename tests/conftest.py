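import numpy as np
import pytest

import rbpattn as rb


@pytest.fixture
def tiny_model_cfg():
    """Small but complete model: every branch and block exercised cheaply."""
    return rb.ModelConfig(length=24, dim=16, heads=2, blocks=2, ffn_dim=32,
                          seq2vec_dim=8, context_dim=8, encoder_channels=8,
                          dropout=0.0, seed=0)


@pytest.fixture
def tiny_train_cfg():
    return rb.TrainingConfig(epochs=2, batch_size=16, seed=0,
                             seq2vec_epochs=2)


@pytest.fixture
def tiny_dataset():
    """Motif-planted dataset small enough for sub-second featurization."""
    return rb.generate_dataset(rb.GeneratorConfig(
        n=60, L=24, seed=5, motif=rb.MotifSpec(consensus="UGCAUG",
                                               mutation_rate=0.0)))


def random_sequence(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
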