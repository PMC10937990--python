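import numpy as np
import pytest

from cmixup import (
    EncoderSpec,
    SyntheticCorpusSpec,
    build_model,
    generate_corpus,
)

#: desk-scale encoder used throughout the tests: the tiny convnet backbone
#: with a narrow projector/predictor so forward+backward stay sub-second.
TINY_ENCODER = EncoderSpec(
    backbone="tiny_cnn", projector_out_dim=32, predictor_hidden_dim=16
)


@pytest.fixture(scope="session")
def small_corpus():
    """4-class 32-px corpus: 140-image unlabeled pool + 60 labeled images."""
    spec = SyntheticCorpusSpec(
        n_classes=4, images_per_class=50, image_size=32,
        unlabeled_fraction=0.7, noise_sd=0.05, seed=7,
    )
    return generate_corpus(spec)


@pytest.fixture()
def tiny_model():
    return build_model(TINY_ENCODER, np.random.default_rng(11))
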