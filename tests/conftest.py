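"""Shared fixtures: small synthetic circle studies and quickly trained models.

Everything is generated programmatically at test time; image sizes and step
counts are kept small so the full suite stays fast on one CPU.
"""

import numpy as np
import pytest

from lspheno.datamodel import GenotypeMatrix
from lspheno.decoder import DecoderConfig, train_decoder
from lspheno.embedding import EmbeddingConfig, train_embedding
from lspheno.preprocess import split_train_validation
from lspheno.simulate import CircleConfig, generate_circle_dataset, generate_genotypes


TINY_CIRCLE = CircleConfig(
    n_per_condition=12,
    n_timepoints=4,
    image_size=16,
    d0_mean=4.0,
    d0_sd=0.6,
    rate_mean_control=3.0,
    rate_mean_treated=1.2,
    rate_sd=0.35,
    qtl_effect=0.1,
    causal_effect=0.3,
    seed=1234,
)


@pytest.fixture(scope="session")
def tiny_genotypes() -> GenotypeMatrix:
    return generate_genotypes(12, 40, causal_index=7, seed=99)


@pytest.fixture(scope="session")
def tiny_circles(tiny_genotypes):
    """12 genotypes x 2 conditions of 16x16 circle sequences, with truth."""
    return generate_circle_dataset(TINY_CIRCLE, tiny_genotypes)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_circles):
    return tiny_circles[0]


@pytest.fixture(scope="session")
def tiny_split(tiny_dataset):
    return split_train_validation(tiny_dataset, seed=5)


@pytest.fixture(scope="session")
def tiny_embedding(tiny_split):
    """A small embedding model trained on clearly separable circles."""
    train, val = tiny_split
    cfg = EmbeddingConfig(max_steps=260, early_stop_patience=10, seed=21, cnn_channels=(8, 16, 32, 64))
    return train_embedding(train, val, cfg)


@pytest.fixture(scope="session")
def tiny_decoder(tiny_embedding, tiny_split):
    train, _ = tiny_split
    return train_decoder(tiny_embedding, train, DecoderConfig(max_steps=5000, seed=3, base_channels=32, eval_every=500))
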