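import numpy as np
import pytest

from spixseg import nn
from spixseg.classifier import ClassifierConfig, train_classifier
from spixseg.data import MultimodalSlice
from spixseg.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_phantom_train():
    """24 easy-contrast 16×16 phantom slices for fast training tests."""
    cfg = PhantomConfig(
        n_images=24, image_size=(16, 16), lesion_prevalence=0.6,
        lesion_radius_range=(3.0, 5.0), lesion_contrast=(0.3, 0.4, 0.5, 0.8),
        noise_sd=0.03, rng_seed=7,
    )
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def tiny_phantom_val():
    cfg = PhantomConfig(
        n_images=12, image_size=(16, 16), lesion_prevalence=0.6,
        lesion_radius_range=(3.0, 5.0), lesion_contrast=(0.3, 0.4, 0.5, 0.8),
        noise_sd=0.03, rng_seed=8,
    )
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def tiny_classifier(tiny_phantom_train, tiny_phantom_val):
    """A quickly trained small classifier shared by Stage-2 tests."""
    cfg = ClassifierConfig(backbone="vgg-small", epochs=10, batch_size=8,
                           lr_init=1e-3, weight_decay=0.01, rng_seed=3)
    return train_classifier(tiny_phantom_train, tiny_phantom_val, cfg)


def make_slice(pixels: np.ndarray, label: int = 0,
               mask: np.ndarray | None = None) -> MultimodalSlice:
    return MultimodalSlice(pixels=pixels, label=label, reference_mask=mask)
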