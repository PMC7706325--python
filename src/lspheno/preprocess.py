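"""Image standardization, training-time augmentation, and the train/validation split."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .datamodel import Dataset

_EPS = 1e-8


def standardize_image(image: np.ndarray) -> np.ndarray:
    """Center to zero mean and scale to unit standard deviation per image.

    Statistics are taken over all pixels and channels of the single image
    (population standard deviation). A small epsilon keeps constant images
    well-defined: they map to all zeros.
    """
    img = np.asarray(image, dtype=np.float32)
    mean = img.mean()
    sd = img.std()
    return (img - mean) / (sd + _EPS)


@dataclass
class AugmentConfig:
    """Which augmentations to apply during embedding training.

    ``crop_fraction`` is the linear fraction of each image side retained by
    the random crop (1.0 disables cropping; the crop is resized back to the
    original shape).
    """

    hflip: bool = False
    brightness_delta: float = 0.0
    contrast_delta: float = 0.0
    crop_fraction: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.crop_fraction <= 1.0):
            raise ValueError(f"crop_fraction must be in (0, 1], got {self.crop_fraction}")
        if self.brightness_delta < 0 or self.contrast_delta < 0:
            raise ValueError("brightness/contrast jitter amplitudes must be >= 0")

    @property
    def enabled(self) -> bool:
        return self.hflip or self.brightness_delta > 0 or self.contrast_delta > 0 or self.crop_fraction < 1.0


def augment_image(image: np.ndarray, rng: np.random.Generator, config: AugmentConfig) -> np.ndarray:
    """Randomly flip/jitter/crop one image; identity when all switches are off."""
    img = np.asarray(image, dtype=np.float32).copy()
    h, w = img.shape[:2]
    if config.hflip and rng.random() < 0.5:
        img = img[:, ::-1]
    if config.brightness_delta > 0:
        img = img + rng.uniform(-config.brightness_delta, config.brightness_delta)
    if config.contrast_delta > 0:
        factor = rng.uniform(1.0 - config.contrast_delta, 1.0 + config.contrast_delta)
        mean = img.mean()
        img = mean + (img - mean) * factor
    if config.crop_fraction < 1.0:
        ch = max(1, int(round(h * config.crop_fraction)))
        cw = max(1, int(round(w * config.crop_fraction)))
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        crop = img[top : top + ch, left : left + cw]
        img = resize(crop, img.shape, order=1, mode="edge", anti_aliasing=False, preserve_range=True)
    return np.ascontiguousarray(img, dtype=np.float32)


def split_train_validation(dataset: Dataset, seed: int, val_fraction: float = 0.2):
    """Split by genotype so replicates/conditions never straddle the split.

    Genotypes are shuffled deterministically by ``seed``; the validation set
    takes ``round(val_fraction * G)`` genotypes (at least one).
    """
    genotypes = dataset.genotype_ids()
    g = len(genotypes)
    if g < 5:
        raise ValueError(
            f"need at least 5 distinct genotypes for an 80-20 genotype split, got {g}; "
            "use a smaller validation fraction or more genotypes"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(g))
    n_val = max(1, int(round(val_fraction * g)))
    val_genos = {genotypes[i] for i in order[:n_val]}
    train_genos = [gt for gt in genotypes if gt not in val_genos]
    return dataset.subset(train_genos), dataset.subset(sorted(val_genos, key=genotypes.index))
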