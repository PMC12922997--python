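"""Normalization, resizing, random augmentation and dataset splitting.

Geometric transforms always act on the image and its mask with the same
map: bilinear interpolation for intensities, nearest-neighbour for labels,
so mask label sets never grow.  All randomness flows through an explicit
`numpy.random.Generator`.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .samples import ImageSample

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class AugmentConfig:
    """Augmentation settings.

    rotation_range : (low, high) angles in radians, default (-pi/6, pi/6)
    crop_h, crop_w : random-crop output size in pixels
    flip_prob     : probability of each of the vertical / horizontal flips
    target_h, target_w : resize target applied before augmentation
    """

    rotation_range: tuple[float, float] = (-math.pi / 6, math.pi / 6)
    crop_h: int = 56
    crop_w: int = 56
    flip_prob: float = 0.5
    target_h: int = 64
    target_w: int = 64

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must lie in [0, 1]")
        if self.crop_h > self.target_h or self.crop_w > self.target_w:
            raise ValueError("crop dims must not exceed target dims")


def zscore_normalize(sample: ImageSample) -> ImageSample:
    """Per-image standardization X <- (X - mean) / sd.

    A constant image (sd = 0) maps to all zeros with a warning rather than
    dividing by zero.
    """
    pixels = sample.pixels
    if not np.all(np.isfinite(pixels)):
        raise ValueError("pixels must be finite for z-score normalization")
    mu = pixels.mean()
    sigma = pixels.std()
    if sigma == 0.0:
        logger.warning("constant image %r: z-score returns all zeros", sample.id)
        out = np.zeros_like(pixels)
    else:
        out = (pixels - mu) / sigma
    return ImageSample(out, sample.mask.copy(), sample.id, sample.split)


def dataset_normalize(samples: list[ImageSample]) -> list[ImageSample]:
    """Standardize with the dataset-level mean and standard deviation."""
    stacked = np.concatenate([s.pixels.ravel() for s in samples])
    mu, sigma = stacked.mean(), stacked.std()
    if sigma == 0.0:
        logger.warning("constant dataset: normalization returns all zeros")
        return [ImageSample(np.zeros_like(s.pixels), s.mask.copy(), s.id, s.split) for s in samples]
    return [ImageSample((s.pixels - mu) / sigma, s.mask.copy(), s.id, s.split) for s in samples]


def resize(sample: ImageSample, target_h: int, target_w: int) -> ImageSample:
    """Resize to (target_h, target_w): bilinear pixels, nearest-neighbour mask.

    Uses the align-corners-false convention (source coordinate of output
    pixel i is (i + 0.5) / scale - 0.5, edge-clamped), so resizing a 1x2
    ramp [0, 1] to 1x4 yields [0, 0.25, 0.75, 1].
    """
    if target_h < 1 or target_w < 1:
        raise ValueError("resize targets must be >= 1")
    if (target_h, target_w) == sample.shape:
        return sample.copy()
    pixels = _sk_resize(
        sample.pixels, (target_h, target_w), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    mask = _sk_resize(
        sample.mask.astype(float), (target_h, target_w), order=0, mode="edge",
        anti_aliasing=False, preserve_range=True,
    ).astype(sample.mask.dtype)
    return ImageSample(pixels, mask, sample.id, sample.split)


def flip(sample: ImageSample, axis: int) -> ImageSample:
    """Mirror along axis 0 (vertical flip) or 1 (horizontal flip)."""
    return ImageSample(
        np.flip(sample.pixels, axis=axis).copy(),
        np.flip(sample.mask, axis=axis).copy(),
        sample.id,
        sample.split,
    )


def random_flip(sample: ImageSample, rng: np.random.Generator, prob: float = 0.5) -> ImageSample:
    """Independently apply vertical and horizontal mirror, each with ``prob``."""
    out = sample
    if rng.random() < prob:
        out = flip(out, 0)
    if rng.random() < prob:
        out = flip(out, 1)
    return out.copy() if out is sample else out


def rotate(sample: ImageSample, angle_rad: float) -> ImageSample:
    """Rotate about the image center with edge-replication fill.

    Pixels are interpolated bilinearly, the mask nearest-neighbour.
    """
    angle_deg = math.degrees(angle_rad)
    pixels = ndimage.rotate(
        sample.pixels, angle_deg, reshape=False, order=1, mode="nearest"
    )
    mask = ndimage.rotate(
        sample.mask, angle_deg, reshape=False, order=0, mode="nearest"
    )
    return ImageSample(pixels, mask, sample.id, sample.split)


def random_rotate(
    sample: ImageSample,
    rng: np.random.Generator,
    rotation_range: tuple[float, float] = (-math.pi / 6, math.pi / 6),
) -> ImageSample:
    angle = rng.uniform(*rotation_range)
    return rotate(sample, angle)


def crop(sample: ImageSample, top: int, left: int, h: int, w: int) -> ImageSample:
    if top < 0 or left < 0 or top + h > sample.shape[0] or left + w > sample.shape[1]:
        raise ValueError("crop window exceeds image bounds")
    return ImageSample(
        sample.pixels[top : top + h, left : left + w].copy(),
        sample.mask[top : top + h, left : left + w].copy(),
        sample.id,
        sample.split,
    )


def random_crop(sample: ImageSample, rng: np.random.Generator, h: int, w: int) -> ImageSample:
    """Crop a random h x w window drawn uniformly over valid positions."""
    H, W = sample.shape
    if h > H or w > W:
        raise ValueError(f"crop {h}x{w} larger than image {H}x{W}")
    top = int(rng.integers(0, H - h + 1))
    left = int(rng.integers(0, W - w + 1))
    return crop(sample, top, left, h, w)


def augment(sample: ImageSample, config: AugmentConfig, rng: np.random.Generator) -> ImageSample:
    """Resize, then random flips, rotation and crop — the training-time chain."""
    out = resize(sample, config.target_h, config.target_w)
    out = random_flip(out, rng, config.flip_prob)
    out = random_rotate(out, rng, config.rotation_range)
    out = random_crop(out, rng, config.crop_h, config.crop_w)
    return out


def split_dataset(
    samples: list[ImageSample],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> list[ImageSample]:
    """Randomly tag samples train/val/test by the given fractions.

    Sizes are the floor of fraction * n for val and test, remainder to
    train; deterministic under ``seed``; returns new samples, original
    order preserved.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(samples)
    n_val = int(fractions[1] * n + 1e-12)
    n_test = int(fractions[2] * n + 1e-12)
    n_train = n - n_val - n_test
    if n < sum(1 for f in fractions if f > 0):
        raise ValueError(f"cannot split {n} samples into {fractions}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    tags = [""] * n
    for idx in order[:n_train]:
        tags[idx] = "train"
    for idx in order[n_train : n_train + n_val]:
        tags[idx] = "val"
    for idx in order[n_train + n_val :]:
        tags[idx] = "test"
    return [
        ImageSample(s.pixels.copy(), s.mask.copy(), s.id, tag)
        for s, tag in zip(samples, tags)
    ]
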