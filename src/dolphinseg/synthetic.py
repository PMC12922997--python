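"""Seeded generators for dermoscopy-like lesion images and fetal-MRI-like
multi-class images.

The binary generator draws a star-convex lesion (an ellipse whose radius
is modulated by a smooth periodic perturbation), darker than the skin
background, and corrupts the image the way dermoscopy photographs are
corrupted: thin dark hair arcs, a smooth multiplicative bias field, and
additive Gaussian noise.  In the noise-free limit the two intensity
levels are exactly separable, so thresholding at the contrast midpoint
recovers the mask — an analytic oracle the tests rely on.

The multi-class generator places a compact "brain"-like blob and an
elongated "placenta"-like crescent (labels 1 and 2) on a darker
background with the same noise/bias model.

Per-sample random streams are split from the master seed as
``default_rng([seed, index])``, so sample i does not depend on how many
samples are generated.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .samples import ImageSample, write_image_png, write_manifest, write_mask_png


@dataclasses.dataclass
class LesionSimConfig:
    """Binary lesion simulation settings.

    h, w : image size in pixels (>= 16)
    lesion_area_range : admissible mask area as a fraction of the image
    boundary_irregularity : amplitude of the smooth radial perturbation
        (0 gives an exact ellipse)
    contrast : foreground-minus-background intensity gap; negative makes
        the lesion darker, the dermoscopy convention
    noise_sigma : additive Gaussian noise level on the [0,1] scale
    hair_count : number of thin dark arcs drawn over the image
    bias_field_strength : amplitude of the smooth multiplicative field
    """

    h: int = 64
    w: int = 64
    lesion_area_range: tuple[float, float] = (0.05, 0.4)
    boundary_irregularity: float = 0.3
    contrast: float = -0.4
    noise_sigma: float = 0.05
    hair_count: int = 3
    bias_field_strength: float = 0.15
    background_level: float = 0.7

    def __post_init__(self) -> None:
        if self.h < 16 or self.w < 16:
            raise ValueError("image size must be at least 16x16")
        lo, hi = self.lesion_area_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("lesion_area_range must be an interval inside (0, 1)")
        if self.noise_sigma < 0 or self.boundary_irregularity < 0:
            raise ValueError("noise and irregularity amplitudes must be >= 0")
        if self.hair_count < 0 or self.bias_field_strength < 0:
            raise ValueError("hair_count and bias_field_strength must be >= 0")

    def noise_free(self) -> "LesionSimConfig":
        """Copy with noise, hairs and bias field switched off."""
        return dataclasses.replace(self, noise_sigma=0.0, hair_count=0,
                                   bias_field_strength=0.0)


@dataclasses.dataclass
class FetalSimConfig:
    """Two-organ multi-class simulation settings (labels: 1 brain, 2 placenta)."""

    h: int = 64
    w: int = 64
    background_level: float = 0.2
    brain_level: float = 0.8
    placenta_level: float = 0.55
    noise_sigma: float = 0.05
    bias_field_strength: float = 0.15

    def __post_init__(self) -> None:
        if self.h < 16 or self.w < 16:
            raise ValueError("image size must be at least 16x16")


def _star_convex_mask(config: LesionSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Ellipse with smoothly modulated radius; resampled until the area fits."""
    h, w = config.h, config.w
    lo, hi = config.lesion_area_range
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(100):
        frac = rng.uniform(lo, hi)
        aspect = rng.uniform(0.6, 1.0)
        area = frac * h * w
        ay = np.sqrt(area / np.pi * aspect)
        ax = np.sqrt(area / np.pi / aspect)
        cy = rng.uniform(0.35 * h, 0.65 * h)
        cx = rng.uniform(0.35 * w, 0.65 * w)
        u = (yy - cy) / ay
        v = (xx - cx) / ax
        rho = np.hypot(u, v)
        theta = np.arctan2(u, v)
        modulation = np.ones_like(theta)
        if config.boundary_irregularity > 0:
            for k in range(2, 6):
                amp = rng.normal(0.0, 1.0) / k
                phase = rng.uniform(0.0, 2.0 * np.pi)
                modulation = modulation + config.boundary_irregularity * amp * np.cos(
                    k * theta + phase
                )
        mask = (rho <= np.clip(modulation, 0.2, None)).astype(np.int64)
        if lo <= mask.mean() <= hi:
            return mask
    raise RuntimeError(
        f"could not draw a lesion with area in {config.lesion_area_range} "
        "after 100 attempts"
    )


def _bias_field(h: int, w: int, strength: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + strength * (low-frequency surface)."""
    if strength == 0.0:
        return np.ones((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    field = np.zeros((h, w))
    for _ in range(3):
        fy = rng.uniform(0.5, 1.5) * np.pi / h
        fx = rng.uniform(0.5, 1.5) * np.pi / w
        phase_y = rng.uniform(0, 2 * np.pi)
        phase_x = rng.uniform(0, 2 * np.pi)
        field += rng.uniform(-1.0, 1.0) * np.cos(fy * yy + phase_y) * np.cos(fx * xx + phase_x)
    field /= max(np.abs(field).max(), 1e-12)
    return 1.0 + strength * field


def _draw_hairs(pixels: np.ndarray, count: int, rng: np.random.Generator) -> np.ndarray:
    """Overlay thin dark circular arcs emulating hairs/skin lines."""
    h, w = pixels.shape
    out = pixels.copy()
    for _ in range(count):
        cy = rng.uniform(-0.5 * h, 1.5 * h)
        cx = rng.uniform(-0.5 * w, 1.5 * w)
        radius = rng.uniform(0.4 * min(h, w), 1.5 * min(h, w))
        theta0 = rng.uniform(0, 2 * np.pi)
        span = rng.uniform(0.5, 1.5)
        darkness = rng.uniform(0.2, 0.4)
        ts = np.linspace(theta0, theta0 + span, int(4 * radius * span) + 2)
        ys = np.round(cy + radius * np.sin(ts)).astype(int)
        xs = np.round(cx + radius * np.cos(ts)).astype(int)
        keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        out[ys[keep], xs[keep]] -= darkness
    return out


def generate_lesion_sample(config: LesionSimConfig, rng: np.random.Generator,
                           sample_id: str = "lesion") -> ImageSample:
    """One dermoscopy-like sample: star-convex lesion + hairs + bias + noise."""
    mask = _star_convex_mask(config, rng)
    pixels = config.background_level + config.contrast * mask.astype(float)
    pixels = pixels * _bias_field(config.h, config.w, config.bias_field_strength, rng)
    pixels = _draw_hairs(pixels, config.hair_count, rng)
    if config.noise_sigma > 0:
        pixels = pixels + rng.normal(0.0, config.noise_sigma, size=pixels.shape)
    return ImageSample(pixels, mask, id=sample_id)


def generate_fetal_sample(config: FetalSimConfig, rng: np.random.Generator,
                          sample_id: str = "fetal") -> ImageSample:
    """One multi-class sample: compact blob (1) and crescent (2), disjoint."""
    h, w = config.h, config.w
    yy, xx = np.mgrid[0:h, 0:w]
    # brain: compact ellipse in the left/upper half
    by = rng.uniform(0.25 * h, 0.45 * h)
    bx = rng.uniform(0.25 * w, 0.45 * w)
    br = rng.uniform(0.12, 0.18) * min(h, w)
    aspect = rng.uniform(0.8, 1.0)
    brain = (((yy - by) / (br * aspect)) ** 2 + ((xx - bx) / br) ** 2) <= 1.0
    # placenta: crescent = annulus sector around a center in the opposite corner
    py = rng.uniform(0.6 * h, 0.75 * h)
    px = rng.uniform(0.6 * w, 0.75 * w)
    r_out = rng.uniform(0.28, 0.38) * min(h, w)
    r_in = r_out * rng.uniform(0.55, 0.7)
    ang = np.arctan2(yy - py, xx - px)
    ang0 = rng.uniform(0, 2 * np.pi)
    width = rng.uniform(1.8, 2.6)
    dist = np.hypot(yy - py, xx - px)
    angular = np.abs(np.angle(np.exp(1j * (ang - ang0)))) <= width / 2
    placenta = (dist <= r_out) & (dist >= r_in) & angular
    placenta = placenta & ~brain  # construction guarantee: labels disjoint
    mask = np.zeros((h, w), dtype=np.int64)
    mask[placenta] = 2
    mask[brain] = 1
    pixels = np.full((h, w), config.background_level)
    pixels[brain] = config.brain_level
    pixels[placenta] = config.placenta_level
    pixels = pixels * _bias_field(h, w, config.bias_field_strength, rng)
    if config.noise_sigma > 0:
        pixels = pixels + rng.normal(0.0, config.noise_sigma, size=pixels.shape)
    return ImageSample(pixels, mask, id=sample_id)


def sample_rng(seed: int, index: int) -> np.random.Generator:
    """Per-sample stream split from the master seed (independent of n)."""
    return np.random.default_rng([seed, index])


def generate_samples(n: int, config: LesionSimConfig | FetalSimConfig,
                     seed: int) -> list[ImageSample]:
    """n samples from independent per-sample streams."""
    gen = (generate_lesion_sample if isinstance(config, LesionSimConfig)
           else generate_fetal_sample)
    return [gen(config, sample_rng(seed, i), sample_id=f"sample_{i:04d}")
            for i in range(n)]


def generate_dataset(n: int, config: LesionSimConfig | FetalSimConfig,
                     seed: int, out_dir: Path | str) -> Path:
    """Write n samples as PNG pairs plus a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in generate_samples(n, config, seed):
        image_rel = f"images/{sample.id}.png"
        mask_rel = f"masks/{sample.id}.png"
        write_image_png(out_dir / image_rel, sample.pixels)
        write_mask_png(out_dir / mask_rel, sample.mask)
        rows.append({"id": sample.id, "image_path": image_rel,
                     "mask_path": mask_rel, "split": sample.split})
    manifest = out_dir / "manifest.csv"
    write_manifest(manifest, rows)
    return manifest
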