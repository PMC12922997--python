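"""Image/mask sample container and PNG + manifest I/O.

A dataset on disk is a directory of grayscale PNG images, label-mask PNGs
and a manifest CSV with columns ``id,image_path,mask_path,split``.  Masks
are stored 8-bit with the binary convention 0/255 <-> 0/1; multi-class
masks store small consecutive label integers directly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

MANIFEST_COLUMNS = ["id", "image_path", "mask_path", "split"]
SPLITS = ("train", "val", "test", "unassigned")


@dataclasses.dataclass
class ImageSample:
    """One grayscale image with its label mask and provenance tag.

    Parameters
    ----------
    pixels : ndarray of float, shape (H, W)
        Image intensities on an arbitrary scale.
    mask : ndarray of int, shape (H, W)
        Label map; ``{0, 1}`` for binary segmentation (1 = foreground) or
        ``{0..K}`` for multi-class.
    id : str
        Stable identifier used in manifests and metric tables.
    split : str
        One of ``train``, ``val``, ``test``, ``unassigned``.
    """

    pixels: np.ndarray
    mask: np.ndarray
    id: str = ""
    split: str = "unassigned"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.pixels.shape != self.mask.shape:
            raise ValueError(
                f"pixels shape {self.pixels.shape} != mask shape {self.mask.shape}"
            )
        if self.split not in SPLITS:
            raise ValueError(f"unknown split {self.split!r}; expected one of {SPLITS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def copy(self) -> "ImageSample":
        return ImageSample(self.pixels.copy(), self.mask.copy(), self.id, self.split)


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Reduce an (H, W, C) array to (H, W) by channel-mean luminance."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim == 3:
        return pixels.mean(axis=2)
    if pixels.ndim != 2:
        raise ValueError(f"expected 2-D or 3-D pixel array, got shape {pixels.shape}")
    return pixels


def write_image_png(path: Path | str, pixels: np.ndarray) -> None:
    """Write intensities to 8-bit grayscale PNG, linearly mapping [min,max] -> [0,255]."""
    pixels = np.asarray(pixels, dtype=float)
    lo, hi = float(pixels.min()), float(pixels.max())
    scaled = np.zeros_like(pixels) if hi == lo else (pixels - lo) / (hi - lo)
    arr = np.round(scaled * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def write_mask_png(path: Path | str, mask: np.ndarray) -> None:
    """Write a label mask as 8-bit PNG: binary masks as {0,255}, multi-class as labels."""
    mask = np.asarray(mask)
    labels = np.unique(mask)
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("mask must be an integer label map")
    if labels.max(initial=0) <= 1:
        arr = (mask * 255).astype(np.uint8)
    else:
        arr = mask.astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def write_prob_png(path: Path | str, prob: np.ndarray) -> None:
    """Write a probability map in [0,1] as 16-bit PNG (value = round(p * 65535))."""
    prob = np.asarray(prob, dtype=float)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map must lie in [0, 1]")
    arr = np.round(prob * 65535.0).astype(np.uint16)
    Image.fromarray(arr).save(path, format="PNG")


def read_image_png(path: Path | str) -> np.ndarray:
    img = Image.open(path)
    arr = np.asarray(img, dtype=float)
    if arr.ndim == 3:
        arr = to_grayscale(arr)
    if img.mode == "L":
        arr = arr / 255.0
    elif img.mode in ("I", "I;16"):
        arr = arr / 65535.0
    return arr


def read_mask_png(path: Path | str) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    labels = np.unique(arr)
    if set(labels.tolist()) <= {0, 255}:
        return (arr > 0).astype(np.int64)
    return arr.astype(np.int64)


def read_prob_png(path: Path | str) -> np.ndarray:
    arr = np.asarray(Image.open(path), dtype=float)
    return arr / 65535.0


def write_manifest(path: Path | str, rows: list[dict]) -> None:
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path: Path | str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    return df


def load_dataset(manifest_path: Path | str, split: str | None = None) -> list[ImageSample]:
    """Load all samples listed in a manifest, optionally filtered by split tag."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    root = manifest_path.parent
    samples = []
    for _, row in df.iterrows():
        tag = row["split"] or "unassigned"
        if split is not None and tag != split:
            continue
        image_path = root / row["image_path"]
        mask_path = root / row["mask_path"]
        samples.append(
            ImageSample(
                pixels=read_image_png(image_path),
                mask=read_mask_png(mask_path),
                id=row["id"],
                split=tag,
            )
        )
    return samples
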