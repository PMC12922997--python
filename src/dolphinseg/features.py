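"""Block partition of an image and per-block feature vectors.

The image is edge-padded to a multiple of the block size and cut into a
raster-ordered grid of non-overlapping blocks; each block yields a fixed
feature vector combining intensity statistics, gradient-magnitude
statistics and a ridge (principal Hessian eigenvalue) response.  The
resulting ordered sequence is the recurrent model's input; an alternative
raw mode flattens block pixels directly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .samples import ImageSample

INTENSITY_NAMES = ["int_mean", "int_std", "int_min", "int_max"]
GRADIENT_NAMES = ["grad_mean", "grad_std"]
RIDGE_NAMES = ["ridge_mean", "ridge_max"]


@dataclasses.dataclass(frozen=True)
class BlockGrid:
    """Raster-ordered non-overlapping block decomposition of an image.

    Block t (row-major) covers pixel window
    rows [ (t // cols) * block_h, ... ) x cols [ (t % cols) * block_w, ... )
    of the edge-padded image; ``image_h``/``image_w`` record the original
    (unpadded) size so predictions can be mapped back.
    """

    block_h: int
    block_w: int
    rows: int
    cols: int
    image_h: int
    image_w: int

    @property
    def n_blocks(self) -> int:
        return self.rows * self.cols

    def window(self, t: int) -> tuple[slice, slice]:
        """Half-open pixel window of block t in the padded image."""
        r, c = divmod(t, self.cols)
        return (
            slice(r * self.block_h, (r + 1) * self.block_h),
            slice(c * self.block_w, (c + 1) * self.block_w),
        )


@dataclasses.dataclass
class FeatureSequence:
    """Ordered per-block feature vectors plus the grid geometry."""

    vectors: np.ndarray  # (T, d)
    grid: BlockGrid
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] < 1:
            raise ValueError("vectors must be a (T, d) array with T >= 1")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("feature vectors must be finite")
        if self.vectors.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match vector dimension")

    @property
    def T(self) -> int:
        return self.vectors.shape[0]

    @property
    def d(self) -> int:
        return self.vectors.shape[1]


@dataclasses.dataclass
class FeatureConfig:
    """Featurization settings: block size and feature mode."""

    block_h: int = 8
    block_w: int = 8
    mode: str = "handcrafted"  # or "raw": flattened block pixels

    def __post_init__(self) -> None:
        if self.block_h < 1 or self.block_w < 1:
            raise ValueError("block dims must be >= 1")
        if self.mode not in ("handcrafted", "raw"):
            raise ValueError(f"unknown feature mode {self.mode!r}")

    @property
    def dim(self) -> int:
        if self.mode == "raw":
            return self.block_h * self.block_w
        return len(INTENSITY_NAMES) + len(GRADIENT_NAMES) + len(RIDGE_NAMES)


def pad_to_grid(pixels: np.ndarray, block_h: int, block_w: int) -> tuple[np.ndarray, BlockGrid]:
    """Edge-pad so both dims are multiples of the block size."""
    h, w = pixels.shape
    rows = -(-h // block_h)
    cols = -(-w // block_w)
    padded = np.pad(pixels, ((0, rows * block_h - h), (0, cols * block_w - w)), mode="edge")
    grid = BlockGrid(block_h, block_w, rows, cols, h, w)
    return padded, grid


def partition_blocks(
    pixels: np.ndarray, block_h: int, block_w: int
) -> tuple[BlockGrid, list[np.ndarray]]:
    """Cut the (edge-padded) image into raster-ordered block_h x block_w tiles."""
    if block_h < 1 or block_w < 1:
        raise ValueError("block dims must be >= 1")
    padded, grid = pad_to_grid(np.asarray(pixels, dtype=float), block_h, block_w)
    blocks = [padded[grid.window(t)] for t in range(grid.n_blocks)]
    return grid, blocks


def intensity_features(block: np.ndarray) -> np.ndarray:
    """(mean, population std, min, max) of block intensities."""
    block = np.asarray(block, dtype=float)
    return np.array([block.mean(), block.std(), block.min(), block.max()])


def _gradients(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # np.gradient: central differences inside, one-sided at edges
    block = np.asarray(block, dtype=float)
    if block.shape[0] == 1:
        gy = np.zeros_like(block)
    else:
        gy = np.gradient(block, axis=0)
    if block.shape[1] == 1:
        gx = np.zeros_like(block)
    else:
        gx = np.gradient(block, axis=1)
    return gy, gx


def gradient_features(block: np.ndarray) -> np.ndarray:
    """(mean, population std) of the Euclidean gradient magnitude."""
    gy, gx = _gradients(block)
    mag = np.hypot(gy, gx)
    return np.array([mag.mean(), mag.std()])


def ridge_features(block: np.ndarray) -> np.ndarray:
    """(mean, max) of the principal Hessian eigenvalue magnitude.

    The per-pixel 2x2 Hessian comes from finite differences of the
    finite-difference gradients; the ridge response is the absolute value
    of the larger-magnitude eigenvalue, which highlights tubular
    structures such as hairs and vessels.
    """
    gy, gx = _gradients(block)
    hyy, hyx = _gradients(gy)
    hxy, hxx = _gradients(gx)
    hoff = 0.5 * (hyx + hxy)
    # eigenvalues of [[hyy, hoff], [hoff, hxx]]
    tr = hyy + hxx
    disc = np.sqrt(np.maximum(0.25 * (hyy - hxx) ** 2 + hoff**2, 0.0))
    lam1 = 0.5 * tr + disc
    lam2 = 0.5 * tr - disc
    principal = np.where(np.abs(lam1) >= np.abs(lam2), lam1, lam2)
    mag = np.abs(principal)
    return np.array([mag.mean(), mag.max()])


def block_features(block: np.ndarray) -> np.ndarray:
    """Concatenated (intensity, gradient, ridge) feature vector, d = 8."""
    return np.concatenate(
        [intensity_features(block), gradient_features(block), ridge_features(block)]
    )


def extract_sequence(sample: ImageSample, config: FeatureConfig | None = None) -> FeatureSequence:
    """Featurize a (normalized) sample into the model's input sequence."""
    config = config or FeatureConfig()
    grid, blocks = partition_blocks(sample.pixels, config.block_h, config.block_w)
    if config.mode == "raw":
        vectors = np.stack([b.ravel() for b in blocks])
        names = [f"px_{i}" for i in range(config.dim)]
    else:
        vectors = np.stack([block_features(b) for b in blocks])
        names = INTENSITY_NAMES + GRADIENT_NAMES + RIDGE_NAMES
    return FeatureSequence(vectors, grid, names)


def block_label_stats(mask: np.ndarray, grid: BlockGrid) -> tuple[np.ndarray, np.ndarray]:
    """Per-block (foreground pixel count, pixel count) within the unpadded image.

    Used by the training loss to relate block predictions to pixel truth.
    """
    counts = np.zeros(grid.n_blocks)
    sizes = np.zeros(grid.n_blocks)
    mask = np.asarray(mask)
    for t in range(grid.n_blocks):
        rs, cs = grid.window(t)
        rs = slice(rs.start, min(rs.stop, grid.image_h))
        cs = slice(cs.start, min(cs.stop, grid.image_w))
        if rs.start >= grid.image_h or cs.start >= grid.image_w:
            continue
        window = mask[rs, cs]
        counts[t] = window.sum()
        sizes[t] = window.size
    return counts, sizes
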