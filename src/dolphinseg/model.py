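"""The block-sequence segmenter: model object, exact-gradient training, results.

`BlockSequenceSegmenter` is built from training/validation samples and a
`Hyperparameters` configuration; `.fit()` minimises the soft Dice loss of
the predicted probability map against the pixel truth by plain mini-batch
gradient descent with exact backpropagation through the prediction head,
the attention pooling, both LSTM recurrences, and the block-to-pixel
upsampling operator.  `.fit()` returns a `SegmenterResults` carrying the
trained parameters, the per-epoch history, and prediction/evaluation/
persistence methods.

The prediction head emits one probability per block; the probability map
is that grid upsampled to pixel resolution, bilinearly by default
("nearest" reproduces the hard per-block broadcast), and the binary mask
is the map thresholded at exactly 0.5 (ties to foreground).
"""

from __future__ import annotations

import dataclasses
import io
import json
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from . import metrics as _metrics
from .features import BlockGrid, FeatureConfig, block_label_stats, extract_sequence
from .lstm import (
    LSTMParams,
    attention_pool,
    bilstm_states,
    head_logits,
    init_lstm_params,
    lstm_backward,
    sigmoid,
)
from .samples import ImageSample

THRESHOLD = 0.5  # fixed decision threshold; ties go to foreground


@dataclasses.dataclass
class Hyperparameters:
    """Trainable-model settings; the first four span the tuning search space.

    learning_rate : gradient-descent step size (search prior: log-uniform
        on [1e-4, 1e-2])
    hidden_units  : LSTM state size per direction (search range 32-256 at
        full scale; desk-scale configurations go as low as 4)
    dropout_rate  : inverted-dropout probability on the concatenated
        states during training (search range 0.1-0.5)
    batch_size    : images per gradient step (search range 8-64)
    epochs        : passes over the training set
    """

    learning_rate: float = 3e-3
    hidden_units: int = 16
    dropout_rate: float = 0.1
    batch_size: int = 8
    epochs: int = 150

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class BiLSTMModel:
    """All trainable parameters of the bidirectional segmenter."""

    forward: LSTMParams
    backward: LSTMParams
    Wa: np.ndarray  # (2*hidden,) attention scoring vector
    wo: np.ndarray  # (4*hidden,) head weights over [H_t | context]
    bo: float
    dropout_rate: float = 0.0
    concat_cell_states: bool = False
    threshold: float = THRESHOLD

    def __post_init__(self) -> None:
        nh = self.forward.hidden
        self.Wa = np.asarray(self.Wa, dtype=float).reshape(-1)
        self.wo = np.asarray(self.wo, dtype=float).reshape(-1)
        if self.backward.hidden != nh or self.backward.d != self.forward.d:
            raise ValueError("forward/backward parameter shapes disagree")
        if self.Wa.shape != (2 * nh,) or self.wo.shape != (4 * nh,):
            raise ValueError("attention/head weight shapes inconsistent with hidden size")
        if self.threshold != THRESHOLD:
            raise ValueError("decision threshold is fixed at 0.5")

    @property
    def hidden(self) -> int:
        return self.forward.hidden

    @property
    def d(self) -> int:
        return self.forward.d

    # -- flat parameter vector (used by the finite-difference gradient check)
    def _arrays(self) -> list[np.ndarray]:
        return [self.forward.W, self.forward.U, self.forward.b,
                self.backward.W, self.backward.U, self.backward.b,
                self.Wa, self.wo]

    def to_vector(self) -> np.ndarray:
        return np.concatenate([a.ravel() for a in self._arrays()] + [[self.bo]])

    def from_vector(self, vec: np.ndarray) -> "BiLSTMModel":
        out = self.copy()
        pos = 0
        for a in out._arrays():
            a[...] = vec[pos : pos + a.size].reshape(a.shape)
            pos += a.size
        out.bo = float(vec[pos])
        return out

    def copy(self) -> "BiLSTMModel":
        return BiLSTMModel(
            self.forward.copy(), self.backward.copy(), self.Wa.copy(),
            self.wo.copy(), self.bo, self.dropout_rate, self.concat_cell_states,
        )


def init_model(d: int, hidden: int, rng: np.random.Generator,
               dropout_rate: float = 0.0, scale: float = 0.08) -> BiLSTMModel:
    """Seeded uniform(-scale, scale) initialisation, forget biases offset +1."""
    fwd = init_lstm_params(d, hidden, rng, scale=scale)
    bwd = init_lstm_params(d, hidden, rng, scale=scale)
    Wa = rng.uniform(-scale, scale, size=2 * hidden)
    wo = rng.uniform(-scale, scale, size=4 * hidden)
    bo = float(rng.uniform(-scale, scale))
    return BiLSTMModel(fwd, bwd, Wa, wo, bo, dropout_rate=dropout_rate)


# ---------------------------------------------------------------------------
# block-grid -> pixel upsampling

_UPSAMPLER_CACHE: dict[tuple, sparse.csr_matrix] = {}


def build_upsampler(grid: BlockGrid, mode: str = "bilinear") -> sparse.csr_matrix:
    """Sparse (H*W, T) operator mapping block values to pixel values.

    "nearest" broadcasts each block's value over its own pixels;
    "bilinear" interpolates between block centers (align-corners-false:
    pixel i sits at grid coordinate (i + 0.5)/block - 0.5, edge-clamped).
    The transpose is the exact adjoint used during backpropagation.
    """
    key = (grid.block_h, grid.block_w, grid.rows, grid.cols,
           grid.image_h, grid.image_w, mode)
    if key in _UPSAMPLER_CACHE:
        return _UPSAMPLER_CACHE[key]
    H, W = grid.image_h, grid.image_w
    if mode == "nearest":
        ry = np.minimum(np.arange(H) // grid.block_h, grid.rows - 1)
        cx = np.minimum(np.arange(W) // grid.block_w, grid.cols - 1)
        src = (ry[:, None] * grid.cols + cx[None, :]).ravel()
        M = sparse.csr_matrix(
            (np.ones(H * W), (np.arange(H * W), src)), shape=(H * W, grid.n_blocks)
        )
    elif mode == "bilinear":
        gy = np.clip((np.arange(H) + 0.5) / grid.block_h - 0.5, 0, grid.rows - 1)
        gx = np.clip((np.arange(W) + 0.5) / grid.block_w - 0.5, 0, grid.cols - 1)
        y0 = np.floor(gy).astype(int)
        x0 = np.floor(gx).astype(int)
        y1 = np.minimum(y0 + 1, grid.rows - 1)
        x1 = np.minimum(x0 + 1, grid.cols - 1)
        wy = gy - y0
        wx = gx - x0
        rows_idx, cols_idx, vals = [], [], []
        pix = np.arange(H * W)
        WY, WX = np.meshgrid(wy, wx, indexing="ij")
        Y0, X0 = np.meshgrid(y0, x0, indexing="ij")
        Y1, X1 = np.meshgrid(y1, x1, indexing="ij")
        for yy, xx, ww in (
            (Y0, X0, (1 - WY) * (1 - WX)),
            (Y0, X1, (1 - WY) * WX),
            (Y1, X0, WY * (1 - WX)),
            (Y1, X1, WY * WX),
        ):
            rows_idx.append(pix)
            cols_idx.append((yy * grid.cols + xx).ravel())
            vals.append(ww.ravel())
        M = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows_idx), np.concatenate(cols_idx))),
            shape=(H * W, grid.n_blocks),
        )
    else:
        raise ValueError(f"unknown upsample mode {mode!r}")
    M.sum_duplicates()
    _UPSAMPLER_CACHE[key] = M
    return M


# ---------------------------------------------------------------------------
# forward / backward through the whole stack


def _forward(model: BiLSTMModel, X: np.ndarray, drop_mask: np.ndarray | None = None):
    """Full forward pass on a batch X (B, T, d); returns intermediates."""
    H, cache_f, cache_b = bilstm_states(
        X, model.forward, model.backward, model.concat_cell_states
    )
    if drop_mask is not None:
        H = H * drop_mask
    alpha, context = attention_pool(H, model.Wa)
    z = head_logits(H, context, model.wo, model.bo)
    p = sigmoid(z)
    return {"H": H, "alpha": alpha, "context": context, "z": z, "p": p,
            "cache_f": cache_f, "cache_b": cache_b, "drop_mask": drop_mask}


def predict_probs(model: BiLSTMModel, X: np.ndarray) -> np.ndarray:
    """Per-block probabilities (B, T) without dropout."""
    return _forward(model, X)["p"]


def probs_to_map(p: np.ndarray, grid: BlockGrid, upsample: str = "bilinear") -> np.ndarray:
    """Upsample block probabilities (T,) or (B, T) to pixel maps."""
    M = build_upsampler(grid, upsample)
    single = p.ndim == 1
    pb = p[None] if single else p
    flat = (M @ pb.T).T
    maps = flat.reshape(pb.shape[0], grid.image_h, grid.image_w)
    return maps[0] if single else maps


def predict(sample: ImageSample, model: BiLSTMModel,
            feature_config: FeatureConfig | None = None,
            upsample: str = "bilinear") -> tuple[np.ndarray, np.ndarray]:
    """Probability map and thresholded binary mask for one sample.

    The sample is expected normalized; features follow ``feature_config``.
    """
    from .preprocess import zscore_normalize  # local import avoids a cycle

    seq = extract_sequence(zscore_normalize(sample), feature_config)
    if seq.d != model.d:
        raise ValueError(f"feature dim {seq.d} != model input dim {model.d}")
    p = predict_probs(model, seq.vectors[None])[0]
    prob_map = probs_to_map(p, seq.grid, upsample)
    mask = (prob_map >= model.threshold).astype(np.int64)
    return prob_map, mask


def batch_loss_and_grads(model: BiLSTMModel, X: np.ndarray, masks: np.ndarray,
                         grid: BlockGrid, upsample: str = "bilinear",
                         eps: float = 1.0, drop_mask: np.ndarray | None = None):
    """Mean soft Dice loss over the batch and exact parameter gradients.

    X : (B, T, d) feature sequences; masks : (B, H, W) binary truth for
    the common grid.  Returns (loss, grads) where grads mirrors
    `BiLSTMModel.to_vector` ordering.
    """
    B, T, _ = X.shape
    M = build_upsampler(grid, upsample)
    fwd = _forward(model, X, drop_mask)
    H, alpha, context, p = fwd["H"], fwd["alpha"], fwd["context"], fwd["p"]
    nh2 = H.shape[-1]

    Y = masks.reshape(B, -1).astype(float)
    P = (M @ p.T).T  # (B, H*W)
    inter = (Y * P).sum(axis=1)
    sums = Y.sum(axis=1) + P.sum(axis=1)
    num = 2.0 * inter + eps
    den = sums + eps
    losses = 1.0 - num / den
    loss = float(losses.mean())
    if not np.isfinite(loss):
        raise FloatingPointError(f"non-finite training loss: per-image {losses}")

    # dL/dP, averaged over the batch
    dP = (num[:, None] - 2.0 * Y * den[:, None]) / den[:, None] ** 2 / B
    dp = (M.T @ dP.T).T  # (B, T)
    dz = dp * p * (1.0 - p)

    wo_H = model.wo[:nh2]
    wo_c = model.wo[nh2:]
    dwo = np.concatenate([
        np.einsum("bt,bth->h", dz, H),
        dz.sum(axis=1) @ context,
    ])
    dbo = float(dz.sum())
    dH = dz[..., None] * wo_H
    dcontext = dz.sum(axis=1)[:, None] * wo_c  # (B, 2*hidden)

    # attention backward: context = sum_t alpha_t H_t, alpha = softmax(H Wa)
    dalpha = np.einsum("bth,bh->bt", H, dcontext)
    dH += alpha[..., None] * dcontext[:, None, :]
    ds = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
    dWa = np.einsum("bt,bth->h", ds, H)
    dH += ds[..., None] * model.Wa

    if fwd["drop_mask"] is not None:
        dH = dH * fwd["drop_mask"]

    nh = model.hidden
    dHf, dHb = dH[..., :nh], dH[..., nh:]
    zeros = np.zeros_like(dHf)
    if model.concat_cell_states:
        fW, fU, fb, _ = lstm_backward(fwd["cache_f"], model.forward, zeros, dHf)
        bW, bU, bb, _ = lstm_backward(fwd["cache_b"], model.backward, zeros, dHb[:, ::-1])
    else:
        fW, fU, fb, _ = lstm_backward(fwd["cache_f"], model.forward, dHf)
        bW, bU, bb, _ = lstm_backward(fwd["cache_b"], model.backward, dHb[:, ::-1])

    grads = np.concatenate([a.ravel() for a in
                            (fW, fU, fb, bW, bU, bb, dWa, dwo)] + [[dbo]])
    return loss, grads


# ---------------------------------------------------------------------------
# training


def _stack_split(samples: list[ImageSample], feature_config: FeatureConfig):
    """Featurize samples sharing one image shape into (X, masks, grid)."""
    from .preprocess import zscore_normalize

    shapes = {s.shape for s in samples}
    if len(shapes) != 1:
        raise ValueError(
            f"samples must share one image shape for batched training; got {sorted(shapes)}"
        )
    seqs = [extract_sequence(zscore_normalize(s), feature_config) for s in samples]
    X = np.stack([seq.vectors for seq in seqs])
    masks = np.stack([s.mask for s in samples]).astype(float)
    return X, masks, seqs[0].grid


def _batch_dsc(p: np.ndarray, masks: np.ndarray, grid: BlockGrid, upsample: str) -> float:
    """Mean Dice (%) of thresholded probability maps against truth."""
    maps = probs_to_map(p, grid, upsample)
    pred = maps >= THRESHOLD
    truth = masks.astype(bool)
    tp = (pred & truth).sum(axis=(1, 2))
    denom = pred.sum(axis=(1, 2)) + truth.sum(axis=(1, 2))
    dice = np.where(denom > 0, 2.0 * tp / np.maximum(denom, 1), 1.0)
    return float(dice.mean() * 100.0)


class _SGD:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, vec: np.ndarray, grads: np.ndarray) -> None:
        vec -= self.lr * grads


class _Momentum:
    def __init__(self, lr: float, momentum: float = 0.9):
        self.lr = lr
        self.momentum = momentum
        self.v: np.ndarray | None = None

    def step(self, vec: np.ndarray, grads: np.ndarray) -> None:
        if self.v is None:
            self.v = np.zeros_like(vec)
        self.v = self.momentum * self.v - self.lr * grads
        vec += self.v


class _Adam:
    def __init__(self, lr: float, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m: np.ndarray | None = None
        self.v: np.ndarray | None = None
        self.t = 0

    def step(self, vec: np.ndarray, grads: np.ndarray) -> None:
        if self.m is None:
            self.m = np.zeros_like(vec)
            self.v = np.zeros_like(vec)
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grads
        self.v = self.b2 * self.v + (1 - self.b2) * grads**2
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        vec -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


_OPTIMIZERS = {"sgd": _SGD, "momentum": _Momentum, "adam": _Adam}


def train(hp: Hyperparameters, train_set: list[ImageSample],
          val_set: list[ImageSample], seed: int,
          feature_config: FeatureConfig | None = None,
          upsample: str = "bilinear", eps: float = 1.0,
          optimizer: str = "adam"):
    """Fit a model by mini-batch gradient descent on the soft Dice loss.

    ``optimizer`` selects the update rule ("sgd" for plain descent,
    "momentum", or "adam", the default); all three are deterministic, so
    a run is exactly reproducible under ``seed``.  Validation Dice is
    tracked each epoch and the best-validation parameters are the ones
    returned (falling back to final-epoch parameters when there is no
    validation set).  Returns (model, history dict).
    """
    if not train_set:
        raise ValueError("train_set must contain at least one sample")
    feature_config = feature_config or FeatureConfig()
    rng = np.random.default_rng(seed)
    Xtr, Mtr, grid = _stack_split(train_set, feature_config)
    if val_set:
        Xva, Mva, grid_va = _stack_split(val_set, feature_config)
    model = init_model(feature_config.dim, hp.hidden_units, rng,
                       dropout_rate=hp.dropout_rate)
    vec = model.to_vector()
    n = len(train_set)
    history = {"train_loss": [], "val_dsc": [], "best_epoch": None}
    best_vec = vec.copy()
    best_dsc = -np.inf
    keep = 1.0 - hp.dropout_rate
    if optimizer not in _OPTIMIZERS:
        raise ValueError(f"unknown optimizer {optimizer!r}")
    opt = _OPTIMIZERS[optimizer](hp.learning_rate)
    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            drop = None
            if hp.dropout_rate > 0.0:
                drop = (rng.random((len(idx), Xtr.shape[1], 2 * hp.hidden_units))
                        < keep) / keep
            loss, grads = batch_loss_and_grads(
                model, Xtr[idx], Mtr[idx], grid, upsample, eps, drop
            )
            opt.step(vec, grads)
            model = model.from_vector(vec)
            epoch_losses.append(loss)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if val_set:
            p = predict_probs(model, Xva)
            val_dsc = _batch_dsc(p, Mva, grid_va, upsample)
        else:
            val_dsc = float("nan")
        history["val_dsc"].append(val_dsc)
        if val_set and val_dsc > best_dsc:
            best_dsc = val_dsc
            best_vec = vec.copy()
            history["best_epoch"] = epoch
    if not val_set:
        best_vec = vec
        history["best_epoch"] = hp.epochs - 1
    return model.from_vector(best_vec), history


# ---------------------------------------------------------------------------
# statsmodels-style surface


class BlockSequenceSegmenter:
    """Bidirectional-LSTM segmentation model over block sequences.

    Parameters
    ----------
    train_samples, val_samples : lists of ImageSample (a common image
        shape per list; resize beforehand if needed).
    hyperparameters : Hyperparameters, optional.
    feature_config : FeatureConfig, optional (block size and
        handcrafted-vs-raw featurization).
    upsample : "bilinear" (default) or "nearest" block-to-pixel mapping.
    dice_eps : smoothing constant of the soft Dice loss.

    Examples
    --------
    >>> seg = BlockSequenceSegmenter(train, val, Hyperparameters(epochs=50))
    >>> res = seg.fit(seed=1)
    >>> prob, mask = res.predict(test[0])
    """

    def __init__(self, train_samples: list[ImageSample],
                 val_samples: list[ImageSample] | None = None,
                 hyperparameters: Hyperparameters | None = None,
                 feature_config: FeatureConfig | None = None,
                 upsample: str = "bilinear", dice_eps: float = 1.0,
                 optimizer: str = "adam"):
        if upsample not in ("bilinear", "nearest"):
            raise ValueError(f"unknown upsample mode {upsample!r}")
        self.train_samples = list(train_samples)
        self.val_samples = list(val_samples or [])
        self.hyperparameters = hyperparameters or Hyperparameters()
        self.feature_config = feature_config or FeatureConfig()
        self.upsample = upsample
        self.dice_eps = dice_eps
        self.optimizer = optimizer

    @classmethod
    def from_manifest(cls, manifest_path, **kwargs) -> "BlockSequenceSegmenter":
        """Build from a dataset manifest using its train/val split tags."""
        from .samples import load_dataset

        return cls(load_dataset(manifest_path, "train"),
                   load_dataset(manifest_path, "val"), **kwargs)

    def fit(self, seed: int = 0) -> "SegmenterResults":
        model, history = train(
            self.hyperparameters, self.train_samples, self.val_samples, seed,
            self.feature_config, self.upsample, self.dice_eps, self.optimizer,
        )
        return SegmenterResults(model, history, self.hyperparameters,
                                self.feature_config, self.upsample, seed)


class SegmenterResults:
    """Fitted parameters, training history and evaluation utilities."""

    def __init__(self, model: BiLSTMModel, history: dict,
                 hyperparameters: Hyperparameters,
                 feature_config: FeatureConfig, upsample: str, seed: int):
        self.model = model
        self.history = history
        self.hyperparameters = hyperparameters
        self.feature_config = feature_config
        self.upsample = upsample
        self.seed = seed

    def predict(self, sample: ImageSample) -> tuple[np.ndarray, np.ndarray]:
        """(probability map, binary mask) for one sample."""
        return predict(sample, self.model, self.feature_config, self.upsample)

    def evaluate(self, samples: list[ImageSample]) -> pd.DataFrame:
        """Per-image metric table (DSC/JSI/accuracy/precision/recall/F1/HD)."""
        pairs = [(s.id, self.predict(s)[1], np.asarray(s.mask)) for s in samples]
        return _metrics.evaluate_table(pairs)

    def summary(self) -> str:
        """Plain-text fit summary table."""
        hp = self.hyperparameters
        hist = self.history
        final_loss = hist["train_loss"][-1] if hist["train_loss"] else float("nan")
        best_epoch = hist.get("best_epoch")
        best_dsc = (hist["val_dsc"][best_epoch]
                    if best_epoch is not None and hist["val_dsc"] else float("nan"))
        lines = [
            "Block-sequence Bi-LSTM segmenter".center(58),
            "=" * 58,
            f"{'hidden units':<28}{hp.hidden_units:>30}",
            f"{'learning rate':<28}{hp.learning_rate:>30.6g}",
            f"{'dropout rate':<28}{hp.dropout_rate:>30.3g}",
            f"{'batch size':<28}{hp.batch_size:>30}",
            f"{'epochs':<28}{hp.epochs:>30}",
            f"{'feature mode':<28}{self.feature_config.mode:>30}",
            f"{'block size':<28}{f'{self.feature_config.block_h}x{self.feature_config.block_w}':>30}",
            f"{'upsample':<28}{self.upsample:>30}",
            f"{'seed':<28}{self.seed:>30}",
            "-" * 58,
            f"{'final train Dice loss':<28}{final_loss:>30.4f}",
            f"{'best epoch (val DSC)':<28}{str(best_epoch):>30}",
            f"{'best val DSC (%)':<28}{best_dsc:>30.2f}",
            "=" * 58,
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Training-loss and validation-Dice curves on twin axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = np.arange(1, len(self.history["train_loss"]) + 1)
        ax.plot(epochs, self.history["train_loss"], color="tab:blue",
                label="train Dice loss")
        ax.set_xlabel("epoch")
        ax.set_ylabel("train Dice loss", color="tab:blue")
        if self.history["val_dsc"] and np.isfinite(self.history["val_dsc"][0]):
            ax2 = ax.twinx()
            ax2.plot(epochs, self.history["val_dsc"], color="tab:orange",
                     label="val DSC (%)")
            ax2.set_ylabel("val DSC (%)", color="tab:orange")
        return ax

    def plot_prediction(self, sample: ImageSample, ax=None):
        """Image with predicted (red) and reference (green) mask contours."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        prob, mask = self.predict(sample)
        ax.imshow(sample.pixels, cmap="gray")
        ax.contour(mask, levels=[0.5], colors="red", linewidths=1.0)
        ax.contour(np.asarray(sample.mask) > 0, levels=[0.5], colors="lime",
                   linewidths=1.0)
        ax.set_title(sample.id)
        ax.set_axis_off()
        return ax

    # -- persistence: a zip archive of .npy arrays plus a JSON header
    _ARRAY_KEYS = ("fW", "fU", "fb", "bW", "bU", "bb", "Wa", "wo")

    def save(self, path: Path | str) -> None:
        m = self.model
        arrays = dict(zip(self._ARRAY_KEYS,
                          (m.forward.W, m.forward.U, m.forward.b,
                           m.backward.W, m.backward.U, m.backward.b,
                           m.Wa, m.wo)))
        header = {
            "bo": m.bo,
            "dropout_rate": m.dropout_rate,
            "concat_cell_states": m.concat_cell_states,
            "hidden": m.hidden,
            "d": m.d,
            "seed": self.seed,
            "upsample": self.upsample,
            "hyperparameters": self.hyperparameters.as_dict(),
            "feature_config": dataclasses.asdict(self.feature_config),
            "history": self.history,
        }
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            def put(name: str, data) -> None:
                # fixed timestamp so identical runs give identical bytes
                info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
                info.compress_type = zipfile.ZIP_DEFLATED
                zf.writestr(info, data)

            put("header.json", json.dumps(header, sort_keys=True, indent=2))
            for key, arr in arrays.items():
                buf = io.BytesIO()
                np.save(buf, arr)
                put(f"{key}.npy", buf.getvalue())

    @classmethod
    def load(cls, path: Path | str) -> "SegmenterResults":
        with zipfile.ZipFile(path) as zf:
            header = json.loads(zf.read("header.json"))
            arrays = {key: np.load(io.BytesIO(zf.read(f"{key}.npy")))
                      for key in cls._ARRAY_KEYS}
        model = BiLSTMModel(
            LSTMParams(arrays["fW"], arrays["fU"], arrays["fb"]),
            LSTMParams(arrays["bW"], arrays["bU"], arrays["bb"]),
            arrays["Wa"], arrays["wo"], header["bo"],
            dropout_rate=header["dropout_rate"],
            concat_cell_states=header["concat_cell_states"],
        )
        return cls(model, header["history"],
                   Hyperparameters(**header["hyperparameters"]),
                   FeatureConfig(**header["feature_config"]),
                   header["upsample"], header["seed"])
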