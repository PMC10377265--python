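"""Compact trainable CNN and the optimizer's fitness function.

The classifier built from a :class:`~mammober.space.CNNConfig` is three
conv blocks (conv with "same" padding -> activation -> 2x2 max-pool),
flatten, one dense hidden layer, dropout, and a 2-unit softmax head,
trained with plain stochastic gradient descent on cross-entropy. It is
implemented directly on numpy arrays (im2col convolutions, explicit
backprop), which at the image sizes used here — raw lesions or extracted
feature vectors reshaped into small square maps — trains in well under a
second per epoch on one CPU core.

``fitness_for`` is the bridge to the optimizer: decode a unit-hypercube
position into a configuration, estimate its quality by stratified k-fold
cross-validation on the training split, and return 1 - mean validation
accuracy (a minimization objective). Identical decoded configurations hit
a cache, which matters because a converging population re-proposes the
same grid point many times.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .space import CNNConfig, SearchSpace, decode, default_space

__all__ = ["TrainProtocol", "TrainedModel", "build_model", "train",
           "predict", "save_model", "load_model", "FitnessEvaluator",
           "fitness_for", "vectors_to_maps"]

_LRELU_SLOPE = 0.01
_ELU_ALPHA = 1.0


@dataclass(frozen=True)
class TrainProtocol:
    epochs: int = 10
    cv_folds: int = 5
    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _activation(name: str):
    if name == "relu":
        return (lambda x: np.maximum(x, 0.0),
                lambda x, y: (x > 0.0).astype(x.dtype))
    if name == "lrelu":
        return (lambda x: np.where(x > 0.0, x, _LRELU_SLOPE * x),
                lambda x, y: np.where(x > 0.0, 1.0, _LRELU_SLOPE).astype(x.dtype))
    if name == "elu":
        # exp argument clamped at 0: positive branch never uses it
        return (lambda x: np.where(
                    x > 0.0, x, _ELU_ALPHA * (np.exp(np.minimum(x, 0.0)) - 1.0)),
                lambda x, y: np.where(x > 0.0, 1.0, y + _ELU_ALPHA).astype(x.dtype))
    raise ValueError(f"unknown activation {name!r}")


def _pad_lr(k: int) -> tuple[int, int]:
    return (k - 1) // 2, k // 2


class _ConvBlock:
    """conv(same) -> activation -> 2x2 max-pool, with explicit backprop."""

    def __init__(self, in_ch: int, out_ch: int, k: int, activation: str,
                 rng: np.random.Generator):
        fan_in = in_ch * k * k
        self.w = (rng.standard_normal((out_ch, in_ch, k, k))
                  * math.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.k = k
        self.act, self.act_grad = _activation(activation)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        pl, pr = _pad_lr(k)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr), (pl, pr)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        return np.ascontiguousarray(
            win.transpose(0, 2, 3, 1, 4, 5)
        ).reshape(n, h * w, c * k * k)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        f = self.w.shape[0]
        cols = self._im2col(x)
        z = (cols @ self.w.reshape(f, -1).T + self.b).transpose(0, 2, 1)
        z = z.reshape(n, f, h, w)
        a = self.act(z)
        h2, w2 = h // 2, w // 2
        if h2 < 1 or w2 < 1:
            raise ValueError(
                f"feature map {h}x{w} too small for 2x2 pooling; "
                f"use a larger input image"
            )
        ac = a[:, :, : 2 * h2, : 2 * w2]
        pooled = ac.reshape(n, f, h2, 2, w2, 2).max(axis=(3, 5))
        if train:
            self._cache = (x, cols, z, a, pooled)
        return pooled

    def backward(self, dpool: np.ndarray, lr: float) -> np.ndarray:
        x, cols, z, a, pooled = self._cache
        n, c, h, w = x.shape
        f = self.w.shape[0]
        h2, w2 = pooled.shape[2], pooled.shape[3]
        # route gradients through the pooling argmax
        da = np.zeros_like(a)
        ac = a[:, :, : 2 * h2, : 2 * w2].reshape(n, f, h2, 2, w2, 2)
        mask = ac == pooled[:, :, :, None, :, None]
        # resolve ties by normalizing the mask
        mask = mask / np.maximum(mask.sum(axis=(3, 5), keepdims=True), 1)
        da[:, :, : 2 * h2, : 2 * w2] = (
            mask * dpool[:, :, :, None, :, None]
        ).reshape(n, f, 2 * h2, 2 * w2)
        dz = da * self.act_grad(z, a)
        dz_flat = np.ascontiguousarray(
            dz.reshape(n, f, h * w).transpose(0, 2, 1)
        )  # (n, hw, f)
        dz2d = dz_flat.reshape(n * h * w, f)
        dw = (dz2d.T @ cols.reshape(n * h * w, -1)).reshape(self.w.shape)
        db = dz2d.sum(axis=0)
        dcols = dz_flat @ self.w.reshape(f, -1)  # (n, hw, ckk)
        dx = self._col2im(dcols, x.shape)
        self.w -= lr * dw / n
        self.b -= lr * db / n
        return dx

    def _col2im(self, dcols: np.ndarray, x_shape) -> np.ndarray:
        n, c, h, w = x_shape
        k = self.k
        pl, pr = _pad_lr(k)
        dxp = np.zeros((n, c, h + pl + pr, w + pl + pr), dtype=np.float32)
        dcols = dcols.reshape(n, h, w, c, k, k)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + h, dj:dj + w] += dcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, pl:pl + h, pl:pl + w]


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((n_in, n_out))
                  * math.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray, lr: float) -> np.ndarray:
        x = self._x
        dx = dout @ self.w.T
        self.w -= lr * (x.T @ dout) / x.shape[0]
        self.b -= lr * dout.sum(axis=0) / x.shape[0]
        return dx


class SmallCNN:
    """The configurable classifier; see the module docstring."""

    def __init__(self, cfg: CNNConfig, input_shape: tuple[int, int],
                 n_classes: int = 2, seed: int = 0):
        h, w = input_shape
        if h // 8 < 1 or w // 8 < 1:
            raise ValueError(
                f"input {h}x{w} collapses under three 2x2 poolings; "
                f"inputs must be at least 8x8"
            )
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.input_shape = (h, w)
        self.blocks = [
            _ConvBlock(1, cfg.filters_1, cfg.ksize_1, cfg.activation, rng),
            _ConvBlock(cfg.filters_1, cfg.filters_2, cfg.ksize_2, cfg.activation, rng),
            _ConvBlock(cfg.filters_2, cfg.filters_3, cfg.ksize_3, cfg.activation, rng),
        ]
        flat = cfg.filters_3 * (h // 8) * (w // 8)
        self.fc1 = _Dense(flat, cfg.full_hidden1, rng)
        self.act, self.act_grad = _activation(cfg.activation)
        self.head = _Dense(cfg.full_hidden1, n_classes, rng)
        self.n_classes = n_classes

    def forward(self, x: np.ndarray, train: bool = False,
                drop_rng: np.random.Generator | None = None) -> np.ndarray:
        x = x.astype(np.float32)
        if x.ndim == 3:
            x = x[:, None, :, :]
        for blk in self.blocks:
            x = blk.forward(x, train)
        n = x.shape[0]
        x = x.reshape(n, -1)
        z1 = self.fc1.forward(x, train)
        a1 = self.act(z1)
        if train and self.cfg.dropout > 0.0:
            keep = 1.0 - self.cfg.dropout
            mask = (drop_rng.uniform(size=a1.shape) < keep) / keep
            a1d = a1 * mask
            self._cache = (z1, a1, mask)
        else:
            a1d = a1
            if train:
                self._cache = (z1, a1, None)
        logits = self.head.forward(a1d.astype(np.float32), train)
        # stable softmax
        logits = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(logits)
        return ez / ez.sum(axis=1, keepdims=True)

    def train_step(self, x: np.ndarray, y: np.ndarray, lr: float,
                   drop_rng: np.random.Generator) -> float:
        probs = self.forward(x, train=True, drop_rng=drop_rng)
        n = x.shape[0]
        loss = -float(np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        da1d = self.head.backward(dlogits.astype(np.float32), lr)
        z1, a1, mask = self._cache
        if mask is not None:
            da1d = da1d * mask
        dz1 = da1d * self.act_grad(z1, a1)
        dflat = self.fc1.backward(dz1.astype(np.float32), lr)
        shape = self.blocks[-1]._cache[4].shape
        dx = dflat.reshape(shape)
        for blk in reversed(self.blocks):
            dx = blk.backward(dx.astype(np.float32), lr)
        return loss


@dataclass
class TrainedModel:
    architecture: CNNConfig
    model: SmallCNN
    loss_history: list[float]

    def predict(self, x: np.ndarray) -> np.ndarray:
        return predict(self, x)


def build_model(cfg: CNNConfig, input_shape: tuple[int, int],
                n_classes: int = 2, seed: int = 0) -> SmallCNN:
    """Construct an untrained classifier; same (cfg, seed) gives identical
    initial parameters."""
    return SmallCNN(cfg, input_shape, n_classes=n_classes, seed=seed)


def train(model: SmallCNN, x: np.ndarray, y: np.ndarray,
          protocol: TrainProtocol | None = None) -> TrainedModel:
    """Mini-batch SGD at the configuration's learning rate and batch size.

    ``x`` is (n, h, w) maps (or (n, p) vectors, reshaped via
    :func:`vectors_to_maps` by the caller); ``y`` is integer class labels.
    Deterministic under ``protocol.seed``.
    """
    protocol = protocol or TrainProtocol()
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain at least two classes")
    counts = np.bincount(y)
    if (counts[counts > 0] < 2).any():
        raise ValueError("each class needs at least two examples")
    rng = np.random.default_rng(protocol.seed)
    n = x.shape[0]
    bs = min(model.cfg.batch_size, n)
    lr = model.cfg.learning_rate
    losses: list[float] = []
    for _ in range(protocol.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            epoch_loss += model.train_step(x[idx], y[idx], lr, rng)
            n_batches += 1
        losses.append(epoch_loss / n_batches)
    return TrainedModel(architecture=model.cfg, model=model, loss_history=losses)


def predict(trained: TrainedModel | SmallCNN, x: np.ndarray) -> np.ndarray:
    model = trained.model if isinstance(trained, TrainedModel) else trained
    return model.forward(x, train=False).argmax(axis=1)


def vectors_to_maps(values: np.ndarray, min_side: int = 8) -> np.ndarray:
    """Reshape (n, p) feature vectors into square (n, s, s) maps.

    p is zero-padded to the next square of side >= ``min_side`` so that
    three halving poolings remain valid.
    """
    n, p = values.shape
    side = max(min_side, math.ceil(math.sqrt(p)))
    padded = np.zeros((n, side * side), dtype=np.float64)
    padded[:, :p] = values
    return padded.reshape(n, side, side)


def save_model(trained: TrainedModel, path: str | Path) -> Path:
    """Serialize weights (npz) with the architecture and loss history."""
    path = Path(path)
    model = trained.model
    arrays = {}
    for i, blk in enumerate(model.blocks):
        arrays[f"block{i}_w"] = blk.w
        arrays[f"block{i}_b"] = blk.b
    arrays["fc1_w"], arrays["fc1_b"] = model.fc1.w, model.fc1.b
    arrays["head_w"], arrays["head_b"] = model.head.w, model.head.b
    arrays["input_shape"] = np.array(model.input_shape)
    np.savez(path, **arrays)
    meta = {"architecture": trained.architecture.as_dict(),
            "loss_history": trained.loss_history}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))
    return path


def load_model(path: str | Path) -> TrainedModel:
    """Rebuild a :class:`TrainedModel` from :func:`save_model` output."""
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    cfg = CNNConfig(**meta["architecture"])
    with np.load(path) as data:
        input_shape = tuple(int(v) for v in data["input_shape"])
        model = SmallCNN(cfg, input_shape, seed=0)
        for i, blk in enumerate(model.blocks):
            blk.w = data[f"block{i}_w"]
            blk.b = data[f"block{i}_b"]
        model.fc1.w, model.fc1.b = data["fc1_w"], data["fc1_b"]
        model.head.w, model.head.b = data["head_w"], data["head_b"]
    return TrainedModel(architecture=cfg, model=model,
                        loss_history=meta["loss_history"])


class FitnessEvaluator:
    """1 - cross-validated accuracy of the decoded configuration.

    Inputs are the training-split samples only; the held-out test split
    never enters the objective. Feature standardization statistics are fit
    on each fold's training part. Build/train failures yield +inf fitness
    with a recorded warning so the optimizer stays total.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray,
                 space: SearchSpace | None = None,
                 protocol: TrainProtocol | None = None):
        self.space = space or default_space()
        self.protocol = protocol or TrainProtocol()
        if x.ndim == 2:
            x = vectors_to_maps(x)
        self.x = np.ascontiguousarray(x, dtype=np.float32)
        self.y = np.asarray(y)
        self._cache: dict[tuple, float] = {}
        self.warnings: list[str] = []
        self.n_evaluations = 0

    def __call__(self, position: np.ndarray) -> float:
        cfg = decode(position, self.space)
        key = tuple(sorted(cfg.as_dict().items()))
        if key in self._cache:
            return self._cache[key]
        self.n_evaluations += 1
        try:
            fit = 1.0 - self._cv_accuracy(cfg)
        except ValueError as exc:
            self.warnings.append(f"{cfg.as_dict()}: {exc}")
            fit = math.inf
        self._cache[key] = fit
        return fit

    def _cv_accuracy(self, cfg: CNNConfig) -> float:
        skf = StratifiedKFold(
            n_splits=self.protocol.cv_folds, shuffle=True,
            random_state=self.protocol.seed,
        )
        accs = []
        for fold, (tr, va) in enumerate(skf.split(self.x, self.y)):
            xtr, xva = self.x[tr], self.x[va]
            mu = xtr.mean(axis=0)
            sd = xtr.std(axis=0) + 1e-8
            xtr = (xtr - mu) / sd
            xva = (xva - mu) / sd
            model = build_model(cfg, self.x.shape[1:], seed=self.protocol.seed + fold)
            trained = train(model, xtr, self.y[tr], self.protocol)
            accs.append(float((predict(trained, xva) == self.y[va]).mean()))
        return float(np.mean(accs))


def fitness_for(position: np.ndarray, x: np.ndarray, y: np.ndarray,
                space: SearchSpace | None = None,
                protocol: TrainProtocol | None = None) -> float:
    """One-shot convenience wrapper around :class:`FitnessEvaluator`."""
    return FitnessEvaluator(x, y, space=space, protocol=protocol)(position)
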