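"""Frozen convolutional feature extraction.

The pipeline's transfer-learning stage turns each grayscale image into a
flat feature vector with a convolutional network whose weights are never
trained. The built-in backbone draws its kernels once from a seeded
Gaussian stream (random convolutional features): each stage is
conv (3x3, "same" padding) -> ReLU -> 2x2 max-pool, and with
``output="vector"`` the final stage is globally average-pooled so the
feature dimension equals the last stage's channel count (default
16-64-128, i.e. 128 features). Random frozen convolutions are a standard
cheap stand-in for a pretrained encoder: they preserve local texture and
edge statistics, which is what separates smooth from spiculated lesions.

An ``external_adapter`` kind delegates to any user-supplied callable
(e.g. a wrapper around a pretrained AlexNet) that maps a list of images to
an (n, p) matrix; the shape contract is enforced here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .synthetic import LabeledImage

__all__ = ["relu", "BackboneConfig", "FeatureMatrix", "extract_features",
           "write_features", "read_features"]


def relu(x):
    """Rectified linear unit, f(x) = max(x, 0), elementwise."""
    return np.maximum(x, 0)


@dataclass(frozen=True)
class BackboneConfig:
    kind: str = "builtin"
    stages: int = 3
    channels_per_stage: tuple[int, ...] = (16, 64, 128)
    output: str = "vector"
    weights_seed: int = 0
    adapter: Callable[[list[LabeledImage]], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("builtin", "external_adapter"):
            raise ValueError("kind must be 'builtin' or 'external_adapter'")
        if self.stages < 1:
            raise ValueError("stages must be >= 1")
        if len(self.channels_per_stage) != self.stages:
            raise ValueError("channels_per_stage length must equal stages")
        if any(c < 1 for c in self.channels_per_stage):
            raise ValueError("channel counts must be positive")
        if self.output not in ("vector", "feature_map"):
            raise ValueError("output must be 'vector' or 'feature_map'")
        if self.kind == "external_adapter" and self.adapter is None:
            raise ValueError("external_adapter kind requires an adapter callable")


@dataclass
class FeatureMatrix:
    values: np.ndarray
    ids: list[str]
    feature_dim: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be an (n, p) matrix")
        if self.values.shape[0] != len(self.ids):
            raise ValueError("row count must equal number of ids")
        if self.values.shape[1] != self.feature_dim:
            raise ValueError("column count must equal feature_dim")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def _conv2d_same(x: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """'Same' 2-D cross-correlation. x: (n,c,h,w), kernels: (f,c,k,k)."""
    n, c, h, w = x.shape
    f, _, k, _ = kernels.shape
    pl = (k - 1) // 2
    pr = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pr), (pl, pr)))
    # im2col: (n, h*w, c*k*k)
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)
    out = cols @ kernels.reshape(f, -1).T
    return out.transpose(0, 2, 1).reshape(n, f, h, w)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    """2x2 max-pool, stride 2, floor semantics (odd trailing row/col dropped)."""
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    if h2 < 1 or w2 < 1:
        raise ValueError(f"feature map {h}x{w} too small to pool")
    x = x[:, :, : 2 * h2, : 2 * w2]
    return x.reshape(n, c, h2, 2, w2, 2).max(axis=(3, 5))


def _builtin_forward(pixels: np.ndarray, cfg: BackboneConfig) -> np.ndarray:
    rng = np.random.default_rng(cfg.weights_seed)
    x = pixels[:, None, :, :].astype(np.float64)
    in_ch = 1
    for out_ch in cfg.channels_per_stage:
        fan_in = in_ch * 9
        kernels = rng.standard_normal((out_ch, in_ch, 3, 3)) / np.sqrt(fan_in)
        x = relu(_conv2d_same(x, kernels))
        x = _maxpool2(x)
        in_ch = out_ch
    if cfg.output == "vector":
        return x.mean(axis=(2, 3))
    return x


def extract_features(
    images: Sequence[LabeledImage], backbone: BackboneConfig | None = None
) -> FeatureMatrix:
    """Map images to an (n, p) feature matrix; pure in (pixels, config)."""
    backbone = backbone or BackboneConfig()
    if not images:
        raise ValueError("no images to extract features from")
    sizes = {img.pixels.shape for img in images}
    if len(sizes) != 1:
        raise ValueError(f"all images must share one size, got {sizes}")
    ids = [img.id for img in images]
    if backbone.kind == "external_adapter":
        values = np.asarray(backbone.adapter(list(images)), dtype=np.float64)
        if values.ndim != 2 or values.shape[0] != len(images):
            raise ValueError(
                f"adapter must return ({len(images)}, p) matrix, "
                f"got shape {values.shape}"
            )
    else:
        pixels = np.stack([img.pixels for img in images])
        values = _builtin_forward(pixels, backbone)
        if values.ndim > 2:
            values = values.reshape(values.shape[0], -1)
    return FeatureMatrix(values=values, ids=ids, feature_dim=values.shape[1])


def write_features(fm: FeatureMatrix, path: str | Path) -> Path:
    """CSV with an ``id`` column followed by f0..f(p-1)."""
    path = Path(path)
    df = pd.DataFrame(fm.values, columns=[f"f{i}" for i in range(fm.feature_dim)])
    df.insert(0, "id", fm.ids)
    df.to_csv(path, index=False)
    return path


def read_features(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    ids = df["id"].astype(str).tolist()
    values = df.drop(columns="id").to_numpy(dtype=np.float64)
    return FeatureMatrix(values=values, ids=ids, feature_dim=values.shape[1])
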