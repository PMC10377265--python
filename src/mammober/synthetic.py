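"""Synthetic two-class mammogram-like image sets.

Real screening mammograms show benign lesions as smooth, roughly circular
masses and malignant lesions as spiculated masses (radiating linear
projections) often accompanied by clusters of punctate microcalcifications.
This module emulates those cues on a textured background so the whole
classification pipeline can be exercised and tested without any clinical
data: benign images carry one radially symmetric Gaussian mass; malignant
images carry the same mass plus ``spicule_count`` radial line segments and a
Poisson number of bright dots.

The ``effect_size`` knob scales the amplitude of every malignant-only cue.
At ``effect_size=0`` the two class-conditional distributions coincide
exactly, so the label carries no information and any classifier's expected
accuracy is 1/2 — a useful null for calibration tests.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "SyntheticConfig",
    "LabeledImage",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "LABELS",
]

LABELS = ("benign", "malignant")

MANIFEST_NAME = "manifest.csv"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic image set.

    Parameters
    ----------
    n_per_class : int
        Images generated for each of the two classes.
    image_size : int
        Side length of the square images, in pixels.
    mass_radius_range : tuple of float
        Low/high bounds (pixels) for the Gaussian mass radius.
    spicule_count_range : tuple of int
        Inclusive bounds for the number of radial spicules on a malignant
        mass.
    calcification_rate : float
        Expected number of bright punctate dots per malignant image
        (Poisson mean).
    background_noise_sd : float
        Standard deviation of the smoothed background texture, in [0, 1]
        intensity units.
    effect_size : float
        In [0, 1]; scales the amplitude of all malignant-specific structure.
    seed : int
        Seed of the generator's private random stream.
    """

    n_per_class: int = 200
    image_size: int = 64
    mass_radius_range: tuple[float, float] = (6.0, 12.0)
    spicule_count_range: tuple[int, int] = (5, 11)
    calcification_rate: float = 6.0
    background_noise_sd: float = 0.08
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_per_class) < 1:
            raise ValueError("n_per_class must be >= 1")
        if int(self.image_size) < 16:
            raise ValueError("image_size must be >= 16")
        lo, hi = self.mass_radius_range
        if not (0 < lo <= hi):
            raise ValueError("mass_radius_range must satisfy 0 < low <= high")
        slo, shi = self.spicule_count_range
        if not (0 <= slo <= shi):
            raise ValueError("spicule_count_range must satisfy 0 <= low <= high")
        if self.calcification_rate < 0:
            raise ValueError("calcification_rate must be >= 0")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")
        if not (0.0 <= self.effect_size <= 1.0):
            raise ValueError("effect_size must lie in [0, 1]")


@dataclass
class LabeledImage:
    """A square grayscale image with pixels in [0, 1] and a class label."""

    pixels: np.ndarray
    label: str
    id: str = field(default="")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("pixels must be a square 2-D matrix")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 1):
            raise ValueError("pixel values must lie in [0, 1]")


def _background(rng: np.random.Generator, size: int, noise_sd: float) -> np.ndarray:
    """Gaussian-smoothed white noise around mid-gray, emulating parenchyma."""
    noise = rng.standard_normal((size, size))
    texture = gaussian_filter(noise, sigma=2.0)
    scale = texture.std()
    if scale > 0:
        texture = texture / scale
    return 0.35 + noise_sd * texture


def _mass(size: int, cx: float, cy: float, radius: float, amp: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    return amp * np.exp(-d2 / (2.0 * (radius / 1.5) ** 2))


def _spicules(
    rng: np.random.Generator,
    size: int,
    cx: float,
    cy: float,
    radius: float,
    n_spicules: int,
    amp: float,
) -> np.ndarray:
    """Thin bright radial segments emanating from the mass rim."""
    canvas = np.zeros((size, size))
    angles = rng.uniform(0.0, 2.0 * np.pi, size=n_spicules)
    lengths = rng.uniform(1.2 * radius, 2.6 * radius, size=n_spicules)
    t = np.linspace(0.0, 1.0, 40)
    for ang, length in zip(angles, lengths):
        xs = cx + t * length * np.cos(ang)
        ys = cy + t * length * np.sin(ang)
        ix = np.clip(np.round(xs).astype(int), 0, size - 1)
        iy = np.clip(np.round(ys).astype(int), 0, size - 1)
        canvas[iy, ix] = np.maximum(canvas[iy, ix], amp * (1.0 - 0.6 * t))
    return gaussian_filter(canvas, sigma=0.6)


def _calcifications(
    rng: np.random.Generator, size: int, rate: float, amp: float
) -> np.ndarray:
    canvas = np.zeros((size, size))
    n_dots = rng.poisson(rate)
    for _ in range(n_dots):
        x = rng.integers(2, size - 2)
        y = rng.integers(2, size - 2)
        canvas[y, x] = amp
    return gaussian_filter(canvas, sigma=0.7) * 4.0


def generate_dataset(config: SyntheticConfig) -> list[LabeledImage]:
    """Generate ``2 * n_per_class`` labeled images, benign first.

    The same random draws are made for both classes' shared structure, and
    every malignant-only component has its amplitude multiplied by
    ``effect_size``, so ``effect_size=0`` makes the two class-conditional
    distributions identical. Identical configs (same seed) give bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    images: list[LabeledImage] = []
    for label in LABELS:
        malignant = label == "malignant"
        for i in range(config.n_per_class):
            bg = _background(rng, size, config.background_noise_sd)
            # keep the mass centre inside the frame even for small images
            margin = min(max(config.mass_radius_range) + 2, size // 2 - 1)
            cx = rng.uniform(margin, size - margin)
            cy = rng.uniform(margin, size - margin)
            radius = rng.uniform(*config.mass_radius_range)
            img = bg + _mass(size, cx, cy, radius, amp=0.45)
            # Malignant-only draws happen for both classes to keep streams
            # aligned across labels; amplitude 0 erases them for benign.
            amp = 0.5 * config.effect_size if malignant else 0.0
            n_spic = int(rng.integers(config.spicule_count_range[0],
                                      config.spicule_count_range[1] + 1))
            img = img + _spicules(rng, size, cx, cy, radius, n_spic, amp)
            img = img + _calcifications(rng, size, config.calcification_rate, amp)
            pixels = np.clip(img, 0.0, 1.0)
            images.append(
                LabeledImage(pixels=pixels, label=label, id=f"{label}_{i:04d}")
            )
    return images


def write_dataset(images: list[LabeledImage], directory: str | Path) -> Path:
    """Write one 8-bit grayscale PNG per image plus a CSV manifest.

    Returns the manifest path. Columns are ``id,filename,label``; intensities
    are quantized to 8 bits, so a read-back differs from the in-memory pixels
    by at most 1/255 per pixel.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / MANIFEST_NAME
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "filename", "label"])
        for img in images:
            fname = f"{img.id}.png"
            arr = np.round(img.pixels * 255.0).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(directory / fname)
            writer.writerow([img.id, fname, img.label])
    return manifest


def read_dataset(directory: str | Path) -> list[LabeledImage]:
    """Read a PNG+manifest dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    manifest = directory / MANIFEST_NAME
    if not manifest.exists():
        raise FileNotFoundError(f"manifest not found: {manifest}")
    images: list[LabeledImage] = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            label = row["label"]
            if label not in LABELS:
                raise ValueError(
                    f"label {label!r} for id {row['id']!r} not in {LABELS}"
                )
            path = directory / row["filename"]
            try:
                with Image.open(path) as im:
                    arr = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
            except (OSError, ValueError) as exc:
                raise OSError(f"unreadable PNG {path}: {exc}") from exc
            images.append(LabeledImage(pixels=arr, label=label, id=row["id"]))
    return images
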