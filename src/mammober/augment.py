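"""Dataset enlargement by exact flips and 90-degree rotations.

Two modes are provided. ``algorithm1`` adds, per image, its left-right flip,
its up-down flip and its 90-degree rotation (x4 counting the original —
the factor that reproduces the published dataset sizes, 1696 -> 6784 and
1356 -> 5424). ``prose8`` adds the four rotations {0, 90, 180, 270} degrees
together with the left-right flip of each (x9 counting the original); the
0-degree "rotation" is pixel-identical to its source but kept as a distinct
record, which is how an x9 enlargement arises from eight saved shots.

All transforms are pure array re-indexings (no interpolation), so the pixel
multiset and therefore the intensity histogram of every image is preserved,
and class labels are untouched. Rotations are counter-clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import LabeledImage

__all__ = ["AugmentationConfig", "augment_image", "augment_set", "MODES"]

MODES = ("algorithm1", "prose8")


@dataclass(frozen=True)
class AugmentationConfig:
    mode: str = "algorithm1"
    include_originals: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


def _derived(img: LabeledImage, pixels: np.ndarray, suffix: str) -> LabeledImage:
    return LabeledImage(pixels=pixels, label=img.label, id=f"{img.id}_{suffix}")


def augment_image(image: LabeledImage, mode: str = "algorithm1") -> list[LabeledImage]:
    """Return the new images derived from one input (the input excluded)."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    p = image.pixels
    if p.shape[0] != p.shape[1]:
        raise ValueError("rotation requires a square image")
    if mode == "algorithm1":
        return [
            _derived(image, np.fliplr(p), "fliplr"),
            _derived(image, np.flipud(p), "flipud"),
            _derived(image, np.rot90(p), "rot90"),
        ]
    out = []
    for k in range(4):
        rot = np.rot90(p, k)
        out.append(_derived(image, rot, f"rot{90 * k}"))
        out.append(_derived(image, np.fliplr(rot), f"rot{90 * k}_fliplr"))
    return out


def augment_set(
    images: list[LabeledImage], config: AugmentationConfig | None = None
) -> list[LabeledImage]:
    """Augment a whole set; output count is exactly 4x or 9x the input.

    With ``include_originals=False`` the factors are 3 and 8. Per-class
    counts scale by the same factor, so class balance is invariant.
    """
    if not images:
        raise ValueError("augment_set requires a nonempty image list")
    config = config or AugmentationConfig()
    out: list[LabeledImage] = []
    for img in images:
        if config.include_originals:
            out.append(img)
        out.extend(augment_image(img, config.mode))
    return out
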