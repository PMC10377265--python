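"""Enlarge an image set by flips and 90-degree rotations.

The default mode adds three transformed copies per image (x4 with the
originals), which is the factor behind the published 1696 -> 6784 and
1356 -> 5424 dataset enlargements; the prose8 mode yields x9.
"""

from mammober import AugmentationConfig, SyntheticConfig, augment_set, generate_dataset

images = generate_dataset(SyntheticConfig(n_per_class=848, image_size=16, seed=0))
print(f"input images: {len(images)}")
for mode in ("algorithm1", "prose8"):
    out = augment_set(images, AugmentationConfig(mode=mode))
    print(f"mode {mode:10s}: {len(out)} images "
          f"(factor {len(out) // len(images)})")
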