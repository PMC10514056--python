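"""Phantom volume and virtual sectioning.

Generates the deterministic phantom "brain", renders a coronal and an
oblique section through it, applies the training-set augmentation, and
shows the minimal-tissue filter at work.
"""

import numpy as np

from coronalign import (
    AnchorSampler,
    augment,
    axis_aligned_anchor,
    generate_phantom,
    sample_random_anchors,
    sample_section,
    tissue_filter,
)

volume = generate_phantom(seed=0)
print("phantom:", volume.shape, "voxels;", int(volume.mask.sum()), "inside the brain mask")

plane = sample_section(volume, axis_aligned_anchor(volume, 64))
exact = np.array_equal(plane, volume.intensity[:, 64, :].T)
print(f"axis-aligned slice at y=64: {plane.shape} image, "
      f"bit-identical to the stored plane: {exact}")

[oblique] = sample_random_anchors(AnchorSampler(seed=4), 1, volume)
image = sample_section(volume, oblique)
print(f"random oblique slice '{oblique.filename}': mean intensity {image.mean():.3f}")

degraded = augment(image, seed=7)  # noise + dropout + elastic warp
print(f"after augmentation: mean {degraded.mean():.3f} "
      f"(dropout zeroes ~10% of pixels, warp smears edges)")

empty = np.zeros_like(image)
print("tissue filter keeps the section:", tissue_filter(image),
      "| keeps an empty image:", tissue_filter(empty))
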