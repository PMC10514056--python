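"""Generate-and-recover: locate a section image in the volume.

Renders one oblique section through the phantom and asks the brute-force
template matcher to find its rostrocaudal position and cutting angles
again from the image alone.  Takes ~10 s on one CPU.
"""

from coronalign import (
    AnchorSampler,
    compute_cutting_angles,
    generate_phantom,
    sample_random_anchors,
    sample_section,
    section_center,
    template_match_predict,
)

volume = generate_phantom(seed=0)
[anchor] = sample_random_anchors(AnchorSampler(seed=21, dv_sd_deg=3, ml_sd_deg=3), 1, volume)
truth_angles = compute_cutting_angles(anchor)
truth_y = section_center(anchor)[1]
print(f"ground truth: y={truth_y:.2f} voxels, "
      f"DV {truth_angles.dv_deg:+.2f} deg, ML {truth_angles.ml_deg:+.2f} deg")

image = sample_section(volume, anchor)
result = template_match_predict(image, volume)
found_angles = compute_cutting_angles(result.anchor)
found_y = section_center(result.anchor)[1]
print(f"recovered:    y={found_y:.2f} voxels, "
      f"DV {found_angles.dv_deg:+.2f} deg, ML {found_angles.ml_deg:+.2f} deg "
      f"(NCC score {result.score:.4f})")
print(f"errors: {abs(found_y - truth_y):.2f} voxels rostrocaudal, "
      f"{abs(found_angles.dv_deg - truth_angles.dv_deg):.2f} / "
      f"{abs(found_angles.ml_deg - truth_angles.ml_deg):.2f} deg in DV/ML — "
      "within the fine search step of the matcher")
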