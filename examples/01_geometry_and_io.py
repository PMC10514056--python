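"""Anchoring-vector geometry and QuickNII file round trips.

Builds a tilted section plane from cutting angles, projects pixels into
atlas space, and round-trips the series through both QuickNII dialects.
"""

import tempfile
from pathlib import Path

from coronalign import (
    CuttingAngles,
    SeriesAlignment,
    build_anchor_from_angles,
    compute_cutting_angles,
    map_pixel_to_voxel,
    read_series,
    section_center,
    write_series,
)

# A section through atlas position y=220 (voxels), tilted 4 deg dorsoventrally
anchor = build_anchor_from_angles(
    center=(228, 220, 160), angles=CuttingAngles(dv_deg=4.0, ml_deg=-1.5),
    width_len=456, height_len=320, width=512, height=512, filename="demo_s001.png",
)
print("O =", anchor.o, " U =", anchor.u, " V =", anchor.v)
print("center:", section_center(anchor), "(voxel units; x=ML, y=RC, z=DV)")

angles = compute_cutting_angles(anchor)
print(f"measured angles: DV {angles.dv_deg:.3f} deg, ML {angles.ml_deg:.3f} deg "
      "(round trip of the construction angles)")

corner = map_pixel_to_voxel(anchor, 0, 0)
mid = map_pixel_to_voxel(anchor, 255.5, 255.5)
print("top-left pixel ->", corner, "= O exactly; image middle ->", mid)

series = SeriesAlignment(name="demo", sections=[anchor])
with tempfile.TemporaryDirectory() as d:
    for ext in ("json", "xml"):
        path = Path(d) / f"demo.{ext}"
        write_series(series, path)
        back = read_series(path)
        same = (back.sections[0].components == anchor.components).all()
        print(f"{ext}: wrote {path.name}, read back identical components: {same}")
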