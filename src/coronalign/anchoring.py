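"""Anchoring-vector data model and section-plane geometry.

A section plane is parametrized QuickNII-style by three atlas-space vectors:
``O`` is the voxel coordinate of the image's top-left corner, ``U`` spans the
image width (left to right) and ``V`` spans the image height (top to bottom).
The atlas convention is fixed as x = mediolateral, y = rostrocaudal,
z = dorsoventral, so a perfectly coronal section has U along +x and V along
+z.  All coordinates are in atlas voxels (25 µm per voxel by default).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ANCHORING_FIELDS",
    "AtlasConvention",
    "SectionAnchor",
    "SeriesAlignment",
    "CuttingAngles",
    "DegeneratePlaneError",
    "map_pixel_to_voxel",
    "section_center",
    "compute_cutting_angles",
    "build_anchor_from_angles",
]

#: The nine anchoring components, in canonical (QuickNII) order.
ANCHORING_FIELDS = ("ox", "oy", "oz", "ux", "uy", "uz", "vx", "vy", "vz")

DEFAULT_TARGET = "ABA_Mouse_CCFv3_2017_25um"


class DegeneratePlaneError(ValueError):
    """The anchoring vectors do not define a usable section plane."""


@dataclass(frozen=True)
class AtlasConvention:
    """Axis convention and voxel size of the reference volume.

    Axis order is fixed: x = mediolateral, y = rostrocaudal (the anchoring
    origin's ``oy`` component), z = dorsoventral.  ``voxel_size_um`` converts
    voxel distances into micrometres.
    """

    voxel_size_um: float = 25.0
    name: str = DEFAULT_TARGET

    def __post_init__(self) -> None:
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be positive, got {self.voxel_size_um}")


@dataclass(frozen=True)
class CuttingAngles:
    """Tilt of a cutting plane away from the ideal coronal plane, in degrees.

    ``dv_deg`` is the dorsoventral tilt (positive tilts the section bottom
    caudally); ``ml_deg`` is the mediolateral tilt (positive tilts the
    image-right edge caudally).  Both must lie strictly inside (-90, 90).
    """

    dv_deg: float
    ml_deg: float

    def __post_init__(self) -> None:
        for label, value in (("dv_deg", self.dv_deg), ("ml_deg", self.ml_deg)):
            if not (-90.0 < value < 90.0):
                raise ValueError(f"{label}={value} outside the open interval (-90, 90)")


@dataclass(frozen=True)
class SectionAnchor:
    """One section image's anchoring: O, U, V plus pixel dimensions.

    The nine floats are atlas-voxel coordinates; ``width``/``height`` are the
    image pixel dimensions; ``cutting_index`` is the optional serial-sectioning
    order token parsed from the filename.
    """

    filename: str
    ox: float
    oy: float
    oz: float
    ux: float
    uy: float
    uz: float
    vx: float
    vy: float
    vz: float
    width: int
    height: int
    cutting_index: int | None = None

    def __post_init__(self) -> None:
        # normalize numpy scalars to builtins so repr/serialization are clean
        for name in ANCHORING_FIELDS:
            object.__setattr__(self, name, float(getattr(self, name)))
        object.__setattr__(self, "width", int(self.width))
        object.__setattr__(self, "height", int(self.height))
        if self.cutting_index is not None:
            object.__setattr__(self, "cutting_index", int(self.cutting_index))
        if self.width < 2 or self.height < 2:
            raise ValueError(
                f"{self.filename!r}: width and height must be >= 2 pixels, "
                f"got {self.width}x{self.height}"
            )
        if self.cutting_index is not None and self.cutting_index < 0:
            raise ValueError(f"{self.filename!r}: cutting_index must be non-negative")
        u, v = self.u, self.v
        if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
            raise DegeneratePlaneError(f"{self.filename!r}: |U| and |V| must be positive")
        if np.linalg.norm(np.cross(u, v)) == 0:
            raise DegeneratePlaneError(f"{self.filename!r}: U and V are parallel")

    @property
    def o(self) -> np.ndarray:
        return np.array([self.ox, self.oy, self.oz], dtype=float)

    @property
    def u(self) -> np.ndarray:
        return np.array([self.ux, self.uy, self.uz], dtype=float)

    @property
    def v(self) -> np.ndarray:
        return np.array([self.vx, self.vy, self.vz], dtype=float)

    @property
    def components(self) -> np.ndarray:
        """The nine anchoring components as a vector, in canonical order."""
        return np.array([getattr(self, f) for f in ANCHORING_FIELDS], dtype=float)

    @classmethod
    def from_components(
        cls,
        filename: str,
        components,
        width: int,
        height: int,
        cutting_index: int | None = None,
    ) -> "SectionAnchor":
        comps = [float(c) for c in components]
        if len(comps) != 9:
            raise ValueError(f"{filename!r}: expected 9 anchoring components, got {len(comps)}")
        return cls(filename, *comps, width=width, height=height, cutting_index=cutting_index)

    def translated(self, t) -> "SectionAnchor":
        """Rigidly translate the plane origin by atlas-space vector ``t``."""
        tx, ty, tz = (float(c) for c in t)
        return dataclasses.replace(self, ox=self.ox + tx, oy=self.oy + ty, oz=self.oz + tz)

    def replace(self, **kwargs) -> "SectionAnchor":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SeriesAlignment:
    """An ordered set of section anchors cut from one tissue block.

    This is the unit on which angle integration and cutting-index weighting
    operate; ``target`` names the reference atlas the anchoring coordinates
    live in.
    """

    name: str
    sections: list[SectionAnchor]
    target: str = DEFAULT_TARGET

    def __post_init__(self) -> None:
        names = [s.filename for s in self.sections]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate filenames in series {self.name!r}: {dupes}")

    def __len__(self) -> int:
        return len(self.sections)

    def __iter__(self):
        return iter(self.sections)

    @property
    def filenames(self) -> list[str]:
        return [s.filename for s in self.sections]

    def get(self, filename: str) -> SectionAnchor:
        for s in self.sections:
            if s.filename == filename:
                return s
        raise KeyError(filename)

    def with_sections(self, sections: list[SectionAnchor]) -> "SeriesAlignment":
        return SeriesAlignment(name=self.name, sections=list(sections), target=self.target)


def map_pixel_to_voxel(anchor: SectionAnchor, i: float, j: float) -> np.ndarray:
    """Project pixel (column ``i``, row ``j``) onto the atlas plane.

    Uses the corner-anchored bilinear parametrization
    ``O + i/(width-1) * U + j/(height-1) * V`` so the four corner pixels map
    exactly onto O, O+U, O+V and O+U+V.
    """
    if not (0 <= i <= anchor.width - 1):
        raise ValueError(f"pixel column {i} outside [0, {anchor.width - 1}]")
    if not (0 <= j <= anchor.height - 1):
        raise ValueError(f"pixel row {j} outside [0, {anchor.height - 1}]")
    s = i / (anchor.width - 1)
    t = j / (anchor.height - 1)
    return anchor.o + s * anchor.u + t * anchor.v


def section_center(anchor: SectionAnchor) -> np.ndarray:
    """Atlas coordinate of the section's geometric center, ``O + (U+V)/2``."""
    return anchor.o + (anchor.u + anchor.v) / 2.0


def compute_cutting_angles(anchor: SectionAnchor) -> CuttingAngles:
    """Measure the dorsoventral and mediolateral cutting angles of a plane.

    ``ml_deg = atan2(U_y, U_x)``: how far the width vector swings out of the
    mediolateral axis toward rostrocaudal.  ``dv_deg = atan2(V_y, V_z)``: how
    far the height vector swings out of the dorsoventral axis.  A perfectly
    coronal anchor has (dv, ml) = (0, 0).
    """
    if anchor.ux == 0 and anchor.uy == 0:
        raise DegeneratePlaneError(
            f"{anchor.filename!r}: U has no projection in the x-y plane; ML angle undefined"
        )
    if anchor.vz == 0 and anchor.vy == 0:
        raise DegeneratePlaneError(
            f"{anchor.filename!r}: V has no projection in the y-z plane; DV angle undefined"
        )
    ml = math.degrees(math.atan2(anchor.uy, anchor.ux))
    dv = math.degrees(math.atan2(anchor.vy, anchor.vz))
    return CuttingAngles(dv_deg=dv, ml_deg=ml)


def build_anchor_from_angles(
    center,
    angles: CuttingAngles,
    width_len: float,
    height_len: float,
    width: int,
    height: int,
    filename: str = "section",
    cutting_index: int | None = None,
) -> SectionAnchor:
    """Construct the canonical anchor with the given center and cutting angles.

    The canonical two-angle plane family has U in the x-y plane (no z
    component) and V in the y-z plane (no x component): the minimal
    parametrization in which the (DV, ML) pair fully determines the plane
    orientation.  ``width_len``/``height_len`` are the physical edge lengths in
    voxels.  Round trip: ``compute_cutting_angles`` on the result returns the
    input angles (to ~1e-12 degrees) and ``section_center`` returns ``center``
    exactly.
    """
    if width_len <= 0 or height_len <= 0:
        raise ValueError("edge lengths must be positive")
    ml = math.radians(angles.ml_deg)
    dv = math.radians(angles.dv_deg)
    u = np.array([width_len * math.cos(ml), width_len * math.sin(ml), 0.0])
    v = np.array([0.0, height_len * math.sin(dv), height_len * math.cos(dv)])
    o = np.asarray(center, dtype=float) - (u + v) / 2.0
    return SectionAnchor(
        filename=filename,
        ox=o[0], oy=o[1], oz=o[2],
        ux=u[0], uy=u[1], uz=u[2],
        vx=v[0], vy=v[1], vz=v[2],
        width=width, height=height,
        cutting_index=cutting_index,
    )
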