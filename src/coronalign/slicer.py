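"""Virtual sectioning: render 2D sections through a volume from anchoring
vectors, plus the synthetic machinery around it (phantom volume, random
anchoring sampler, image augmentation, minimal-tissue filter).

The phantom volume is a deterministic synthetic "brain": a bilaterally
near-symmetric ellipsoidal envelope whose interior intensity trends along the
rostrocaudal axis, seeded with ellipsoidal "nuclei" at fixed fractional
positions (one deliberately unpaired so mirrored planes are distinguishable),
plus low-amplitude seeded texture.  It encodes rostrocaudal position in image
appearance, which is what lets generate-and-recover experiments run without
downloading a reference atlas.

Volumes are indexed ``intensity[x, y, z]`` with x = mediolateral,
y = rostrocaudal, z = dorsoventral, matching the anchoring convention.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .anchoring import (
    AtlasConvention,
    CuttingAngles,
    SectionAnchor,
    build_anchor_from_angles,
)

__all__ = [
    "VolumeTemplate",
    "AnchorSampler",
    "generate_phantom",
    "sample_section",
    "axis_aligned_anchor",
    "nominal_edge_lengths",
    "sample_random_anchors",
    "augment",
    "tissue_filter",
    "save_volume",
    "load_volume",
]


@dataclass
class VolumeTemplate:
    """A reference volume: intensity in [0, 1] plus a binary brain mask."""

    intensity: np.ndarray
    mask: np.ndarray
    convention: AtlasConvention = field(default_factory=AtlasConvention)
    name: str = "volume"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be a 3D array")
        if self.intensity.shape != self.mask.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} != mask shape {self.mask.shape}"
            )
        if not np.isfinite(self.intensity).all():
            raise ValueError("intensity must be finite")
        if self.intensity.min() < -1e-9 or self.intensity.max() > 1 + 1e-9:
            raise ValueError("intensity must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape


# Interior "nuclei" of the phantom: fractional (x, y, z) center, fractional
# semi-axes, and intensity.  Most come in bilaterally mirrored pairs around
# x = 0.5; the final entry is deliberately unpaired so that left-right
# mirrored planes are distinguishable.
PHANTOM_NUCLEI: tuple[tuple[tuple[float, float, float], tuple[float, float, float], float], ...] = (
    ((0.32, 0.16, 0.40), (0.10, 0.055, 0.12), 0.95),
    ((0.68, 0.16, 0.40), (0.10, 0.055, 0.12), 0.90),
    ((0.38, 0.30, 0.62), (0.08, 0.050, 0.10), 0.05),
    ((0.62, 0.30, 0.62), (0.08, 0.050, 0.10), 0.10),
    ((0.30, 0.45, 0.50), (0.09, 0.060, 0.09), 0.85),
    ((0.70, 0.45, 0.50), (0.09, 0.060, 0.09), 0.80),
    ((0.40, 0.60, 0.35), (0.07, 0.050, 0.14), 0.15),
    ((0.60, 0.60, 0.35), (0.07, 0.050, 0.14), 0.20),
    ((0.35, 0.76, 0.58), (0.09, 0.055, 0.10), 1.00),
    ((0.65, 0.76, 0.58), (0.09, 0.055, 0.10), 0.75),
    ((0.50, 0.88, 0.45), (0.10, 0.045, 0.12), 0.90),
    # unpaired asymmetric nucleus
    ((0.68, 0.52, 0.72), (0.06, 0.045, 0.08), 0.65),
)


def generate_phantom(
    seed: int = 0,
    shape: tuple[int, int, int] = (64, 128, 64),
    texture_amplitude: float = 0.10,
    texture_sigma: tuple[float, float, float] = (1.5, 0.6, 1.5),
    convention: AtlasConvention | None = None,
) -> VolumeTemplate:
    """Build the deterministic phantom volume.

    The envelope is an ellipsoid with semi-axes 0.45 x shape; interior base
    intensity rises linearly along y so that every coronal level looks
    different, nuclei (see :data:`PHANTOM_NUCLEI`) add discrete landmarks at
    fixed fractional positions, and seeded Gaussian-smoothed noise adds
    texture.  The texture is deliberately anisotropic — much sharper along
    the rostrocaudal axis than in-plane — so that each coronal level carries
    a near-unique fingerprint and small plane mis-placements are
    discriminable.  The mask is exactly the envelope support.  Identical
    seeds give identical volumes.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 16:
        raise ValueError(f"phantom shape must be 3 axes of at least 16 voxels, got {shape}")
    nx, ny, nz = shape
    x, y, z = np.meshgrid(
        np.arange(nx, dtype=float), np.arange(ny, dtype=float), np.arange(nz, dtype=float),
        indexing="ij",
    )
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ax, ay, az = 0.45 * nx, 0.45 * ny, 0.45 * nz
    envelope = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0

    intensity = np.zeros(shape)
    intensity[envelope] = 0.30 + 0.25 * (y[envelope] / (ny - 1))
    for (fx, fy, fz), (sx, sy, sz), value in PHANTOM_NUCLEI:
        r2 = (
            ((x - fx * (nx - 1)) / (sx * nx)) ** 2
            + ((y - fy * (ny - 1)) / (sy * ny)) ** 2
            + ((z - fz * (nz - 1)) / (sz * nz)) ** 2
        )
        intensity[(r2 <= 1.0) & envelope] = value
    rng = np.random.default_rng(seed)
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), texture_sigma)
    texture /= texture.std()
    intensity[envelope] += texture_amplitude * texture[envelope]
    np.clip(intensity, 0.0, 1.0, out=intensity)
    intensity[~envelope] = 0.0
    return VolumeTemplate(
        intensity=intensity,
        mask=envelope,
        convention=convention or AtlasConvention(),
        name=f"phantom-seed{seed}",
    )


def anchor_pixel_coordinates(anchor: SectionAnchor, snap_tol: float = 1e-9) -> np.ndarray:
    """Atlas coordinates of every pixel of an anchor, shape (3, height, width).

    Coordinates within ``snap_tol`` of an integer are snapped onto the voxel
    lattice so that axis-aligned native-resolution planes are reproduced
    bit-exactly despite the i/(width-1) float round-off.
    """
    s = np.arange(anchor.width, dtype=float) / (anchor.width - 1)
    t = np.arange(anchor.height, dtype=float) / (anchor.height - 1)
    coords = (
        anchor.o[:, None, None]
        + anchor.u[:, None, None] * s[None, None, :]
        + anchor.v[:, None, None] * t[None, :, None]
    )
    if snap_tol > 0:
        rounded = np.round(coords)
        near = np.abs(coords - rounded) < snap_tol
        coords[near] = rounded[near]
    return coords


def sample_section(
    volume: VolumeTemplate, anchor: SectionAnchor, order: int = 1
) -> np.ndarray:
    """Render the 2D section an anchor cuts through a volume.

    Pixel (i, j) is the trilinear interpolation (``order=1``; cubic available
    behind ``order=3``) of the volume intensity at the pixel's projected atlas
    coordinate; coordinates outside the volume read as zero.  Returns a
    (height, width) array in [0, 1].
    """
    coords = anchor_pixel_coordinates(anchor)
    flat = coords.reshape(3, -1)
    values = ndimage.map_coordinates(
        volume.intensity, flat, order=order, mode="constant", cval=0.0,
        prefilter=(order > 1),
    )
    return values.reshape(anchor.height, anchor.width)


def axis_aligned_anchor(volume: VolumeTemplate, y: float, filename: str = "plane") -> SectionAnchor:
    """The native-resolution coronal anchor selecting plane ``y`` of a volume."""
    nx, _, nz = volume.shape
    return SectionAnchor(
        filename=filename,
        ox=0.0, oy=float(y), oz=0.0,
        ux=float(nx - 1), uy=0.0, uz=0.0,
        vx=0.0, vy=0.0, vz=float(nz - 1),
        width=nx, height=nz,
    )


def nominal_edge_lengths(volume: VolumeTemplate, frac: float = 0.95) -> tuple[float, float]:
    """Nominal (width, height) edge lengths, in voxels, of a full-frame section."""
    nx, _, nz = volume.shape
    return frac * (nx - 1), frac * (nz - 1)


@dataclass(frozen=True)
class AnchorSampler:
    """Distributional model of realistic coronal anchorings.

    Cutting angles are drawn from zero-mean Gaussians (default SD 4 degrees
    for both DV and ML, matching the spread of slide-mounted histology),
    rostrocaudal center position uniformly over the central 90% of the
    volume's y extent, and an in-plane scale factor from Normal(1, 0.05)
    applied to the nominal full-frame edge lengths.  Sampling is reproducible
    given the seed.
    """

    seed: int = 0
    dv_mean_deg: float = 0.0
    dv_sd_deg: float = 4.0
    ml_mean_deg: float = 0.0
    ml_sd_deg: float = 4.0
    y_margin_frac: float = 0.05
    scale_mean: float = 1.0
    scale_sd: float = 0.05
    edge_frac: float = 0.95

    def __post_init__(self) -> None:
        if self.dv_sd_deg < 0 or self.ml_sd_deg < 0 or self.scale_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0 <= self.y_margin_frac < 0.5:
            raise ValueError("y_margin_frac must be in [0, 0.5)")


def sample_random_anchors(
    sampler: AnchorSampler,
    n: int,
    volume: VolumeTemplate,
    width: int | None = None,
    height: int | None = None,
) -> list[SectionAnchor]:
    """Draw ``n`` random section anchors through a volume.

    Anchors are built in the canonical two-angle family; pixel dimensions
    default to the volume's native x/z extents.  Filenames carry a
    cutting-index token (``synthetic_s001.png`` ...) so the batch doubles as
    CI-weighting test input.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    nx, ny, nz = volume.shape
    width = width or nx
    height = height or nz
    nominal_w, nominal_h = nominal_edge_lengths(volume, sampler.edge_frac)
    cx, cz = (nx - 1) / 2, (nz - 1) / 2
    rng = np.random.default_rng(sampler.seed)
    lo = sampler.y_margin_frac * (ny - 1)
    hi = (1 - sampler.y_margin_frac) * (ny - 1)
    anchors = []
    for k in range(n):
        dv = float(np.clip(rng.normal(sampler.dv_mean_deg, sampler.dv_sd_deg), -89.0, 89.0))
        ml = float(np.clip(rng.normal(sampler.ml_mean_deg, sampler.ml_sd_deg), -89.0, 89.0))
        cy = float(rng.uniform(lo, hi))
        scale = float(max(rng.normal(sampler.scale_mean, sampler.scale_sd), 0.1))
        anchors.append(
            build_anchor_from_angles(
                center=(cx, cy, cz),
                angles=CuttingAngles(dv, ml),
                width_len=scale * nominal_w,
                height_len=scale * nominal_h,
                width=width,
                height=height,
                filename=f"synthetic_s{k + 1:03d}.png",
                cutting_index=k + 1,
            )
        )
    return anchors


def augment(
    image: np.ndarray,
    seed: int = 0,
    noise_sd: float = 0.05,
    dropout_p: float = 0.1,
    warp_grid: tuple[int, int] = (8, 8),
    warp_sd_px: float = 2.0,
) -> np.ndarray:
    """Degrade a rendered section the way real histology degrades.

    Three independent, individually disableable stages, applied in order:
    additive Gaussian noise (clipped back to [0, 1]), independent per-pixel
    dropout to zero with probability ``dropout_p``, and a smooth elastic warp
    driven by a coarse Gaussian displacement grid upsampled to pixel
    resolution (bilinear resampling, outside reads zero).  Deterministic per
    seed; a disabled stage consumes no randomness, so disabling all three is
    the exact identity.
    """
    if noise_sd < 0 or dropout_p < 0 or dropout_p > 1 or warp_sd_px < 0:
        raise ValueError("augmentation parameters must be non-negative (dropout_p in [0, 1])")
    img = np.asarray(image, dtype=float)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, 1.0)
    if dropout_p > 0:
        img = np.where(rng.random(img.shape) < dropout_p, 0.0, img)
    if warp_sd_px > 0:
        gh, gw = warp_grid
        coarse = rng.normal(0.0, warp_sd_px, (2, gh, gw))
        dense = np.stack(
            [ndimage.zoom(c, (img.shape[0] / gh, img.shape[1] / gw), order=3) for c in coarse]
        )
        rows, cols = np.meshgrid(
            np.arange(img.shape[0], dtype=float), np.arange(img.shape[1], dtype=float),
            indexing="ij",
        )
        img = ndimage.map_coordinates(
            img, [rows + dense[0], cols + dense[1]], order=1, mode="constant", cval=0.0,
        )
    return img


def tissue_filter(
    image: np.ndarray,
    min_fraction: float = 0.02,
    intensity_floor: float = 0.02,
    mode: str = "fraction",
    min_bytes: int = 7 * 1024,
) -> bool:
    """Decide whether a rendered section contains enough tissue to keep.

    ``fraction`` mode (default) keeps the image iff the fraction of pixels
    brighter than ``intensity_floor`` is at least ``min_fraction`` — a
    codec-independent criterion.  ``compressed_size`` mode keeps the image iff
    its losslessly PNG-compressed size is at least ``min_bytes`` (default
    7 kB): nearly empty sections compress to almost nothing, so small files
    flag minimal tissue.
    """
    img = np.asarray(image, dtype=float)
    if mode == "fraction":
        return bool((img > intensity_floor).mean() >= min_fraction)
    if mode == "compressed_size":
        buf = io.BytesIO()
        Image.fromarray((np.clip(img, 0, 1) * 255).astype(np.uint8)).save(buf, format="PNG")
        return buf.tell() >= min_bytes
    raise ValueError(f"unknown tissue_filter mode {mode!r}")


def save_volume(volume: VolumeTemplate, path) -> None:
    """Write a volume as NIfTI (intensity), with the mask and a JSON sidecar
    alongside (``*_mask.nii.gz`` / ``*.json``)."""
    import nibabel as nib

    path = Path(path)
    voxel_mm = volume.convention.voxel_size_um / 1000.0
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(volume.intensity.astype(np.float32), affine), str(path))
    base = str(path)
    for suffix in (".nii.gz", ".nii"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
            ext = suffix
            break
    else:
        ext = ".nii.gz"
    nib.save(nib.Nifti1Image(volume.mask.astype(np.uint8), affine), base + "_mask" + ext)
    sidecar = {
        "name": volume.name,
        "voxel_size_um": volume.convention.voxel_size_um,
        "axes": {"x": "mediolateral", "y": "rostrocaudal", "z": "dorsoventral"},
    }
    Path(base + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_volume(path) -> VolumeTemplate:
    """Read a volume written by :func:`save_volume`."""
    import nibabel as nib

    path = Path(path)
    base = str(path)
    for suffix in (".nii.gz", ".nii"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
            ext = suffix
            break
    else:
        raise ValueError(f"expected a .nii or .nii.gz path, got {path}")
    intensity = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    mask_path = Path(base + "_mask" + ext)
    if mask_path.exists():
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = intensity > 0
    convention = AtlasConvention()
    name = Path(base).name
    sidecar = Path(base + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        convention = AtlasConvention(voxel_size_um=float(meta.get("voxel_size_um", 25.0)))
        name = meta.get("name", name)
    return VolumeTemplate(intensity=intensity, mask=mask, convention=convention, name=name)
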