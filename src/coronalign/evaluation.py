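"""Registration-error metric, crowd ground truth, and curation.

The error between two alignments of one image is the mean Euclidean distance,
in atlas voxels, between the two projected positions of each image pixel,
restricted to pixels whose reference projection lands inside the brain mask.
Ground truth for human-aligned data is the "wisdom of the crowd": the
component-wise mean of several operators' anchoring vectors, with each
operator scored leave-one-out against the mean of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anchoring import SectionAnchor, SeriesAlignment
from .postprocess import ensemble
from .slicer import VolumeTemplate, anchor_pixel_coordinates

__all__ = [
    "SectionError",
    "ErrorReport",
    "RaterSet",
    "Summary",
    "EmptyMaskError",
    "registration_error",
    "evaluate_series",
    "crowd_ground_truth",
    "leave_one_out_errors",
    "anchoring_mse",
    "mse_curation_threshold",
    "CurationResult",
    "summarize",
    "voxels_to_um",
]


class EmptyMaskError(ValueError):
    """No pixel of any section projected inside the brain mask."""


@dataclass(frozen=True)
class SectionError:
    """Masked mean voxel distance for one section."""

    mean_voxel_dist: float
    masked_pixels: int
    all_outside: bool = False


def _pixel_grid(anchor: SectionAnchor, grid) -> np.ndarray:
    """Projected atlas coordinates on a (possibly down-sampled) pixel grid."""
    if grid is None:
        return anchor_pixel_coordinates(anchor, snap_tol=0.0)
    gw, gh = (grid, grid) if np.isscalar(grid) else grid
    s = np.linspace(0.0, 1.0, int(gw))
    t = np.linspace(0.0, 1.0, int(gh))
    return (
        anchor.o[:, None, None]
        + anchor.u[:, None, None] * s[None, None, :]
        + anchor.v[:, None, None] * t[None, :, None]
    )


def _in_mask(points: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Nearest-voxel mask membership for an array of atlas points (3, ...)."""
    idx = np.round(points).astype(int)
    inside = np.ones(points.shape[1:], dtype=bool)
    for axis in range(3):
        inside &= (idx[axis] >= 0) & (idx[axis] < mask.shape[axis])
    member = np.zeros(points.shape[1:], dtype=bool)
    if inside.any():
        sel = tuple(idx[axis][inside] for axis in range(3))
        member[inside] = mask[sel]
    return member


def registration_error(
    test: SectionAnchor,
    reference: SectionAnchor,
    mask: VolumeTemplate | np.ndarray,
    grid=None,
    symmetric: bool = False,
) -> SectionError:
    """Masked mean voxel distance between two alignments of one image.

    Every pixel of the image is projected into atlas space under both
    anchorings; a pixel contributes if the *reference* projection falls inside
    the brain mask (nearest-voxel lookup; ``symmetric=True`` instead admits a
    pixel if either projection is in-mask).  The result is the mean Euclidean
    distance, in voxels, over contributing pixels; projected coordinates stay
    continuous (no rounding) in the distance itself.  ``grid`` down-samples
    the pixel lattice (int or (gw, gh)); the default uses the native
    width x height.  If no pixel is in-mask the ``all_outside`` flag is set
    rather than reporting a silent zero.
    """
    if (test.width, test.height) != (reference.width, reference.height):
        raise ValueError(
            f"pixel dimensions differ: test {test.width}x{test.height} "
            f"vs reference {reference.width}x{reference.height}"
        )
    mask_arr = mask.mask if isinstance(mask, VolumeTemplate) else np.asarray(mask).astype(bool)
    p_test = _pixel_grid(test, grid)
    p_ref = _pixel_grid(reference, grid)
    keep = _in_mask(p_ref, mask_arr)
    if symmetric:
        keep |= _in_mask(p_test, mask_arr)
    n = int(keep.sum())
    if n == 0:
        return SectionError(mean_voxel_dist=float("nan"), masked_pixels=0, all_outside=True)
    dists = np.linalg.norm((p_test - p_ref)[:, keep], axis=0)
    return SectionError(mean_voxel_dist=float(dists.mean()), masked_pixels=n)


@dataclass
class ErrorReport:
    """Per-section masked distances plus dataset summary statistics.

    ``dataset_median`` and ``dataset_iqr`` (25th, 75th percentiles, linear
    interpolation) are taken over the per-section mean distances of sections
    with at least one in-mask pixel.
    """

    per_section: dict[str, SectionError]
    voxel_size_um: float = 25.0

    @property
    def distances(self) -> np.ndarray:
        return np.array(
            [e.mean_voxel_dist for e in self.per_section.values() if not e.all_outside]
        )

    @property
    def dataset_median(self) -> float:
        return float(np.median(self.distances))

    @property
    def dataset_iqr(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.distances, [25, 75])
        return float(lo), float(hi)


def evaluate_series(
    test: SeriesAlignment,
    reference: SeriesAlignment,
    mask: VolumeTemplate | np.ndarray,
    grid=None,
    voxel_size_um: float | None = None,
    symmetric: bool = False,
) -> ErrorReport:
    """Score a test alignment against a reference, section by filename."""
    test_names, ref_names = set(test.filenames), set(reference.filenames)
    if test_names != ref_names:
        diff = sorted(test_names.symmetric_difference(ref_names))
        raise ValueError(f"test and reference filename sets differ: {', '.join(diff)}")
    if voxel_size_um is None:
        voxel_size_um = mask.convention.voxel_size_um if isinstance(mask, VolumeTemplate) else 25.0
    per_section = {
        s.filename: registration_error(s, reference.get(s.filename), mask, grid, symmetric)
        for s in test
    }
    if all(e.all_outside for e in per_section.values()):
        raise EmptyMaskError("every section projected entirely outside the brain mask")
    return ErrorReport(per_section=per_section, voxel_size_um=voxel_size_um)


@dataclass
class RaterSet:
    """Independent alignments of one image set by several human operators."""

    alignments: dict[str, SeriesAlignment]
    expertise: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = None
        for op, series in self.alignments.items():
            current = set(series.filenames)
            if names is None:
                names = current
            elif current != names:
                diff = sorted(names.symmetric_difference(current))
                raise ValueError(
                    f"operator {op!r} covers a different image set; differing: {', '.join(diff)}"
                )
        for op, label in self.expertise.items():
            if label not in ("novice", "intermediate", "expert"):
                raise ValueError(f"unknown expertise label {label!r} for operator {op!r}")

    @property
    def operators(self) -> list[str]:
        return list(self.alignments)


def crowd_ground_truth(raters: RaterSet) -> SeriesAlignment:
    """Consensus alignment: per-image component-wise mean over all operators."""
    if len(raters.alignments) < 2:
        raise ValueError("crowd ground truth needs at least two operators")
    return ensemble(list(raters.alignments.values()))


def leave_one_out_errors(
    raters: RaterSet,
    mask: VolumeTemplate | np.ndarray,
    grid=None,
) -> dict[str, ErrorReport]:
    """Score each operator against the mean alignment of all the others."""
    ops = raters.operators
    if len(ops) < 3:
        raise ValueError("leave-one-out scoring needs at least three operators")
    reports = {}
    for op in ops:
        others = [raters.alignments[o] for o in ops if o != op]
        reference = ensemble(others)
        reports[op] = evaluate_series(raters.alignments[op], reference, mask, grid)
    return reports


def anchoring_mse(a: SectionAnchor, b: SectionAnchor) -> float:
    """Mean squared difference over the nine anchoring components (voxels^2)."""
    if (a.width, a.height) != (b.width, b.height):
        raise ValueError(
            f"pixel dimensions differ: {a.width}x{a.height} vs {b.width}x{b.height}"
        )
    diff = a.components - b.components
    return float(np.mean(diff**2))


@dataclass
class CurationResult:
    """Outcome of MSE-elbow curation over a set of alignment errors."""

    threshold: float
    kept: list[int]
    excluded: list[int]
    elbow_found: bool


def mse_curation_threshold(
    mse_values,
    manual_threshold: float | None = None,
    eps: float = 1e-12,
) -> CurationResult:
    """Find the inflection point past which alignment MSE grows exponentially.

    Values are sorted ascending and log(MSE + eps) is plotted against
    normalized rank; the threshold is the value at the point of maximum
    perpendicular distance to the chord joining the curve's endpoints (the
    elbow/knee rule).  Items strictly above the threshold are excluded as
    likely-misaligned.  A ``manual_threshold`` bypasses detection entirely;
    an all-identical input has no elbow and excludes nothing.
    """
    values = np.asarray(list(mse_values), dtype=float)
    if (values < 0).any():
        raise ValueError("MSE values must be non-negative")
    if manual_threshold is not None:
        excluded = np.flatnonzero(values > manual_threshold)
        kept = np.flatnonzero(values <= manual_threshold)
        return CurationResult(float(manual_threshold), kept.tolist(), excluded.tolist(), True)
    if len(values) < 10:
        raise ValueError("elbow detection needs at least 10 values")
    order = np.argsort(values, kind="stable")
    srt = values[order]
    if srt[0] == srt[-1]:
        return CurationResult(float(srt[-1]), list(range(len(values))), [], False)
    x = np.arange(len(srt)) / (len(srt) - 1)
    y = np.log(srt + eps)
    # perpendicular distance of each point to the chord between the endpoints
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    dist = np.abs(dx * (y - y[0]) - dy * (x - x[0])) / np.hypot(dx, dy)
    elbow = int(np.argmax(dist))
    threshold = float(srt[elbow])
    excluded = np.flatnonzero(values > threshold)
    kept = np.flatnonzero(values <= threshold)
    return CurationResult(threshold, kept.tolist(), excluded.tolist(), True)


def voxels_to_um(voxels: float, voxel_size_um: float = 25.0) -> float:
    return voxels * voxel_size_um


def _round_to_10(value: float) -> int:
    return int(np.floor(value / 10.0 + 0.5) * 10)


@dataclass(frozen=True)
class Summary:
    """Dataset-level summary of an error report, in voxels and micrometres."""

    median_voxels: float
    iqr_voxels: tuple[float, float]
    median_um: float
    median_um_rounded: int
    n_sections: int


def summarize(report: ErrorReport) -> Summary:
    """Median and interquartile range of per-section errors, with micrometre
    conversion (raw, and rounded to the nearest 10 um)."""
    distances = report.distances
    if len(distances) == 0:
        raise ValueError("cannot summarize an empty error report")
    median = float(np.median(distances))
    um = voxels_to_um(median, report.voxel_size_um)
    return Summary(
        median_voxels=median,
        iqr_voxels=report.dataset_iqr,
        median_um=um,
        median_um_rounded=_round_to_10(um),
        n_sections=len(distances),
    )
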