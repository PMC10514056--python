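"""Post-hoc adjustment of per-section alignment predictions.

Sections cut serially from one tissue block share a cutting-plane
orientation and (approximately) a constant thickness.  Three adjustments
exploit this:

* **Angle Integration (AI)** — measure the cutting angles of every section in
  a series, average them, and re-parametrize each section to the pooled
  average while preserving its center and edge lengths.
* **Cutting-Index (CI) weighting** — parse the serial cutting order from
  filenames, estimate a constant section thickness from the rostrocaudal
  spacing of the predictions, and re-space the sections so their centers are
  exactly affine in cutting index.
* **Model ensembling** — component-wise averaging of anchoring vectors
  predicted for the same images by several predictors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .anchoring import (
    CuttingAngles,
    SectionAnchor,
    SeriesAlignment,
    build_anchor_from_angles,
    compute_cutting_angles,
    section_center,
)

__all__ = [
    "ThicknessEstimate",
    "EmptySeriesError",
    "InsufficientDataError",
    "MissingCuttingIndexError",
    "FilenameMismatchError",
    "angle_integration",
    "parse_cutting_index",
    "assign_cutting_indices",
    "estimate_thickness",
    "apply_cutting_index",
    "ensemble",
    "DEFAULT_CI_PATTERN",
]

#: Default filename pattern for the cutting-index token, e.g. "Exp_s001.tiff" -> 1.
DEFAULT_CI_PATTERN = r"_s(\d+)"


class EmptySeriesError(ValueError):
    """An operation that needs sections was given an empty series."""


class InsufficientDataError(ValueError):
    """Not enough distinct cutting indices to estimate a thickness."""


class MissingCuttingIndexError(ValueError):
    """Sections lack the cutting index required for CI weighting."""

    def __init__(self, filenames: list[str]):
        self.filenames = list(filenames)
        super().__init__(f"sections without a cutting index: {', '.join(self.filenames)}")


class FilenameMismatchError(ValueError):
    """Series to be ensembled do not cover the same image set."""


@dataclass(frozen=True)
class ThicknessEstimate:
    """Estimated rostrocaudal thickness per cutting-index step, in voxels.

    Negative thickness means sectioning ran caudal-to-rostral.  ``method`` is
    ``pairwise_mean`` (mean of adjacent-pair slopes) or ``ols`` (least-squares
    slope of center-y against cutting index); ``n_pairs`` counts the adjacent
    pairs used.
    """

    thickness_voxels: float
    method: str
    n_pairs: int

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not np.isfinite(self.thickness_voxels):
            raise ValueError("thickness must be finite")


def angle_integration(series: SeriesAlignment, trim: float = 0.0) -> SeriesAlignment:
    """Normalize every section's cutting angles to the series average.

    Each section is rebuilt in the canonical two-angle plane family with the
    pooled mean (DV, ML) angles, keeping its own center, edge lengths, pixel
    dimensions, filename and cutting index.  ``trim`` optionally applies a
    symmetric trimmed mean (fraction cut from each tail); the default is the
    plain arithmetic mean over all sections.
    """
    if len(series) == 0:
        raise EmptySeriesError("angle integration needs at least one section")
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    angles = [compute_cutting_angles(s) for s in series]
    dv = np.array([a.dv_deg for a in angles])
    ml = np.array([a.ml_deg for a in angles])
    if trim > 0:
        mean_angles = CuttingAngles(stats.trim_mean(dv, trim), stats.trim_mean(ml, trim))
    else:
        mean_angles = CuttingAngles(float(dv.mean()), float(ml.mean()))
    out = [
        build_anchor_from_angles(
            center=section_center(s),
            angles=mean_angles,
            width_len=float(np.linalg.norm(s.u)),
            height_len=float(np.linalg.norm(s.v)),
            width=s.width,
            height=s.height,
            filename=s.filename,
            cutting_index=s.cutting_index,
        )
        for s in series
    ]
    return series.with_sections(out)


def parse_cutting_index(filename: str, pattern: str = DEFAULT_CI_PATTERN) -> int | None:
    """Extract the cutting-index integer from a filename.

    ``pattern`` must contain exactly one capture group; when it matches more
    than once the last match wins (order tokens conventionally trail the
    experiment identifier).  Returns None when nothing matches.
    """
    compiled = re.compile(pattern)
    if compiled.groups != 1:
        raise ValueError(
            f"cutting-index pattern must have exactly one capture group, "
            f"{pattern!r} has {compiled.groups}"
        )
    matches = compiled.findall(filename)
    if not matches:
        return None
    return int(matches[-1])


def assign_cutting_indices(
    series: SeriesAlignment, pattern: str = DEFAULT_CI_PATTERN
) -> SeriesAlignment:
    """Return a copy of the series with cutting indices parsed from filenames."""
    return series.with_sections(
        [s.replace(cutting_index=parse_cutting_index(s.filename, pattern)) for s in series]
    )


def _center_y(anchor: SectionAnchor) -> float:
    return float(section_center(anchor)[1])


def _require_indices(series: SeriesAlignment) -> None:
    missing = [s.filename for s in series if s.cutting_index is None]
    if missing:
        raise MissingCuttingIndexError(missing)


def estimate_thickness(series: SeriesAlignment, method: str = "pairwise_mean") -> ThicknessEstimate:
    """Estimate section thickness (voxels per cutting-index step).

    ``pairwise_mean`` divides the difference in rostrocaudal center position
    between adjacent sections (sorted by cutting index) by the change in
    cutting index and averages across the series; ``ols`` fits a least-squares
    line of center-y against cutting index.  The two agree exactly when the
    index gaps are uniform and the positions are affine in the index.
    """
    if method not in ("pairwise_mean", "ols"):
        raise ValueError(f"unknown thickness method {method!r}")
    _require_indices(series)
    pairs = sorted((s.cutting_index, _center_y(s)) for s in series)
    ci = np.array([p[0] for p in pairs], dtype=float)
    cy = np.array([p[1] for p in pairs], dtype=float)
    if len(np.unique(ci)) < 2:
        raise InsufficientDataError(
            "thickness estimation needs at least two sections with distinct cutting indices"
        )
    dci = np.diff(ci)
    keep = dci != 0
    n_pairs = int(keep.sum())
    if method == "pairwise_mean":
        slopes = np.diff(cy)[keep] / dci[keep]
        thickness = float(slopes.mean())
    else:
        thickness = float(np.polyfit(ci, cy, 1)[0])
    return ThicknessEstimate(thickness_voxels=thickness, method=method, n_pairs=n_pairs)


def apply_cutting_index(
    series: SeriesAlignment, estimate: ThicknessEstimate | None = None
) -> SeriesAlignment:
    """Re-space sections rostrocaudally using their cutting indices.

    Each section is translated along the rostrocaudal (y) axis only, so that
    its center position becomes ``mean(C_y) + t * (CI - mean(CI))``: centers
    are exactly affine in cutting index and the mean rostrocaudal position of
    the series is preserved.  A series already affine in CI is a fixed point.
    """
    if len(series) == 0:
        raise EmptySeriesError("cutting-index weighting needs at least one section")
    _require_indices(series)
    if estimate is None:
        estimate = estimate_thickness(series)
    t = estimate.thickness_voxels
    ci = np.array([s.cutting_index for s in series], dtype=float)
    cy = np.array([_center_y(s) for s in series])
    target = cy.mean() + t * (ci - ci.mean())
    out = [s.translated((0.0, ty - y, 0.0)) for s, ty, y in zip(series, target, cy)]
    return series.with_sections(out)


def ensemble(series_list: list[SeriesAlignment]) -> SeriesAlignment:
    """Average anchoring vectors across several alignments of the same images.

    Per filename, each of the nine anchoring components is the arithmetic
    mean across inputs; pixel dimensions must agree.  The operation is
    permutation-invariant and idempotent (an ensemble of one series, or of k
    copies, is that series).  Section order follows the first input.
    """
    if not series_list:
        raise ValueError("ensemble needs at least one series")
    first = series_list[0]
    ref_names = set(first.filenames)
    for other in series_list[1:]:
        names = set(other.filenames)
        if names != ref_names:
            diff = sorted(ref_names.symmetric_difference(names))
            raise FilenameMismatchError(
                f"series {other.name!r} does not match {first.name!r}; "
                f"differing filenames: {', '.join(diff)}"
            )
    out = []
    for s in first:
        group = [other.get(s.filename) for other in series_list]
        for g in group:
            if (g.width, g.height) != (s.width, s.height):
                raise ValueError(
                    f"{s.filename!r}: pixel dimensions differ across series "
                    f"({g.width}x{g.height} vs {s.width}x{s.height})"
                )
        mean = np.mean([g.components for g in group], axis=0)
        out.append(
            SectionAnchor.from_components(
                s.filename, mean, width=s.width, height=s.height, cutting_index=s.cutting_index
            )
        )
    return first.with_sections(out)
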