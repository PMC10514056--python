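"""Synthetic benchmark experiments for the alignment pipeline.

Two desk-scale experiments quantify the pipeline on the phantom volume:

* **Generate-and-recover** — sample random section anchors, render them
  (optionally degraded), and template-match the images back into the volume;
  the recovered rostrocaudal positions and cutting angles are compared to
  the known truth.
* **Post-processing benefit** — simulate a serial series whose per-section
  predictions carry independent angle and position noise, then measure the
  masked registration error before and after angle integration (AI) and
  cutting-index (CI) weighting, including how the CI benefit scales with
  batch size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anchoring import (
    CuttingAngles,
    SeriesAlignment,
    build_anchor_from_angles,
    compute_cutting_angles,
    section_center,
)
from .evaluation import registration_error
from .postprocess import angle_integration, apply_cutting_index, estimate_thickness
from .predictor import MatchSearchSpec, template_match_predict
from .slicer import (
    AnchorSampler,
    VolumeTemplate,
    augment,
    nominal_edge_lengths,
    sample_random_anchors,
    sample_section,
)

__all__ = [
    "RecoveryResult",
    "recovery_experiment",
    "PipelineBenefitResult",
    "make_serial_series",
    "perturb_series",
    "pipeline_benefit_experiment",
]


@dataclass
class RecoveryResult:
    """Per-section recovery errors of a generate-and-recover run."""

    y_errors: np.ndarray
    dv_errors: np.ndarray
    ml_errors: np.ndarray

    @property
    def n(self) -> int:
        return len(self.y_errors)

    def success_rate(self, y_tol: float = 1.0, angle_tol: float = 0.5) -> float:
        """Fraction of sections recovered within the given tolerances."""
        ok = (
            (self.y_errors <= y_tol)
            & (self.dv_errors <= angle_tol)
            & (self.ml_errors <= angle_tol)
        )
        return float(ok.mean())

    @property
    def median_y_error(self) -> float:
        return float(np.median(self.y_errors))


def recovery_experiment(
    volume: VolumeTemplate,
    n: int = 25,
    seed: int = 11,
    max_angle_deg: float = 8.0,
    augmented: bool = False,
    spec: MatchSearchSpec | None = None,
) -> RecoveryResult:
    """Render ``n`` random sections and template-match them back.

    Anchors are drawn from the standard sampler and restricted to cutting
    angles within ``max_angle_deg`` (so the truth lies inside the matcher's
    search range); with ``augmented=True`` each rendering passes through the
    default noise/dropout/warp augmentation before matching.
    """
    candidates = sample_random_anchors(AnchorSampler(seed=seed), 8 * n, volume)
    anchors = [
        a
        for a in candidates
        if abs(compute_cutting_angles(a).dv_deg) <= max_angle_deg
        and abs(compute_cutting_angles(a).ml_deg) <= max_angle_deg
    ][:n]
    if len(anchors) < n:
        raise RuntimeError(f"only {len(anchors)} in-range anchors out of {8 * n} draws")
    y_err, dv_err, ml_err = [], [], []
    for k, anchor in enumerate(anchors):
        image = sample_section(volume, anchor)
        if augmented:
            image = augment(image, seed=seed * 10_000 + k)
        result = template_match_predict(image, volume, spec)
        truth = compute_cutting_angles(anchor)
        found = compute_cutting_angles(result.anchor)
        y_err.append(abs(section_center(anchor)[1] - section_center(result.anchor)[1]))
        dv_err.append(abs(truth.dv_deg - found.dv_deg))
        ml_err.append(abs(truth.ml_deg - found.ml_deg))
    return RecoveryResult(np.array(y_err), np.array(dv_err), np.array(ml_err))


def make_serial_series(
    volume: VolumeTemplate,
    n_sections: int = 30,
    angles: CuttingAngles = CuttingAngles(3.0, -2.0),
    thickness_voxels: float = 3.0,
    name: str = "simulated",
) -> SeriesAlignment:
    """Ground-truth serial series: common cutting angles, uniform thickness.

    Sections are centered on the volume's x/z midline with rostrocaudal
    centers spaced ``thickness_voxels`` apart around the volume middle, and
    filenames carry sequential cutting-index tokens (``sim_s001.png`` ...).
    """
    nx, ny, nz = volume.shape
    wl, hl = nominal_edge_lengths(volume)
    cx, cz = (nx - 1) / 2, (nz - 1) / 2
    mid = (ny - 1) / 2
    offsets = (np.arange(n_sections) - (n_sections - 1) / 2) * thickness_voxels
    sections = [
        build_anchor_from_angles(
            center=(cx, mid + off, cz),
            angles=angles,
            width_len=wl,
            height_len=hl,
            width=nx,
            height=nz,
            filename=f"sim_s{k + 1:03d}.png",
            cutting_index=k + 1,
        )
        for k, off in enumerate(offsets)
    ]
    return SeriesAlignment(name=name, sections=sections)


def perturb_series(
    series: SeriesAlignment,
    seed: int,
    angle_sd_deg: float = 2.0,
    y_sd_voxels: float = 2.0,
) -> SeriesAlignment:
    """Emulate per-section predictor noise on a ground-truth series.

    Each section's cutting angles get independent Gaussian errors and its
    center is shifted rostrocaudally by Gaussian noise — the error structure
    of a per-image predictor that sees each section in isolation.
    """
    rng = np.random.default_rng(seed)
    out = []
    for s in series:
        truth = compute_cutting_angles(s)
        noisy = CuttingAngles(
            truth.dv_deg + rng.normal(0, angle_sd_deg),
            truth.ml_deg + rng.normal(0, angle_sd_deg),
        )
        center = section_center(s) + np.array([0.0, rng.normal(0, y_sd_voxels), 0.0])
        out.append(
            build_anchor_from_angles(
                center=center,
                angles=noisy,
                width_len=float(np.linalg.norm(s.u)),
                height_len=float(np.linalg.norm(s.v)),
                width=s.width,
                height=s.height,
                filename=s.filename,
                cutting_index=s.cutting_index,
            )
        )
    return series.with_sections(out)


def _median_error(
    test: SeriesAlignment, truth: SeriesAlignment, volume: VolumeTemplate, grid: int
) -> float:
    dists = [
        registration_error(s, truth.get(s.filename), volume, grid=grid).mean_voxel_dist
        for s in test
    ]
    return float(np.median(dists))


@dataclass
class PipelineBenefitResult:
    """Outcome of the post-processing benefit simulation."""

    median_before: float
    median_after_ai: float
    median_after_ai_ci: float
    batch_sizes: list[int] = field(default_factory=list)
    ci_benefit_by_batch: dict[int, float] = field(default_factory=dict)


def pipeline_benefit_experiment(
    volume: VolumeTemplate,
    seed: int = 0,
    n_sections: int = 30,
    batch_sizes: tuple[int, ...] = (5, 10, 20, 30),
    n_reps: int = 200,
    angle_sd_deg: float = 2.0,
    y_sd_voxels: float = 2.0,
    grid: int = 16,
) -> PipelineBenefitResult:
    """Measure how AI and CI weighting improve noisy per-section predictions.

    A ground-truth 30-section serial series is perturbed with per-section
    predictor noise; the masked median registration error is computed raw,
    after angle integration, and after angle integration plus cutting-index
    re-spacing.  The CI benefit (median error with AI only minus with AI+CI)
    is then estimated per batch size by repeatedly subsampling the series,
    mirroring how serial datasets of different lengths respond to CI
    weighting: with few sections the thickness estimate is noisy and CI can
    even hurt, while longer series are re-spaced almost perfectly.
    """
    truth = make_serial_series(volume, n_sections=n_sections)
    noisy = perturb_series(truth, seed=seed, angle_sd_deg=angle_sd_deg, y_sd_voxels=y_sd_voxels)
    ai = angle_integration(noisy)
    ai_ci = apply_cutting_index(ai, estimate_thickness(ai))
    result = PipelineBenefitResult(
        median_before=_median_error(noisy, truth, volume, grid),
        median_after_ai=_median_error(ai, truth, volume, grid),
        median_after_ai_ci=_median_error(ai_ci, truth, volume, grid),
        batch_sizes=list(batch_sizes),
    )
    rng = np.random.default_rng(seed + 1)
    for b in batch_sizes:
        diffs = []
        for rep in range(n_reps):
            keep = sorted(rng.choice(n_sections, size=b, replace=False))
            sub_truth = truth.with_sections([truth.sections[i] for i in keep])
            sub_noisy = perturb_series(
                sub_truth, seed=seed * 100_000 + rep * 100 + b,
                angle_sd_deg=angle_sd_deg, y_sd_voxels=y_sd_voxels,
            )
            sub_ai = angle_integration(sub_noisy)
            sub_ci = apply_cutting_index(sub_ai, estimate_thickness(sub_ai))
            diffs.append(
                _median_error(sub_ai, sub_truth, volume, grid)
                - _median_error(sub_ci, sub_truth, volume, grid)
            )
        result.ci_benefit_by_batch[b] = float(np.mean(diffs))
    return result
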