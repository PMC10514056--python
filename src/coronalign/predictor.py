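"""Section-to-volume prediction: the predictor contract and a brute-force
coarse-to-fine template-matching reference predictor.

A *predictor* is anything that maps a section image to the nine anchoring
components.  The production-scale approach is a convolutional regressor (its
training protocol is documented in :class:`PredictorProtocolConfig`); the
reference implementation shipped here is an exhaustive template matcher that
renders candidate planes through the volume with the virtual slicer and
scores them by normalized cross-correlation, which makes every downstream
stage testable end-to-end on the phantom without a trained network.
"""

from __future__ import annotations

import inspect
import json
from dataclasses import asdict, dataclass

import numpy as np
from skimage.color import rgb2gray
from skimage.transform import resize

from .anchoring import CuttingAngles, SectionAnchor, SeriesAlignment, build_anchor_from_angles
from .slicer import VolumeTemplate, nominal_edge_lengths

__all__ = [
    "PredictorProtocolConfig",
    "MatchSearchSpec",
    "MatchResult",
    "TemplateMatchPredictor",
    "preprocess_image",
    "predict_series",
    "template_match_predict",
]


@dataclass(frozen=True)
class PredictorProtocolConfig:
    """Constants of the CNN regression protocol (documented, not trained here).

    A pretrained image backbone is truncated and topped with two 256-unit
    ReLU dense layers and nine linear outputs (the anchoring components),
    optimized with MSE loss under Adam at an initial learning rate of 0.001
    (dropped to 0.0001 at the final plateau) and batch size 8, on grayscale
    299 x 299 inputs; backbone layers are unfrozen stage-wise as the loss
    plateaus.
    """

    input_size: tuple[int, int] = (299, 299)
    grayscale: bool = True
    dense_units: tuple[int, int] = (256, 256)
    dense_activation: str = "relu"
    n_outputs: int = 9
    output_activation: str = "linear"
    loss: str = "mse"
    optimizer: str = "adam"
    initial_learning_rate: float = 1e-3
    final_learning_rate: float = 1e-4
    batch_size: int = 8
    staged_unfreezing: bool = True

    def __post_init__(self) -> None:
        if min(self.input_size) < 1 or self.n_outputs < 1 or self.batch_size < 1:
            raise ValueError("sizes must be positive")
        if not 0 < self.final_learning_rate <= self.initial_learning_rate:
            raise ValueError("learning rates must satisfy 0 < final <= initial")
        if any(u < 1 for u in self.dense_units):
            raise ValueError("dense layer widths must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PredictorProtocolConfig":
        doc = json.loads(text)
        for key in ("input_size", "dense_units"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


def preprocess_image(image) -> np.ndarray:
    """Standardize an input image: grayscale, 299 x 299, min-max to [0, 1].

    Color inputs are converted to luminance; resizing uses anti-aliased
    (area-averaging) interpolation; a constant image maps to all zeros.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 3:
        img = rgb2gray(img[..., :3])
    elif img.ndim != 2:
        raise ValueError(f"expected a 2D or 2D+channels image, got shape {img.shape}")
    size = PredictorProtocolConfig().input_size
    if img.shape != size:
        img = resize(img, size, order=1, anti_aliasing=True, mode="reflect")
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros(size)
    return (img - lo) / (hi - lo)


@dataclass(frozen=True)
class MatchSearchSpec:
    """Search grid of the coarse-to-fine template matcher.

    Coarse stage: rostrocaudal center every ``coarse_y_step`` voxels across
    the usable y extent, DV/ML angles on ±``angle_range_deg`` at
    ``coarse_angle_step``, in-plane scale on ``scale_range`` at
    ``scale_step``.  Fine stage: a joint (y, dv, ml) grid around the coarse
    optimum with half-widths equal to the coarse steps (so the fine range
    always brackets the coarse optimum) at the fine steps; scale stays at
    the coarse optimum.  Similarity is normalized cross-correlation on
    ``match_size``-squared renderings.
    """

    coarse_y_step: float = 4.0
    fine_y_step: float = 0.5
    angle_range_deg: float = 10.0
    coarse_angle_step: float = 2.0
    fine_angle_step: float = 0.25
    scale_range: tuple[float, float] = (0.9, 1.1)
    scale_step: float = 0.05
    match_size: int = 64
    y_margin_frac: float = 0.05
    chunk_size: int = 1024
    n_seeds: int = 8

    def __post_init__(self) -> None:
        for name in ("coarse_y_step", "fine_y_step", "coarse_angle_step", "fine_angle_step", "scale_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fine_y_step > self.coarse_y_step or self.fine_angle_step > self.coarse_angle_step:
            raise ValueError("fine steps must not exceed coarse steps")
        if self.match_size < 8:
            raise ValueError("match_size must be at least 8")


@dataclass
class MatchResult:
    """Best-matching anchor and its similarity score; ``no_match`` flags a
    degenerate (featureless) query."""

    anchor: SectionAnchor | None
    score: float
    no_match: bool = False


def _normalize(img: np.ndarray) -> np.ndarray | None:
    flat = img.ravel() - img.mean()
    norm = np.linalg.norm(flat)
    if norm == 0:
        return None
    return flat / norm


def _render_batch(volume: VolumeTemplate, candidates, lens, m: int, chunk: int,
                  order: int = 1) -> np.ndarray:
    """Render candidate planes at m x m and return row-normalized images.

    ``candidates`` is an (n, 4) array of (y, dv, ml, scale); ``lens`` the
    nominal (width, height) edge lengths.  Rows with zero variance come back
    as all-NaN so their correlation is never selected.
    """
    from scipy import ndimage

    nx, _, nz = volume.shape
    cx, cz = (nx - 1) / 2, (nz - 1) / 2
    s = (np.arange(m) / (m - 1)).astype(np.float32)
    intensity = volume.intensity.astype(np.float32)
    out = np.empty((len(candidates), m * m), dtype=np.float32)
    for start in range(0, len(candidates), chunk):
        block = candidates[start : start + chunk].astype(np.float32)
        y, dv, ml, scale = (block[:, k] for k in range(4))
        wl = scale * np.float32(lens[0])
        hl = scale * np.float32(lens[1])
        ml_r, dv_r = np.radians(ml), np.radians(dv)
        u = np.stack([wl * np.cos(ml_r), wl * np.sin(ml_r), np.zeros_like(wl)], axis=1)
        v = np.stack([np.zeros_like(hl), hl * np.sin(dv_r), hl * np.cos(dv_r)], axis=1)
        center = np.stack([np.full_like(y, cx), y, np.full_like(y, cz)], axis=1)
        o = center - (u + v) / 2
        # coords: (batch, 3, m, m) -> flatten for one interpolation call
        coords = (
            o[:, :, None, None]
            + u[:, :, None, None] * s[None, None, None, :]
            + v[:, :, None, None] * s[None, None, :, None]
        )
        flat = np.ascontiguousarray(np.moveaxis(coords, 1, 0)).reshape(3, -1)
        vals = ndimage.map_coordinates(
            intensity, flat, order=order, mode="constant", cval=0.0, prefilter=False
        ).reshape(len(block), m * m)
        vals = vals - vals.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(vals, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(norms > 0, vals / norms, np.nan)
        out[start : start + chunk] = vals
    return out


def _score_candidates(volume, query_n, candidates, lens, spec, order: int = 1):
    """NCC scores per candidate, with candidates re-ordered so that argmax
    ties break toward smaller |angles|, then smaller y."""
    tie = np.lexsort((candidates[:, 0], np.abs(candidates[:, 1]) + np.abs(candidates[:, 2])))
    candidates = candidates[tie]
    rendered = _render_batch(volume, candidates, lens, spec.match_size, spec.chunk_size, order)
    scores = np.nan_to_num(rendered @ query_n.astype(np.float32), nan=-np.inf)
    return candidates, scores


def _best_candidate(volume, query_n, candidates, lens, spec) -> tuple[np.ndarray, float]:
    candidates, scores = _score_candidates(volume, query_n, candidates, lens, spec)
    best = int(np.argmax(scores))
    return candidates[best], float(scores[best])


def _top_seeds(volume, query_n, candidates, lens, spec) -> list[np.ndarray]:
    """Highest-scoring coarse candidates, kept mutually distinct by
    non-maximum suppression at one coarse step in (y, dv, ml).

    The coarse sweep scores with nearest-neighbour sampling: at a 4-voxel /
    2-degree grid pitch the basin ranking is insensitive to the
    interpolation order, and the sweep dominates the run time."""
    candidates, scores = _score_candidates(volume, query_n, candidates, lens, spec, order=0)
    seeds: list[np.ndarray] = []
    for idx in np.argsort(-scores, kind="stable"):
        c = candidates[idx]
        close = any(
            abs(c[0] - s[0]) <= spec.coarse_y_step
            and abs(c[1] - s[1]) <= spec.coarse_angle_step
            and abs(c[2] - s[2]) <= spec.coarse_angle_step
            for s in seeds
        )
        if not close:
            seeds.append(c)
        if len(seeds) == spec.n_seeds:
            break
    return seeds


def template_match_predict(
    image: np.ndarray,
    volume: VolumeTemplate,
    spec: MatchSearchSpec | None = None,
    filename: str = "query",
    width: int | None = None,
    height: int | None = None,
    edge_frac: float = 0.95,
) -> MatchResult:
    """Locate a section image in a volume by exhaustive rendering.

    Coarse stage: every (y, dv, ml, scale) grid node is rendered through the
    volume and scored by normalized cross-correlation against the
    down-sampled query.  Fine stage: a joint (y, dv, ml) grid around the
    coarse optimum at the fine steps, scale held at its coarse value.  The
    result is deterministic; an all-constant query returns ``no_match``.
    ``width``/``height`` set the pixel dimensions stamped on the returned
    anchor (default: the query image's own shape).
    """
    spec = spec or MatchSearchSpec()
    img = np.asarray(image, dtype=float)
    query = resize(img, (spec.match_size, spec.match_size), order=1, anti_aliasing=True)
    query_n = _normalize(query)
    if query_n is None:
        return MatchResult(anchor=None, score=float("nan"), no_match=True)

    _, ny, _ = volume.shape
    lens = nominal_edge_lengths(volume, edge_frac)
    y_lo = spec.y_margin_frac * (ny - 1)
    y_hi = (1 - spec.y_margin_frac) * (ny - 1)
    ys = np.arange(y_lo, y_hi + 1e-9, spec.coarse_y_step)
    angles = np.arange(-spec.angle_range_deg, spec.angle_range_deg + 1e-9, spec.coarse_angle_step)
    scales = np.arange(spec.scale_range[0], spec.scale_range[1] + 1e-9, spec.scale_step)
    coarse = np.array(np.meshgrid(ys, angles, angles, scales, indexing="ij"))
    coarse = coarse.reshape(4, -1).T
    seeds = _top_seeds(volume, query_n, coarse, lens, spec)

    # intermediate stage: a half-coarse-step grid around each surviving seed,
    # including a half-step scale refinement (the mid range around every seed
    # brackets that seed's coarse cell)
    mid_y, mid_a, mid_s = spec.coarse_y_step / 4, spec.coarse_angle_step / 2, spec.scale_step / 2
    mid = np.concatenate([
        np.array(np.meshgrid(
            np.arange(s[0] - spec.coarse_y_step, s[0] + spec.coarse_y_step + 1e-9, mid_y),
            np.arange(s[1] - spec.coarse_angle_step, s[1] + spec.coarse_angle_step + 1e-9, mid_a),
            np.arange(s[2] - spec.coarse_angle_step, s[2] + spec.coarse_angle_step + 1e-9, mid_a),
            [s[3] - mid_s, s[3], s[3] + mid_s], indexing="ij",
        )).reshape(4, -1).T
        for s in seeds
    ])
    best, _ = _best_candidate(volume, query_n, mid, lens, spec)

    # final stage at the fine steps around the intermediate optimum; if the
    # arg-max lands on the window boundary the optimum was clipped, so the
    # window is re-centered there and the search repeated (hill climbing)
    for _ in range(5):
        fy = np.arange(best[0] - mid_y, best[0] + mid_y + 1e-9, spec.fine_y_step)
        fdv = np.arange(best[1] - mid_a, best[1] + mid_a + 1e-9, spec.fine_angle_step)
        fml = np.arange(best[2] - mid_a, best[2] + mid_a + 1e-9, spec.fine_angle_step)
        fsc = [best[3] - mid_s / 2, best[3], best[3] + mid_s / 2]
        fine = np.array(np.meshgrid(fy, fdv, fml, fsc, indexing="ij")).reshape(4, -1).T
        best, score = _best_candidate(volume, query_n, fine, lens, spec)
        interior = (
            fy[0] + 1e-6 < best[0] < fy[-1] - 1e-6
            and fdv[0] + 1e-6 < best[1] < fdv[-1] - 1e-6
            and fml[0] + 1e-6 < best[2] < fml[-1] - 1e-6
        )
        if interior:
            break

    nx, _, nz = volume.shape
    h, w = img.shape[:2]
    anchor = build_anchor_from_angles(
        center=((nx - 1) / 2, best[0], (nz - 1) / 2),
        angles=CuttingAngles(dv_deg=best[1], ml_deg=best[2]),
        width_len=best[3] * lens[0],
        height_len=best[3] * lens[1],
        width=width or w,
        height=height or h,
        filename=filename,
    )
    return MatchResult(anchor=anchor, score=score)


class TemplateMatchPredictor:
    """Callable predictor wrapping :func:`template_match_predict`."""

    def __init__(self, volume: VolumeTemplate, spec: MatchSearchSpec | None = None,
                 edge_frac: float = 0.95):
        self.volume = volume
        self.spec = spec or MatchSearchSpec()
        self.edge_frac = edge_frac

    def __call__(self, image: np.ndarray, filename: str = "query") -> SectionAnchor:
        result = template_match_predict(
            image, self.volume, self.spec, filename=filename, edge_frac=self.edge_frac
        )
        if result.no_match:
            raise ValueError(f"{filename!r}: degenerate query, no match found")
        return result.anchor


def predict_series(
    images,
    predictor,
    filenames=None,
    name: str = "predicted",
) -> tuple[SeriesAlignment, dict[str, str]]:
    """Run a predictor over a list of images, collecting per-file failures.

    ``predictor`` is any callable mapping an image (and optionally the
    filename keyword) to a :class:`SectionAnchor`.  A failing image is
    recorded in the returned failure map and the run continues; section order
    follows the input order.
    """
    images = list(images)
    if filenames is None:
        filenames = [f"image_{k:03d}.png" for k in range(len(images))]
    if len(filenames) != len(images):
        raise ValueError("filenames and images must have equal length")
    try:
        params = inspect.signature(predictor).parameters
        accepts_filename = "filename" in params or any(
            p.kind is inspect.Parameter.VAR_KEYWORD for p in params.values()
        )
    except (TypeError, ValueError):
        accepts_filename = False
    sections, failures = [], {}
    for fname, img in zip(filenames, images):
        try:
            anchor = predictor(img, filename=fname) if accepts_filename else predictor(img)
            sections.append(anchor.replace(filename=fname))
        except Exception as exc:  # noqa: BLE001 - contract: record and continue
            failures[fname] = str(exc)
    return SeriesAlignment(name=name, sections=sections), failures
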