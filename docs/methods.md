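# Methods

This note documents the models and procedures `coronalign` implements, the
parameters that matter, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Coordinate convention and plane model

All geometry lives in atlas voxel space with a fixed axis order:
x = mediolateral, y = rostrocaudal, z = dorsoventral.  The voxel pitch
(default 25 µm) is carried by `AtlasConvention` and only enters when
distances are converted to micrometres.

A section plane is the QuickNII anchoring triple (O, U, V): O is the atlas
position of the image's top-left corner, U spans the width (left→right), V
the height (top→bottom).  Pixel (i, j) of a w×h image projects to
`O + i/(w−1)·U + j/(h−1)·V`.  The `(w−1)` normalization is deliberate: it
places the corner *pixels* exactly on the corner vectors, which is what
makes corner-based representations round-trip exactly.  The alternative
`i/w` is off by half a pixel at every edge.

Cutting angles are defined directly on the vector components:
`ml = atan2(U_y, U_x)` (how far the width vector swings toward
rostrocaudal) and `dv = atan2(V_y, V_z)`.  The inverse construction —
`build_anchor_from_angles` — uses the canonical two-angle family
U = w·(cos ml, sin ml, 0), V = h·(0, sin dv, cos dv), the minimal
parametrization in which (DV, ML) fully determines plane orientation.
Arbitrary anchors (which may carry in-plane rotation or shear) are
*projected* into this family by angle integration; for near-coronal
histology the discarded components are negligible, and the projection is
what guarantees the angle↔anchor round trip to 1e−9°.  Sign convention:
positive dv tilts the section bottom caudally, positive ml tilts the
image-right edge caudally.

## Post-hoc adjustments

Serial sections cut from one tissue block share a plane orientation and an
approximately constant thickness.  Three adjustments exploit this:

* **Angle Integration (AI).**  Measure (dv, ml) per section, take the
  arithmetic mean over the series, and rebuild every section in the
  canonical family with the mean angles while preserving its own center,
  edge lengths (|U|, |V|), pixel dimensions and metadata.  The mean is
  unweighted (an optional symmetric trimmed mean exists but is off by
  default); there is no outlier rejection.  AI is idempotent, and a
  one-section series is simply re-parametrized with its own angles.
* **Cutting Index (CI).**  The cutting order is parsed from filenames with
  a one-group regular expression (default `_s(\d+)`, e.g.
  `Experiment_s001.tiff` → 1; if the pattern matches several times the last
  match wins, since order tokens conventionally trail identifiers).
  Section thickness per index step is estimated either as the mean of
  adjacent-pair slopes ΔC_y/ΔCI after sorting by index (`pairwise_mean`,
  the default) or as the least-squares slope of C_y on CI (`ols`); the two
  agree exactly on uniform-gap affine data, but with unit gaps the pairwise
  mean telescopes to (last−first)/(n−1) and is endpoint-sensitive, which is
  why the regression option exists.  The adjustment then translates each
  section along y only, to `mean(C_y) + t·(CI − mean(CI))`: centers become
  exactly affine in CI and the series mean position is preserved.  The
  rostrocaudal coordinate used is the *section center*, not O_y, because
  the center is invariant under the AI re-parametrization (the two coincide
  for exactly coronal planes).  Series cut from multiple tissue blocks must
  be split by the caller before CI weighting; there is no automatic block
  detection.
* **Ensembling.**  Per filename, the nine anchoring components are averaged
  across predictors.  The operation is permutation-invariant and
  idempotent, and it is also exactly the crowd-ground-truth construction
  (below).

## Evaluation

The registration error between two anchorings of one image is the mean
Euclidean distance, in voxels, between the two projections of each pixel,
over pixels whose **reference** projection falls inside the brain mask.
Reference-side masking keeps the metric well-defined when many test
alignments are compared against one ground truth; the metric is therefore
not symmetric, and a symmetric either-side mode exists behind a flag.
Projected coordinates stay continuous in the distance computation;
rounding to the nearest voxel happens only for mask membership, avoiding
quantization bias at 25 µm pitch.  An image whose pixels all project
outside the mask is flagged (`all_outside`) rather than scored zero.  The
pixel lattice can be down-sampled (`grid`) for speed; distances are exact
for pure translations at any grid.

Crowd ground truth is the per-image component-wise mean over all operators'
anchoring vectors; each operator is scored leave-one-out against the mean
of the others.  Dataset summaries report the median and 25th/75th
percentiles (linear interpolation — the estimator is a declared choice) of
per-section mean distances, with micrometre conversion given raw and
rounded to the nearest 10 µm.

MSE-based curation sorts error values ascending, plots log(MSE + 1e−12)
against normalized rank, and thresholds at the point of maximum
perpendicular distance to the chord joining the curve's endpoints (the
elbow rule).  The log scale makes the "grows exponentially" tail a straight
climb and the bulk a flat shelf, so the elbow is the shelf's end.  The rule
is deterministic and overridable by a manual threshold; an all-identical
input has no elbow and excludes nothing.

## Virtual sectioning and the phantom

`sample_section` renders pixel (i, j) by trilinear interpolation of the
volume at the projected coordinate, reading 0 outside the volume.  Cubic
interpolation is available behind `order=3`; trilinear is the default
because it is exact on lattice planes and smooth enough for matching.
Coordinates within 1e−9 of an integer are snapped onto the voxel lattice
first: the products `i/(w−1)·U` are not exactly integral in floating point
even for axis-aligned native-resolution anchors, and the snap makes such
slices bit-identical to the stored array planes (the slicer's oracle
property).  The snap perturbs genuinely non-integral coordinates by at most
1e−9 voxel, far below interpolation error.

The phantom volume (default 64×128×64 voxels) is a deterministic synthetic
brain: an ellipsoidal envelope (semi-axes 0.45·shape) whose interior base
intensity rises linearly along y, twelve fixed ellipsoidal nuclei with
distinct intensities — eleven in bilaterally mirrored pairs or on the
midline, one deliberately unpaired so mirrored planes are distinguishable —
plus seeded Gaussian-smoothed texture.  The texture is anisotropic
(σ = 1.5, 0.6, 1.5 voxels in x, y, z; amplitude 0.10 after normalizing the
smoothed field to unit variance): it is much sharper along the rostrocaudal
axis than in-plane, so every coronal level carries a near-unique
fingerprint.  This is what makes position and angle recovery well-posed:
neighbouring slices 8 voxels apart correlate below 0.95, and plane
mis-placements of a fraction of a voxel already cost measurable
cross-correlation.  The mask is exactly the envelope support.

The random anchoring sampler draws DV and ML angles from Normal(0, 4°),
the rostrocaudal center uniformly over the central 90% of the y extent,
and an in-plane scale factor from Normal(1, 0.05) applied to nominal
full-frame edge lengths (95% of the volume's x/z extents).  These spreads
are configurable stand-ins chosen to resemble the angle and size
variability of slide-mounted coronal histology.  Augmentation applies, in
order, additive Gaussian noise (SD 0.05, clipped to [0, 1]), independent
per-pixel dropout (p = 0.1), and a smooth elastic warp (8×8 displacement
grid, SD 2 px, bicubically upsampled, bilinear resampling); each stage is
individually disableable and a disabled stage consumes no randomness, so
disabling all three is the exact identity.  The minimal-tissue filter
defaults to the codec-independent criterion — keep iff ≥ 2% of pixels
exceed intensity 0.02 — with a compressed-size mode (PNG bytes ≥ 7 kB)
retained as the historical file-size proxy; the byte threshold is
codec- and image-size-specific, which is why it is not the default.

## Template-matching predictor

The reference predictor is an exhaustive coarse-to-fine search over
(y-center, dv, ml, in-plane scale), rendering every candidate plane through
the volume and scoring it by normalized cross-correlation against the
query down-sampled to 64×64.  NCC rather than MSE makes the score invariant
to the linear intensity scaling that different stains exhibit.  The
section's x/z center is fixed to the volume midline and the edge-length
ratio to the volume's frame; scale search absorbs the unknown physical
extent.

Search schedule: the coarse stage scans y every 4 voxels across the usable
extent, both angles over ±10° in 2° steps, and scale over 0.9–1.1 in 0.05
steps, scoring with nearest-neighbour sampling (at this grid pitch the
basin ranking does not depend on the interpolation order, and the coarse
sweep dominates run time).  The eight best coarse candidates — kept
mutually distinct by non-maximum suppression at one coarse step — seed an
intermediate trilinear-scored grid at half the coarse steps (y ±4 at step
1, angles ±2° at step 1°, scale ±0.025), and the final stage searches
y at 0.5-voxel and angles at 0.25° steps (scale ±0.0125) around the
intermediate optimum, re-centering the window and repeating (up to five
times) whenever the arg-max lands on the window boundary.  Multi-seed
refinement plus boundary re-centering is what makes the search robust to
the shallow, quantization-rippled score landscape near the optimum; ties
break toward smaller |angles|, then smaller y.  An all-constant query has
no NCC and returns a no-match flag.

The matcher exists so the whole pipeline runs end-to-end without a trained
network: `predict_series` accepts any callable obeying the predictor
contract (image → anchor), so a learned regressor drops in without touching
the downstream stages.  The CNN protocol that a production predictor would
use — grayscale 299×299 inputs into a pretrained backbone topped by two
256-unit ReLU dense layers and nine linear outputs, MSE loss, Adam at
1e−3 dropping to 1e−4 at the final plateau, batch size 8, staged
unfreezing — is recorded as validated, serializable constants in
`PredictorProtocolConfig`; training itself is out of scope here.

## Benchmark experiments and problem sizes

`coronalign.benchmarks` defines the two standing experiments, also run by
`scripts/acceptance.py`:

* **Generate-and-recover**: 25 random anchors with |angles| ≤ 8° (inside
  the matcher's search range), rendered noiselessly or with default
  augmentation, then matched back.  Success means y within 1 voxel and
  both angles within 0.5°.  The problem size (25 sections, 64×128×64
  phantom) keeps a full run in the minutes range on one CPU while leaving
  the recovery statistics stable.
* **Post-processing benefit**: a 30-section serial series with common
  angles (dv 3°, ml −2°), 3-voxel thickness, perturbed per-section by
  Normal(0, 2°) angle noise and Normal(0, 2 voxels) rostrocaudal noise —
  an idealization of a per-image predictor's independent errors.  Median
  masked error is measured raw, after AI, and after AI+CI (16×16 pixel
  grid), and the CI benefit is averaged over 200 random subsamples per
  batch size in {5, 10, 20, 30}.  The benefit is negative for small
  batches (the thickness fit is unstable) and grows with batch size,
  reproducing the practical advice to use batches of more than 10–20
  sections.

## What the synthetic experiments do not show

The phantom encodes position far more cleanly than real histology: no
staining variability, tears, bubbles, missing cortex or hemisected tissue,
and its texture is statistically stationary.  Passing recovery tests
therefore validates the *geometry, rendering, search and post-processing
machinery* — not registration accuracy on real brains, which depends on a
trained predictor and real ground truth.  Likewise the noise model of the
benefit simulation is independent zero-mean Gaussian; systematic predictor
bias (e.g., compression of predictions toward the atlas center) would not
be corrected by AI/CI and is not modelled.  Sagittal and horizontal
primary orientations and nonlinear (per-section deformation) refinement
are out of scope throughout.
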