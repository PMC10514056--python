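# coronalign

Registration of coronal mouse-brain section images to a volumetric reference
atlas, built around the QuickNII *anchoring vector* representation of a
section plane.

## The problem and who this is for

Serial histology produces stacks of 2D section images that must be placed in
a standardized 3D coordinate system (for the mouse, the Allen Common
Coordinate Framework at 25 µm voxels) before any brain-wide quantification
can happen.  QuickNII describes where a section sits by three atlas-space
vectors: **O**, the voxel coordinate of the image's top-left corner, **U**,
spanning the image width, and **V**, spanning the image height.  Pixel
(i, j) of a w×h image projects to

    p(i, j) = O + i/(w−1)·U + j/(h−1)·V

so the nine numbers (O, U, V) fully determine the mapping, and the four
image corners land exactly on O, O+U, O+V and O+U+V.

`coronalign` implements the computational pipeline around this
representation for neuroanatomists and tool builders:

* **Geometry** — dorsoventral/mediolateral cutting angles of a plane
  (`ml = atan2(U_y, U_x)`, `dv = atan2(V_y, V_z)`), canonical reconstruction
  of an anchor from center + angles + edge lengths, and QuickNII XML/JSON
  readers and writers.
* **Post-processing** — serial sections share a cutting-plane orientation
  and a constant thickness, so per-section predictions can be improved post
  hoc: *Angle Integration* (normalize every section to the series-average
  angles), *Cutting Index* weighting (re-space sections rostrocaudally using
  the cutting order parsed from filenames, `t = mean(ΔC_y/ΔCI)`), and
  *model ensembling* (component-wise averaging of independent predictions).
* **Evaluation** — the masked registration error: mean Euclidean distance,
  in voxels, between two projections of each image pixel, restricted to
  pixels that project inside the brain mask; multi-rater
  ("wisdom of the crowd") consensus ground truth with leave-one-out
  operator scoring; anchoring-MSE curation with an automatic log-elbow
  threshold.
* **Virtual sectioning** — render 2D sections through any volume from
  anchoring vectors by trilinear interpolation, a deterministic phantom
  volume with position-encoding internal structure, a seeded random
  anchoring sampler, noise/dropout/warp augmentation, and a minimal-tissue
  filter: everything needed to build synthetic training sets.
* **Prediction** — the predictor contract (image → nine anchoring
  components), a brute-force coarse-to-fine template matcher as the
  reference implementation, and the documented CNN training protocol
  constants.

## Worked example

`examples/03_recover_section.py` renders one oblique section through the
phantom volume and recovers its placement from the image alone:

```
ground truth: y=87.48 voxels, DV +1.08 deg, ML +4.53 deg
recovered:    y=87.35 voxels, DV +1.25 deg, ML +4.50 deg (NCC score 0.9991)
errors: 0.13 voxels rostrocaudal, 0.17 / 0.03 deg in DV/ML — within the fine search step of the matcher
```

The rostrocaudal position (y, in 25 µm voxels) and both cutting angles come
back within the matcher's fine grid resolution.
`examples/04_postprocessing.py` shows the post-hoc adjustments on a noisy
30-section simulated series:

```
median masked registration error (30 sections):
  raw noisy predictions : 1.30 voxels (~32 um)
  after angle integration: 1.27 voxels
  after AI + cutting index: 0.73 voxels

CI benefit (AI-only error minus AI+CI error) by batch size:
   5 sections: -1.122 voxels  (too few sections for a stable thickness fit)
  10 sections: -0.780 voxels  (too few sections for a stable thickness fit)
  20 sections: +0.017 voxels  (CI helps)
  30 sections: +0.686 voxels  (CI helps)
```

Cutting-index weighting needs enough sections for a stable thickness
estimate; past ~10–20 sections it clearly pays off.  The remaining examples
(`examples/01…05`) cover geometry/IO, virtual sectioning, and crowd ground
truth, each printing what it computes.

## Command line

The same stages are available as a thin CLI:

```bash
coronalign phantom --seed 7 --out phantom.nii.gz
coronalign slice --volume phantom.nii.gz --random-n 20 --seed 3 \
    --out-dir imgs/ --manifest manifest.json
coronalign predict --images imgs/ --volume phantom.nii.gz --out pred.json
coronalign postprocess --in pred.json --out adj.json \
    --angle-integration --cutting-index --ci-pattern "_s(\d+)"
coronalign evaluate --test adj.json --ref gt.json --mask phantom.nii.gz \
    --grid 64 --out report.csv
coronalign crowd-gt --raters alignments/ --out gt.json \
    --mask phantom.nii.gz --loo-report loo.csv
```

Outputs are QuickNII-compatible JSON/XML, so they can be opened and refined
in QuickNII directly; every output embeds the seed and a config hash.

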