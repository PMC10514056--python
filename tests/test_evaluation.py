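"""Masked voxel-distance metric, crowd ground truth, curation, summaries."""

import numpy as np
import pytest

from coronalign import (
    ErrorReport,
    RaterSet,
    SectionAnchor,
    SeriesAlignment,
    anchoring_mse,
    crowd_ground_truth,
    ensemble,
    leave_one_out_errors,
    mse_curation_threshold,
    registration_error,
    summarize,
    voxels_to_um,
)
from coronalign.evaluation import SectionError

from conftest import make_random_series

FULL_MASK = np.ones((64, 128, 64), dtype=bool)
EMPTY_MASK = np.zeros((64, 128, 64), dtype=bool)

CORONAL = SectionAnchor(
    "a.png", ox=5, oy=60, oz=5, ux=50, uy=0, uz=0, vx=0, vy=0, vz=50,
    width=51, height=51,
)


class TestRegistrationError:
    def test_identity_is_zero(self):
        err = registration_error(CORONAL, CORONAL, FULL_MASK)
        assert err.mean_voxel_dist == 0.0
        assert err.masked_pixels == 51 * 51
        assert not err.all_outside

    def test_pure_origin_shift_345(self):
        """A (3,4,0) origin shift moves every pixel by exactly 5 voxels."""
        shifted = CORONAL.translated((3, 4, 0))
        err = registration_error(shifted, CORONAL, FULL_MASK)
        assert err.mean_voxel_dist == 5.0

    def test_empty_mask_flagged(self):
        err = registration_error(CORONAL, CORONAL, EMPTY_MASK)
        assert err.all_outside and err.masked_pixels == 0
        assert np.isnan(err.mean_voxel_dist)

    def test_dimension_mismatch_rejected(self):
        other = CORONAL.replace(width=10, height=10)
        with pytest.raises(ValueError, match="dimensions"):
            registration_error(other, CORONAL, FULL_MASK)

    def test_reference_side_masking(self, phantom):
        """Membership follows the reference projection: pushing the test
        anchor outside the volume does not change the pixel count."""
        shifted = CORONAL.translated((0, 500, 0))
        base = registration_error(CORONAL, CORONAL, phantom)
        far = registration_error(shifted, CORONAL, phantom)
        assert far.masked_pixels == base.masked_pixels
        assert far.mean_voxel_dist == pytest.approx(500.0)

    def test_downsampled_grid(self):
        shifted = CORONAL.translated((3, 4, 0))
        err = registration_error(shifted, CORONAL, FULL_MASK, grid=16)
        assert err.mean_voxel_dist == pytest.approx(5.0)
        assert err.masked_pixels == 16 * 16


def rater_set(offsets, base_seed=9):
    base = make_random_series(seed=base_seed, n=4, name="base")
    alignments = {
        f"op{k + 1}": base.with_sections([s.translated(off) for s in base])
        for k, off in enumerate(offsets)
    }
    return RaterSet(alignments=alignments)


class TestCrowdGroundTruth:
    def test_two_operator_mean(self):
        raters = rater_set([(0, 0, 0), (4, 0, 0)])
        gt = crowd_ground_truth(raters)
        base = raters.alignments["op1"]
        for g, b in zip(gt, base):
            assert g.ox == pytest.approx(b.ox + 2.0)

    def test_identical_operators_idempotent(self):
        raters = rater_set([(0, 0, 0)] * 7)
        gt = crowd_ground_truth(raters)
        for g, b in zip(gt, raters.alignments["op1"]):
            assert np.allclose(g.components, b.components, atol=1e-12)

    def test_equals_ensemble(self):
        alignments = {f"op{k}": make_random_series(seed=k, n=5) for k in range(1, 8)}
        raters = RaterSet(alignments=alignments)
        gt = crowd_ground_truth(raters)
        ens = ensemble(list(alignments.values()))
        for g, e in zip(gt, ens):
            assert np.allclose(g.components, e.components, atol=1e-12)

    def test_requires_two_operators(self):
        with pytest.raises(ValueError):
            crowd_ground_truth(rater_set([(0, 0, 0)]))

    def test_inconsistent_filename_sets_rejected(self):
        with pytest.raises(ValueError, match="op2"):
            RaterSet(alignments={
                "op1": make_random_series(seed=1, n=3),
                "op2": make_random_series(seed=1, n=4),
            })


class TestLeaveOneOut:
    def test_identical_raters_zero_error(self):
        raters = rater_set([(0, 0, 0)] * 3)
        reports = leave_one_out_errors(raters, FULL_MASK, grid=8)
        for rep in reports.values():
            assert rep.dataset_median == 0.0

    def test_single_outlier_geometry(self):
        """With one rater offset by (3,4,0) and two in agreement, the
        outlier scores 5.0 and the conformers 2.5 (reference shifted by
        half the offset)."""
        raters = rater_set([(3, 4, 0), (0, 0, 0), (0, 0, 0)])
        reports = leave_one_out_errors(raters, FULL_MASK, grid=8)
        assert reports["op1"].dataset_median == pytest.approx(5.0)
        assert reports["op2"].dataset_median == pytest.approx(2.5)
        assert reports["op3"].dataset_median == pytest.approx(2.5)

    def test_label_permutation_equivariance(self):
        raters = rater_set([(3, 4, 0), (0, 0, 0), (1, 0, 0)])
        swapped = RaterSet(alignments={
            "op1": raters.alignments["op2"],
            "op2": raters.alignments["op1"],
            "op3": raters.alignments["op3"],
        })
        a = leave_one_out_errors(raters, FULL_MASK, grid=8)
        b = leave_one_out_errors(swapped, FULL_MASK, grid=8)
        assert a["op1"].dataset_median == pytest.approx(b["op2"].dataset_median)
        assert a["op2"].dataset_median == pytest.approx(b["op1"].dataset_median)

    def test_requires_three_operators(self):
        with pytest.raises(ValueError):
            leave_one_out_errors(rater_set([(0, 0, 0)] * 2), FULL_MASK)


class TestAnchoringMse:
    def test_examples(self):
        a = CORONAL
        assert anchoring_mse(a, a) == 0.0
        b = SectionAnchor.from_components(
            "b.png", a.components + 3.0, width=a.width, height=a.height
        )
        assert anchoring_mse(a, b) == pytest.approx(9.0)
        c = a.replace(ox=a.ox + 3)
        assert anchoring_mse(a, c) == pytest.approx(1.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            anchoring_mse(CORONAL, CORONAL.replace(width=10, height=10))


def bruteforce_elbow(values, eps=1e-12):
    """Independent elbow oracle: maximize point-to-chord distance directly."""
    srt = np.sort(values)
    x = np.arange(len(srt)) / (len(srt) - 1)
    y = np.log(srt + eps)
    p0, p1 = np.array([x[0], y[0]]), np.array([x[-1], y[-1]])
    chord = p1 - p0
    best, best_d = 0, -1.0
    for k in range(len(srt)):
        p = np.array([x[k], y[k]]) - p0
        d = abs(chord[0] * p[1] - chord[1] * p[0]) / np.linalg.norm(chord)
        if d > best_d:
            best, best_d = k, d
    return srt[best]


class TestMseCuration:
    def test_outliers_excluded(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.uniform(0.8, 1.2, 100), [1000, 2000, 3000, 4000, 5000]])
        result = mse_curation_threshold(values)
        assert sorted(result.excluded) == list(range(100, 105))
        assert result.elbow_found
        assert result.threshold == pytest.approx(bruteforce_elbow(values))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = np.exp(rng.uniform(-2, 6, 50))
        result = mse_curation_threshold(values)
        assert result.threshold == pytest.approx(bruteforce_elbow(values))

    def test_constant_list_excludes_nothing(self):
        result = mse_curation_threshold([2.0] * 20)
        assert result.excluded == [] and not result.elbow_found

    def test_manual_threshold(self):
        result = mse_curation_threshold([1, 10, 100], manual_threshold=50)
        assert result.excluded == [2]

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            mse_curation_threshold([1.0] * 9)


class TestSummarize:
    def report(self, distances):
        return ErrorReport(
            per_section={f"s{k}": SectionError(d, 100) for k, d in enumerate(distances)},
            voxel_size_um=25.0,
        )

    def test_median_and_iqr(self):
        s = summarize(self.report([1, 2, 3, 4, 5]))
        assert s.median_voxels == 3
        assert s.iqr_voxels == (2, 4)

    def test_voxel_to_um_worked_conversion(self):
        """7.7 voxels at 25 um/voxel is 192.5 um, i.e. ~190 um."""
        s = summarize(self.report([7.7]))
        assert s.median_um == pytest.approx(192.5)
        assert s.median_um_rounded == 190
        assert voxels_to_um(7.7, 25.0) == pytest.approx(192.5)

    def test_single_value(self):
        s = summarize(self.report([4.2]))
        assert s.median_voxels == pytest.approx(4.2)
        assert s.iqr_voxels == (pytest.approx(4.2), pytest.approx(4.2))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize(ErrorReport(per_section={}))
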