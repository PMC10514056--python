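"""Angle integration, cutting-index weighting, and ensembling."""

import numpy as np
import pytest

from coronalign import (
    CuttingAngles,
    SeriesAlignment,
    angle_integration,
    apply_cutting_index,
    build_anchor_from_angles,
    compute_cutting_angles,
    ensemble,
    estimate_thickness,
    parse_cutting_index,
    section_center,
)
from coronalign.postprocess import (
    EmptySeriesError,
    FilenameMismatchError,
    InsufficientDataError,
    MissingCuttingIndexError,
)

from conftest import make_random_series


def series_with_angles(dv_list, ml_list=None, centers_y=None, name="s"):
    ml_list = ml_list if ml_list is not None else [0.0] * len(dv_list)
    centers_y = centers_y if centers_y is not None else list(range(len(dv_list)))
    sections = [
        build_anchor_from_angles(
            center=(50.0, float(cy), 40.0),
            angles=CuttingAngles(dv, ml),
            width_len=80.0,
            height_len=60.0,
            width=64,
            height=64,
            filename=f"sec_s{k + 1:03d}.png",
            cutting_index=k + 1,
        )
        for k, (dv, ml, cy) in enumerate(zip(dv_list, ml_list, centers_y))
    ]
    return SeriesAlignment(name=name, sections=sections)


class TestAngleIntegration:
    def test_coronal_fixed_point(self):
        series = series_with_angles([0.0, 0.0, 0.0])
        out = angle_integration(series)
        for a, b in zip(series, out):
            assert np.allclose(a.components, b.components, atol=1e-12)

    def test_symmetric_mean_cancels(self):
        out = angle_integration(series_with_angles([-2.0, 0.0, 2.0]))
        for s in out:
            assert compute_cutting_angles(s).dv_deg == pytest.approx(0.0, abs=1e-9)

    def test_mean_angle_exact_and_bruteforce(self):
        series = series_with_angles([1.0, 2.0, 6.0])
        out = angle_integration(series)
        for s in out:
            assert compute_cutting_angles(s).dv_deg == pytest.approx(3.0, abs=1e-9)
        # brute-force: the mean angle over outputs equals the mean over inputs
        mean_in = np.mean([compute_cutting_angles(s).dv_deg for s in series])
        mean_out = np.mean([compute_cutting_angles(s).dv_deg for s in out])
        assert mean_out == pytest.approx(mean_in, abs=1e-9)

    def test_preserves_center_lengths_and_metadata(self, random_series):
        out = angle_integration(random_series)
        for a, b in zip(random_series, out):
            assert np.allclose(section_center(a), section_center(b), atol=1e-9)
            assert np.linalg.norm(b.u) == pytest.approx(np.linalg.norm(a.u), abs=1e-9)
            assert np.linalg.norm(b.v) == pytest.approx(np.linalg.norm(a.v), abs=1e-9)
            assert (a.filename, a.width, a.height) == (b.filename, b.width, b.height)

    def test_idempotent(self, random_series):
        once = angle_integration(random_series)
        twice = angle_integration(once)
        for a, b in zip(once, twice):
            assert np.allclose(a.components, b.components, atol=1e-6)

    def test_single_section_keeps_own_angles(self):
        series = series_with_angles([5.0], [3.0])
        out = angle_integration(series)
        angles = compute_cutting_angles(out.sections[0])
        assert angles.dv_deg == pytest.approx(5.0, abs=1e-9)
        assert angles.ml_deg == pytest.approx(3.0, abs=1e-9)

    def test_empty_series_rejected(self):
        with pytest.raises(EmptySeriesError):
            angle_integration(SeriesAlignment(name="e", sections=[]))


class TestParseCuttingIndex:
    @pytest.mark.parametrize(
        "filename, expected",
        [
            ("ExperimentID_s001.tiff", 1),
            ("brain_42.png", None),
            ("A_s010_B_s020.tif", 20),  # last match wins
            ("exp_s007_section.png", 7),
        ],
    )
    def test_examples(self, filename, expected):
        assert parse_cutting_index(filename) == expected

    @pytest.mark.parametrize("pattern", [r"_s\d+", r"_(s)(\d+)"])
    def test_pattern_must_have_one_group(self, pattern):
        with pytest.raises(ValueError, match="capture group"):
            parse_cutting_index("a_s001.png", pattern)


class TestEstimateThickness:
    def test_exact_affine_both_methods(self):
        series = series_with_angles([0, 0, 0], centers_y=[10, 12, 14])
        for method in ("pairwise_mean", "ols"):
            est = estimate_thickness(series, method)
            assert est.thickness_voxels == pytest.approx(2.0, abs=1e-12)
            assert est.n_pairs == 2

    def test_pairwise_mean_of_slopes(self):
        series = series_with_angles([0, 0, 0], centers_y=[10.1, 11.9, 14.0])
        est = estimate_thickness(series, "pairwise_mean")
        assert est.thickness_voxels == pytest.approx(1.95, abs=1e-12)

    def test_caudal_to_rostral_negative(self):
        series = series_with_angles([0, 0, 0], centers_y=[14, 12, 10])
        assert estimate_thickness(series).thickness_voxels == pytest.approx(-2.0)

    def test_insufficient_indices(self):
        series = series_with_angles([0, 0], centers_y=[10, 12])
        series = series.with_sections([s.replace(cutting_index=5) for s in series])
        # duplicate filenames are not the issue here; indices are identical
        with pytest.raises(InsufficientDataError):
            estimate_thickness(series)


class TestApplyCuttingIndex:
    def test_worked_example(self):
        series = series_with_angles([0, 0, 0], centers_y=[10.1, 11.9, 14.0])
        est = estimate_thickness(series, "pairwise_mean")
        out = apply_cutting_index(series, est)
        got = [section_center(s)[1] for s in out]
        assert got == pytest.approx([10.05, 12.00, 13.95], abs=1e-9)

    def test_affine_input_is_fixed_point(self):
        series = series_with_angles([1, 2, 3], centers_y=[10, 13, 16])
        out = apply_cutting_index(series, estimate_thickness(series))
        for a, b in zip(series, out):
            assert np.allclose(a.components, b.components, atol=1e-9)

    def test_only_rostrocaudal_moves_and_mean_preserved(self):
        series = series_with_angles([0, 0, 0], centers_y=[10.1, 11.9, 14.0])
        out = apply_cutting_index(series, estimate_thickness(series))
        for a, b in zip(series, out):
            assert (a.ox, a.oz) == (b.ox, b.oz)
            assert np.array_equal(a.u, b.u) and np.array_equal(a.v, b.v)
        mean_in = np.mean([section_center(s)[1] for s in series])
        mean_out = np.mean([section_center(s)[1] for s in out])
        assert mean_out == pytest.approx(mean_in, abs=1e-9)
        # output centers exactly affine in cutting index
        ci = np.array([s.cutting_index for s in out])
        cy = np.array([section_center(s)[1] for s in out])
        slope = np.diff(cy) / np.diff(ci)
        assert np.allclose(slope, slope[0], atol=1e-9)

    def test_order_invariance(self):
        series = series_with_angles([0, 0, 0], centers_y=[10.1, 11.9, 14.0])
        shuffled = series.with_sections(series.sections[::-1])
        a = {s.filename: s for s in apply_cutting_index(series, estimate_thickness(series))}
        b = {s.filename: s for s in apply_cutting_index(shuffled, estimate_thickness(shuffled))}
        for fname in a:
            assert np.allclose(a[fname].components, b[fname].components, atol=1e-9)

    def test_repeated_application_fixed_point(self):
        series = series_with_angles([0, 0, 0], centers_y=[10.1, 11.9, 14.0])
        once = apply_cutting_index(series, estimate_thickness(series))
        twice = apply_cutting_index(once, estimate_thickness(once))
        for a, b in zip(once, twice):
            assert np.allclose(a.components, b.components, atol=1e-9)

    def test_missing_index_lists_filenames(self):
        series = series_with_angles([0, 0, 0], centers_y=[10, 12, 14])
        series = series.with_sections(
            [s.replace(cutting_index=None) if k == 1 else s for k, s in enumerate(series)]
        )
        with pytest.raises(MissingCuttingIndexError, match="sec_s002.png"):
            apply_cutting_index(series)


class TestEnsemble:
    def test_idempotent_on_copies(self, random_series):
        out = ensemble([random_series, random_series])
        for a, b in zip(random_series, out):
            assert np.allclose(a.components, b.components, atol=1e-12)

    def test_componentwise_mean(self):
        a = series_with_angles([0], centers_y=[10])
        b = a.with_sections([s.translated((2, 0, 0)) for s in a])
        out = ensemble([a, b])
        assert out.sections[0].ox == pytest.approx(a.sections[0].ox + 1.0)

    def test_bruteforce_oracle_three_series(self):
        series = [make_random_series(seed=s, n=8) for s in (1, 2, 3)]
        out = ensemble(series)
        matrix = np.array([[sec.components for sec in s] for s in series])
        expected = matrix.mean(axis=0)
        got = np.array([sec.components for sec in out])
        assert np.allclose(got, expected, atol=1e-12)

    def test_permutation_invariant(self):
        series = [make_random_series(seed=s, n=5) for s in (1, 2, 3)]
        a = ensemble(series)
        b = ensemble(series[::-1])
        for x, y in zip(a, b):
            assert np.allclose(x.components, y.components, atol=1e-12)

    def test_filename_mismatch_names_difference(self):
        a = make_random_series(seed=1, n=3)
        b = make_random_series(seed=1, n=4)
        with pytest.raises(FilenameMismatchError, match="img_s004.png"):
            ensemble([a, b])
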