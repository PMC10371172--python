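"""Segmentation rules, macro/micro classification, blur, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from chancluster.cluster_metrics import (
    LabeledClusters,
    MacroThreshold,
    classify_macro_micro,
    gaussian_blur_match,
    puncta_density,
    restrict_to_membrane,
    segment_2d,
    segment_3d,
    sphere_diameter_from_volume,
    summarize,
)
from chancluster.synthetic_data import FieldSpec, gen_confocal_stack, gen_localization_field

VOXEL = (100.0, 0.13)  # xy nm, z um


class TestSegment3D:
    def test_blank_stack(self):
        assert len(segment_3d(np.zeros((10, 20, 20)), VOXEL, 0.5)) == 0

    def test_missing_calibration_rejected(self):
        with pytest.raises(ValueError, match="calibration"):
            segment_3d(np.zeros((5, 5, 5)), (None, None), 0.5)

    def test_two_voxel_rule_drops_single_voxels(self):
        stack = np.zeros((10, 20, 20))
        stack[5, 10, 10] = 1.0  # isolated single voxel
        stack[2, 3, 3] = stack[2, 3, 4] = stack[3, 3, 3] = 1.0
        clusters = segment_3d(stack, VOXEL, 0.5, min_diameter=(0.0, 0.0))
        assert len(clusters) == 1

    def test_min_diameter_filters_thin_puncta(self):
        stack = np.zeros((10, 20, 20))
        stack[5, 8:10, 8:10] = 1.0  # one z-slice: 130 nm z-extent < 150 nm
        assert len(segment_3d(stack, VOXEL, 0.5, min_diameter=(100.0, 150.0))) == 0
        assert len(segment_3d(stack, VOXEL, 0.5, min_diameter=(0.0, 0.0))) == 1

    def test_single_sphere_volume_recovered(self):
        spec = FieldSpec(width_nm=5000, height_nm=5000, depth_um=3.0,
                         pixel_nm=100, psf_sigma_nm=50.0, noise_sd=0.01, seed=1)
        stack, _, truth = gen_confocal_stack(spec, 1, 0.09,
                                             volumes_um3=np.array([0.09]))
        clusters = segment_3d(stack, VOXEL, 0.5, min_diameter=(0.0, 0.0))
        assert len(clusters) == 1
        assert abs(clusters.sizes[0] - 0.09) / 0.09 < 0.15

    def test_threshold_monotone_total_size(self):
        rng = np.random.default_rng(0)
        stack = rng.random((12, 30, 30))
        lo = segment_3d(stack, VOXEL, 0.4, min_diameter=(0.0, 0.0), min_voxels=1)
        hi = segment_3d(stack, VOXEL, 0.7, min_diameter=(0.0, 0.0), min_voxels=1)
        assert hi.sizes.sum() <= lo.sizes.sum()


class TestSegment2D:
    def test_blank_image(self):
        assert len(segment_2d(np.zeros((50, 50)), 20.0, 0.5)) == 0

    def test_single_disk_area_recovered(self):
        spec = FieldSpec(width_nm=3000, height_nm=3000, pixel_nm=20,
                         noise_sd=0.02, seed=2)
        image, _ = gen_localization_field(spec, 1, 2500.0,
                                          areas_nm2=np.array([2500.0]))
        clusters = segment_2d(image, 20.0, 0.5)
        assert len(clusters) == 1
        assert abs(clusters.sizes[0] - 2500.0) / 2500.0 < 0.15

    def test_bad_pixel_calibration(self):
        with pytest.raises(ValueError):
            segment_2d(np.zeros((5, 5)), 0.0, 0.5)

    def test_eight_connectivity_joins_diagonals(self):
        image = np.zeros((10, 10))
        image[4, 4] = image[5, 5] = 1.0
        assert len(segment_2d(image, 20.0, 0.5)) == 1


class TestMembraneRestriction:
    def _stack_with_split(self):
        # ten 2x2x1-voxel clusters: six with y in the top half (in-mask),
        # four in the bottom half; mask covers the top half only
        shape = (30, 200, 200)
        stack = np.zeros(shape)
        half = shape[1] // 2
        tops = [(5, 20, 30), (10, 50, 60), (15, 80, 90),
                (20, 10, 120), (25, 40, 150), (10, 70, 180)]
        bottoms = [(15, half + 30, 100), (20, half + 70, 140),
                   (5, half + 10, 20), (25, half + 60, 60)]
        for z, y, x in tops + bottoms:
            stack[z, y:y + 2, x:x + 2] = 1.0
        mask = np.zeros(shape, dtype=bool)
        mask[:, :half, :] = True
        return stack, mask, len(tops)

    def test_identity_and_empty_masks(self):
        stack, mask, _ = self._stack_with_split()
        clusters = segment_3d(stack, VOXEL, 0.5, min_diameter=(0.0, 0.0))
        assert len(restrict_to_membrane(clusters, np.ones_like(mask))) == len(clusters)
        assert len(restrict_to_membrane(clusters, np.zeros_like(mask))) == 0

    def test_constructed_split_retained_exactly(self):
        stack, mask, n_in = self._stack_with_split()
        clusters = segment_3d(stack, VOXEL, 0.5, min_diameter=(0.0, 0.0))
        assert len(clusters) == 10
        kept = restrict_to_membrane(clusters, mask, rule="any-overlap")
        assert len(kept) == n_in
        assert kept.membrane_overlap.all()
        half_nm = mask.shape[1] // 2 * 100.0
        assert np.all(kept.centroids_nm[:, 1] < half_nm)

    def test_shape_mismatch_rejected(self):
        stack, mask, _ = self._stack_with_split()
        clusters = segment_3d(stack, VOXEL, 0.5, min_diameter=(0.0, 0.0))
        with pytest.raises(ValueError, match="shape"):
            restrict_to_membrane(clusters, mask[:, :-1, :])


class TestSphereDiameter:
    def test_macro_cluster_mean_volume_maps_to_560nm(self):
        assert sphere_diameter_from_volume(0.09) == 560.0

    def test_unit_sphere_identity(self):
        assert sphere_diameter_from_volume(np.pi / 6.0, round_to_10nm=False) == pytest.approx(1000.0)

    def test_macro_threshold_geometry(self):
        # 0.03 um^3 corresponds to ~385 nm by sphere geometry
        d = sphere_diameter_from_volume(0.03, round_to_10nm=False)
        assert d == pytest.approx(385.5, abs=1.0)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            sphere_diameter_from_volume(0.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(min_value=1e-4, max_value=10.0))
    def test_doubling_diameter_is_eightfold_volume(self, v):
        d1 = sphere_diameter_from_volume(v, round_to_10nm=False)
        d2 = sphere_diameter_from_volume(8.0 * v, round_to_10nm=False)
        assert d2 == pytest.approx(2.0 * d1, rel=1e-9)


class TestClassifyMacroMicro:
    def test_half_and_half(self):
        macro, micro = classify_macro_micro(np.array([0.01, 0.05]), MacroThreshold(0.03))
        assert (macro, micro) == (50.0, 50.0)

    def test_boundary_counts_as_micro(self):
        macro, micro = classify_macro_micro(np.full(10, 0.03), MacroThreshold(0.03))
        assert macro == 0.0 and micro == 100.0

    @settings(derandomize=True, max_examples=20)
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_invariant_under_unit_rescaling(self, factor):
        sizes = np.array([0.005, 0.02, 0.04, 0.1, 0.3])
        a = classify_macro_micro(sizes, MacroThreshold(0.03))
        b = classify_macro_micro(sizes * factor, MacroThreshold(0.03 * factor))
        assert a == b

    def test_exponential_tail_matches_closed_form(self):
        rng = np.random.default_rng(5)
        sizes = rng.exponential(0.14, size=20000)
        macro, _ = classify_macro_micro(sizes, MacroThreshold(0.03))
        assert abs(macro - np.exp(-0.03 / 0.14) * 100.0) < 3.0

    def test_unit_mismatch_rejected(self):
        clusters = LabeledClusters(ids=np.array([1]), centroids_nm=np.array([[0.0, 0.0]]),
                                   sizes=np.array([2500.0]), units="nm2")
        with pytest.raises(ValueError, match="um3"):
            classify_macro_micro(clusters, MacroThreshold())


class TestGaussianBlurMatch:
    def test_delta_mass_conserved(self):
        image = np.zeros((101, 101))
        image[50, 50] = 7.3
        blurred = gaussian_blur_match(image, 20.0, 200.0)
        assert abs(blurred.sum() - 7.3) / 7.3 < 1e-6
        assert blurred.max() < 7.3

    def test_uniform_image_unchanged(self):
        image = np.full((60, 60), 2.5)
        np.testing.assert_allclose(gaussian_blur_match(image, 20.0, 200.0), image,
                                   rtol=1e-9)

    def test_resolution_limit_merges_close_points(self):
        # two localizations 160 nm apart merge at confocal resolution;
        # 400 nm apart stay resolvable
        close, far = np.zeros((200, 200)), np.zeros((200, 200))
        close[100, 96], close[100, 104] = 1.0, 1.0  # 8 px * 20 nm = 160 nm
        far[100, 90], far[100, 110] = 1.0, 1.0  # 400 nm
        bc = gaussian_blur_match(close, 20.0, 200.0)
        bf = gaussian_blur_match(far, 20.0, 200.0)
        assert ndimage.label(bc > 0.5 * bc.max())[1] == 1
        assert ndimage.label(bf > 0.5 * bf.max())[1] == 2

    def test_subpixel_kernel_rejected(self):
        with pytest.raises(ValueError, match="smaller than one pixel"):
            gaussian_blur_match(np.zeros((10, 10)), 300.0, 200.0)


class TestSummaries:
    def _clusters(self, sizes, units="um3"):
        n = len(sizes)
        return LabeledClusters(ids=np.arange(1, n + 1),
                               centroids_nm=np.zeros((n, 3)),
                               sizes=np.asarray(sizes), units=units)

    def test_percent_membrane_occupied_arithmetic(self):
        s = summarize(self._clusters([0.05]), cell_reference=10.0,
                      membrane_area_um2=10.0, membrane_footprint_um2=0.5)
        assert s.pct_membrane_occupied == pytest.approx(5.0)

    def test_duplication_doubles_count_not_mean(self):
        sizes = [0.01, 0.04, 0.09]
        a = summarize(self._clusters(sizes), cell_reference=100.0)
        b = summarize(self._clusters(sizes * 2), cell_reference=100.0)
        assert b.clusters_per_cell == 2 * a.clusters_per_cell
        assert b.mean_size == pytest.approx(a.mean_size)
        assert b.total_size_per_cell == pytest.approx(2 * a.total_size_per_cell)

    def test_empty_set_gives_zero_summary(self):
        empty = LabeledClusters(ids=np.empty(0, dtype=int),
                                centroids_nm=np.empty((0, 3)),
                                sizes=np.empty(0), units="um3")
        s = summarize(empty, cell_reference=10.0)
        assert s.clusters_per_cell == 0 and s.mean_size == 0.0

    def test_macro_fraction_included_when_threshold_given(self):
        s = summarize(self._clusters([0.01, 0.05]), cell_reference=10.0,
                      thr=MacroThreshold(0.03))
        assert s.macro_fraction == pytest.approx(50.0)


class TestPunctaDensity:
    def test_zero_puncta(self):
        assert puncta_density(0, 100.0) == 0.0

    def test_pla_scale_arithmetic(self):
        assert puncta_density(35, 1000.0) == pytest.approx(0.035)

    def test_poisson_field_density_within_3se(self):
        rng = np.random.default_rng(8)
        intensity, area = 0.05, 2000.0
        n = rng.poisson(intensity * area)
        se = np.sqrt(intensity / area)
        assert abs(puncta_density(n, area) - intensity) < 3 * se

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            puncta_density(5, 0.0)
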