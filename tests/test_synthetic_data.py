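"""Generators: determinism, ground-truth statistics, render consistency."""

import numpy as np
import pytest
import tifffile
from scipy import stats

from chancluster.sparklet import CoupledGatingParams
from chancluster.synthetic_data import (
    FieldSpec,
    PlacementError,
    gen_cluster_sizes,
    gen_confocal_stack,
    gen_localization_field,
    gen_sparklet_traces,
    write_field,
    write_stack,
)


def small_field(seed=0, **kw):
    defaults = dict(width_nm=8000.0, height_nm=8000.0, pixel_nm=20.0, seed=seed)
    defaults.update(kw)
    return FieldSpec(**defaults)


class TestFieldSpec:
    @pytest.mark.parametrize(
        "kw",
        [
            {"width_nm": 0.0},
            {"height_nm": -1.0},
            {"pixel_nm": 0.0},
            {"noise_sd": -0.1},
            {"psf_sigma_nm": -5.0},
        ],
    )
    def test_invalid_geometry_rejected(self, kw):
        with pytest.raises(ValueError):
            small_field(**kw)

    def test_shapes_follow_pitch(self):
        spec = FieldSpec(width_nm=2000, height_nm=1000, pixel_nm=20, depth_um=1.3)
        assert spec.shape_2d == (50, 100)
        assert spec.shape_3d == (10, 50, 100)


class TestLocalizationField:
    def test_empty_field(self):
        image, truth = gen_localization_field(small_field(), 0, 2500.0)
        assert image.shape == (400, 400)
        assert not image.any()
        assert len(truth) == 0

    def test_seeded_determinism(self):
        a, ta = gen_localization_field(small_field(seed=42), 40, 2500.0)
        b, tb = gen_localization_field(small_field(seed=42), 40, 2500.0)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(ta.sizes, tb.sizes)

    def test_truth_area_mean_matches_request(self):
        spec = FieldSpec(width_nm=50000, height_nm=50000, pixel_nm=20, seed=7)
        _, truth = gen_localization_field(spec, 5000, 2500.0)
        assert len(truth) == 5000
        assert abs(truth.sizes.mean() - 2500.0) / 2500.0 < 0.05

    def test_rendered_mass_monotone_in_drawn_size(self):
        # two isolated clusters of very different areas: bigger one carries
        # more rendered intensity
        spec = small_field(seed=3)
        image, truth = gen_localization_field(
            spec, 2, 2500.0, areas_nm2=np.array([800.0, 8000.0])
        )
        px = spec.pixel_nm
        masses = []
        for (x, y), a in zip(truth.centroids_nm, truth.sizes):
            r = int(np.ceil(np.sqrt(a / np.pi) / px)) + 3
            cy, cx = int(y / px), int(x / px)
            masses.append(image[max(cy - r, 0):cy + r, max(cx - r, 0):cx + r].sum())
        order = np.argsort(truth.sizes)
        assert masses[order[0]] < masses[order[1]]

    def test_placement_failure_reports_density(self):
        spec = FieldSpec(width_nm=400, height_nm=400, pixel_nm=20, seed=0)
        with pytest.raises(PlacementError, match="density"):
            gen_localization_field(spec, 200, 20000.0)


class TestConfocalStack:
    def test_whole_volume_placement_unconstrained(self):
        spec = FieldSpec(width_nm=8000, height_nm=8000, depth_um=3.0,
                         pixel_nm=100, seed=1)
        stack, mask, truth = gen_confocal_stack(spec, 30, 0.05, shell="whole")
        assert mask.all()
        assert len(truth) == 30

    def test_truth_volume_mean_matches_request(self):
        spec = FieldSpec(width_nm=15000, height_nm=15000, depth_um=6.0,
                         pixel_nm=100, seed=5)
        _, _, truth = gen_confocal_stack(spec, 200, 0.09)
        assert abs(truth.sizes.mean() - 0.09) / 0.09 < 0.10

    def test_shell_constrains_centroids_and_intensity(self):
        spec = FieldSpec(width_nm=12000, height_nm=12000, depth_um=5.0,
                         pixel_nm=100, psf_sigma_nm=0.0, noise_sd=0.0, seed=9)
        stack, mask, truth = gen_confocal_stack(spec, 50, 0.05, shell=1.0)
        # centroid voxels inside the mask
        for x, y, z in truth.centroids_nm:
            vz = min(int(z / 1000.0 / spec.voxel_z_um), mask.shape[0] - 1)
            vy = min(int(y / spec.pixel_nm), mask.shape[1] - 1)
            vx = min(int(x / spec.pixel_nm), mask.shape[2] - 1)
            assert mask[vz, vy, vx]
        # >= 99% of the rendered intensity lies inside the mask
        assert stack[mask].sum() >= 0.99 * stack.sum()

    def test_thin_shell_rejected(self):
        spec = FieldSpec(width_nm=8000, height_nm=8000, depth_um=3.0,
                         pixel_nm=100, seed=1)
        with pytest.raises(ValueError, match="thinner"):
            gen_confocal_stack(spec, 5, 0.05, shell=0.01)

    def test_seeded_determinism(self):
        spec = FieldSpec(width_nm=8000, height_nm=8000, depth_um=3.0,
                         pixel_nm=100, noise_sd=0.02, seed=11)
        a = gen_confocal_stack(spec, 20, 0.05)
        b = gen_confocal_stack(spec, 20, 0.05)
        np.testing.assert_array_equal(a[0], b[0])


class TestSparkletTraces:
    def test_noiseless_trace_reproduces_k(self):
        params = CoupledGatingParams(N=3, p_open=0.2, kappa=0.4, n_frames=2000, seed=2)
        trace, k = gen_sparklet_traces(params, quantal_dF=1.5, noise_sd=0.0)
        np.testing.assert_allclose(trace["dF"].to_numpy() / 1.5, k)

    def test_fully_coupled_two_level(self):
        params = CoupledGatingParams(N=3, p_open=0.3, kappa=1.0, n_frames=3000, seed=4)
        trace, k = gen_sparklet_traces(params, quantal_dF=1.0, noise_sd=0.01)
        assert set(np.unique(k)) <= {0, 3}
        assert np.all((np.abs(trace["dF"]) < 0.1) | (np.abs(trace["dF"] - 3.0) < 0.1))

    def test_independent_mean_matches_binomial(self):
        params = CoupledGatingParams(N=3, p_open=0.1, kappa=0.0, n_frames=20000, seed=6)
        trace, k = gen_sparklet_traces(params, quantal_dF=1.0, noise_sd=0.0)
        se = np.sqrt(3 * 0.1 * 0.9 / 20000)
        assert abs(k.mean() - 0.3) < 3 * se

    def test_bad_rate_rejected(self):
        params = CoupledGatingParams(N=2, p_open=0.1, kappa=0.0, n_frames=10, seed=0)
        with pytest.raises(ValueError):
            gen_sparklet_traces(params, quantal_dF=1.0, noise_sd=0.1, fs_hz=0.0)


class TestClusterSizes:
    def test_single_draw_positive(self):
        s = gen_cluster_sizes(1, 0.08, seed=123)
        assert s.shape == (1,) and s[0] > 0

    def test_mean_recovery(self):
        s = gen_cluster_sizes(5000, 0.08, seed=1)
        assert abs(s.mean() - 0.08) / 0.08 < 0.05

    def test_determinism(self):
        np.testing.assert_array_equal(
            gen_cluster_sizes(100, 2.0, seed=9), gen_cluster_sizes(100, 2.0, seed=9)
        )

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_scale_rejected(self, bad):
        with pytest.raises(ValueError):
            gen_cluster_sizes(10, bad)

    def test_ks_agreement_across_seeds(self):
        # one-sample KS against the generating exponential at alpha = 0.01
        # should pass for >= 95% of seeds
        passes = 0
        for seed in range(100):
            s = gen_cluster_sizes(500, 0.08, seed=seed)
            p = stats.kstest(s, "expon", args=(0, 0.08)).pvalue
            passes += p > 0.01
        assert passes >= 95


class TestIO:
    def test_field_tiff_roundtrip(self, tmp_path):
        spec = small_field(seed=21)
        image, truth = gen_localization_field(spec, 15, 2500.0)
        paths = write_field(tmp_path, "f", image, truth, spec)
        back = tifffile.imread(paths["tiff"])
        np.testing.assert_allclose(back, image.astype(np.float32))
        assert paths["truth"].exists() and paths["spec"].exists()

    def test_stack_tiff_roundtrip(self, tmp_path):
        spec = FieldSpec(width_nm=4000, height_nm=4000, depth_um=1.3,
                         pixel_nm=100, seed=2)
        stack, mask, truth = gen_confocal_stack(spec, 5, 0.03)
        paths = write_stack(tmp_path, "s", stack, mask, truth, spec)
        assert tifffile.imread(paths["tiff"]).shape == stack.shape
        assert tifffile.imread(paths["mask"]).dtype == np.uint8
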