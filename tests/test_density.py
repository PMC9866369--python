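"""Gaussian kernels, density-map construction, and counting by integration."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import graincount as gc


def naive_density(points, frame_shape, sigma, radius, normalization):
    """Independent brute-force evaluation: explicit loops over pixels and
    dots, with the same snap-to-pixel and border-truncation semantics."""
    h, w = frame_shape
    # discrete normalizer of the truncated kernel, by explicit summation
    norm = 0.0
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            norm += math.exp(-(di * di + dj * dj) / (2.0 * sigma * sigma))
    out = np.zeros((h, w))
    for row, col in points:
        i0, j0 = math.floor(row + 0.5), math.floor(col + 0.5)
        for i in range(max(0, i0 - radius), min(h, i0 + radius + 1)):
            for j in range(max(0, j0 - radius), min(w, j0 + radius + 1)):
                g = math.exp(-((i - i0) ** 2 + (j - j0) ** 2) / (2.0 * sigma * sigma))
                out[i, j] += g / norm if normalization == "unit_integral" else g
    return out


class TestGaussianKernel:
    @pytest.mark.parametrize("sigma", [1.0, 2.0, 4.0])
    def test_unit_peak_center_is_exactly_one(self, sigma):
        g = gc.gaussian_kernel(gc.KernelSpec(sigma, 4 * int(sigma), "unit_peak"))
        r = g.shape[0] // 2
        assert g[r, r] == 1.0
        assert g.max() == 1.0

    @pytest.mark.parametrize("sigma", [1.0, 2.0, 4.0])
    def test_unit_integral_sums_to_one(self, sigma):
        g = gc.gaussian_kernel(gc.KernelSpec(sigma, 4 * int(sigma), "unit_integral"))
        assert abs(g.sum() - 1.0) < 1e-9

    def test_one_pixel_offset_ratio_matches_closed_form(self):
        g = gc.gaussian_kernel(gc.KernelSpec(1.0, 4, "unit_integral"))
        assert g[4, 5] / g[4, 4] == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_symmetry_under_flips_and_transpose(self):
        g = gc.gaussian_kernel(gc.KernelSpec(2.0, 6, "unit_integral"))
        assert np.array_equal(g, g[::-1])
        assert np.array_equal(g, g[:, ::-1])
        assert np.array_equal(g, g.T)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            gc.KernelSpec(sigma=0.0)
        with pytest.raises(ValueError, match="truncation_radius"):
            gc.KernelSpec(sigma=1.0, truncation_radius=0)


class TestBuildDensityMap:
    def test_empty_annotation_gives_zero_map(self):
        ann = gc.DotAnnotation(points=np.empty((0, 2)), frame_shape=(32, 32))
        dmap = gc.build_density_map(ann, gc.KernelSpec())
        assert dmap.values.sum() == 0.0
        assert dmap.source_count == 0

    def test_single_interior_dot_has_unit_mass(self):
        ann = gc.DotAnnotation(points=[(16.0, 16.0)], frame_shape=(33, 33))
        dmap = gc.build_density_map(ann, gc.KernelSpec(2.0, 8, "unit_integral"))
        assert dmap.values.sum() == pytest.approx(1.0, abs=1e-6)

    def test_two_close_dots_superpose_above_unit_peak(self):
        spec = gc.KernelSpec(2.0, 8, "unit_peak")
        ann = gc.DotAnnotation(points=[(16.0, 16.0), (16.0, 17.0)], frame_shape=(33, 33))
        dmap = gc.build_density_map(ann, spec)
        # explicit two-kernel summation at the higher of the two peaks
        expected_peak = 1.0 + math.exp(-1.0 / (2.0 * 4.0))
        assert dmap.values.max() == pytest.approx(expected_peak, rel=1e-12)
        assert dmap.values.max() > 1.0

    def test_dot_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            gc.DotAnnotation(points=[(40.0, 10.0)], frame_shape=(32, 32))

    def test_matches_naive_double_loop(self, rng):
        spec = gc.KernelSpec(2.0, 8, "unit_integral")
        for _ in range(5):
            n = int(rng.integers(0, 11))
            pts = rng.uniform(0, 48, size=(n, 2))
            ann = gc.DotAnnotation(points=pts, frame_shape=(48, 48))
            got = gc.build_density_map(ann, spec).values
            want = naive_density(pts, (48, 48), 2.0, 8, "unit_integral")
            assert np.abs(got - want).max() < 1e-8


class TestCounting:
    def test_zero_map_counts_zero(self):
        dmap = gc.DensityMap(np.zeros((16, 16)), gc.KernelSpec())
        assert gc.count_from_density(dmap) == 0.0

    @pytest.mark.parametrize("normalization", ["unit_integral", "unit_peak"])
    def test_seven_interior_dots_count_seven(self, rng, normalization):
        spec = gc.KernelSpec(2.0, 8, normalization)
        pts = rng.uniform(10, 86, size=(7, 2))
        ann = gc.DotAnnotation(points=pts, frame_shape=(96, 96))
        dmap = gc.build_density_map(ann, spec)
        assert gc.count_from_density(dmap) == pytest.approx(7.0, abs=1e-6)

    def test_full_frame_region_equals_total_count(self, rng):
        spec = gc.KernelSpec(2.0, 8, "unit_peak")
        pts = rng.uniform(0, 64, size=(5, 2))
        dmap = gc.build_density_map(gc.DotAnnotation(pts, (64, 64)), spec)
        full = gc.count_in_region(dmap, (0, 64, 0, 64))
        assert full == pytest.approx(gc.count_from_density(dmap), abs=1e-12)

    def test_window_far_from_dots_counts_zero(self):
        spec = gc.KernelSpec(2.0, 8)
        dmap = gc.build_density_map(gc.DotAnnotation([(10.0, 10.0)], (64, 64)), spec)
        assert gc.count_in_region(dmap, (40, 64, 40, 64)) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_two_dot_scene_splits_between_halves(self):
        spec = gc.KernelSpec(2.0, 8)
        ann = gc.DotAnnotation([(32.0, 16.0), (32.0, 47.0)], (64, 64))
        dmap = gc.build_density_map(ann, spec)
        left = gc.count_in_region(dmap, (0, 64, 0, 32))
        right = gc.count_in_region(dmap, (0, 64, 32, 64))
        assert left == pytest.approx(1.0, abs=1e-3)
        assert right == pytest.approx(1.0, abs=1e-3)

    def test_disjoint_tiling_sums_to_total(self, rng):
        spec = gc.KernelSpec(2.0, 8, "unit_peak")
        pts = rng.uniform(0, 64, size=(8, 2))
        dmap = gc.build_density_map(gc.DotAnnotation(pts, (64, 64)), spec)
        total = sum(
            gc.count_in_region(dmap, (r, r + 16, c, c + 16))
            for r in range(0, 64, 16)
            for c in range(0, 64, 16)
        )
        assert total == pytest.approx(gc.count_from_density(dmap), abs=1e-9)

    def test_out_of_bounds_region_rejected(self):
        dmap = gc.DensityMap(np.zeros((32, 32)), gc.KernelSpec())
        with pytest.raises(ValueError, match="out of bounds"):
            gc.count_in_region(dmap, (0, 40, 0, 32))


class TestInvariants:
    @given(st.integers(0, 2 ** 31 - 1))
    def test_flip_equivariance_is_exact(self, seed):
        r = np.random.default_rng(seed)
        spec = gc.KernelSpec(2.0, 6)
        # stay within [0, 47] so the mirrored coordinate 47 - col is in frame
        pts = r.uniform(0, 47, size=(int(r.integers(1, 8)), 2))
        ann = gc.DotAnnotation(pts, (48, 48))
        flipped_pts = pts.copy()
        flipped_pts[:, 1] = 47 - flipped_pts[:, 1]
        flipped = gc.DotAnnotation(flipped_pts, (48, 48))
        got = gc.build_density_map(flipped, spec).values
        want = gc.build_density_map(ann, spec).values[:, ::-1]
        assert np.array_equal(got, want)

    def test_moving_dot_toward_border_never_increases_count(self):
        spec = gc.KernelSpec(2.0, 8)
        counts = []
        for col in np.linspace(32.0, 0.0, 17):
            dmap = gc.build_density_map(gc.DotAnnotation([(32.0, col)], (64, 64)), spec)
            counts.append(gc.count_from_density(dmap))
        assert all(b <= a + 1e-12 for a, b in zip(counts, counts[1:]))

    def test_density_values_nonnegative_enforced(self):
        with pytest.raises(ValueError, match="non-negative"):
            gc.DensityMap(np.full((4, 4), -1.0), gc.KernelSpec())


def test_density_npy_round_trip(tmp_path, rng):
    spec = gc.KernelSpec()
    pts = rng.uniform(0, 32, size=(4, 2))
    dmap = gc.build_density_map(gc.DotAnnotation(pts, (32, 32)), spec)
    path = tmp_path / "map.npy"
    gc.save_density_npy(dmap, path)
    loaded = gc.load_density_npy(path, spec)
    assert np.allclose(loaded.values, dmap.values, atol=1e-6)


def test_heatmap_png_export(tmp_path, rng):
    from graincount.synthetic import load_image_png

    spec = gc.KernelSpec()
    pts = rng.uniform(0, 32, size=(4, 2))
    dmap = gc.build_density_map(gc.DotAnnotation(pts, (32, 32)), spec)
    path = tmp_path / "map.png"
    gc.save_density_heatmap_png(dmap, path)
    assert load_image_png(path).shape == (32, 32, 3)
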