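import math

import numpy as np
import pytest

import isorecon as ir
from isorecon import (Volume, add_rician_noise, augment_flip, crop_to_factor,
                      downsample_axis, extract_training_cubes, fuse_scans,
                      simulate_orthogonal_scans, upsample_axis)
from isorecon.degrade import OrthogonalScanSet, TrainingPair


def box_average_oracle(arr: np.ndarray, axis: int, r: float) -> np.ndarray:
    """Direct per-slice weighted average with explicit overlap weights,
    independent of the implementation's weight-matrix path."""
    arr = np.moveaxis(arr, axis, 0).astype(np.float64)
    n_in = arr.shape[0]
    n_out = int(round(n_in / r))
    out = np.zeros((n_out,) + arr.shape[1:])
    for j in range(n_out):
        center = (j + 0.5) * r - 0.5
        lo, hi = center - r / 2, center + r / 2
        wsum = 0.0
        for i in range(n_in):
            overlap = min(hi, i + 0.5) - max(lo, i - 0.5)
            if overlap > 0:
                out[j] += overlap * arr[i]
                wsum += overlap
        out[j] /= wsum
    return np.moveaxis(out, 0, axis)


class TestDownsample:
    def test_constant_volume_stays_constant(self):
        v = Volume(np.full((24, 10, 10), 0.4, dtype=np.float32))
        out = downsample_axis(v, 0, 2.0)
        assert out.data.shape == (12, 10, 10)
        np.testing.assert_allclose(out.data, 0.4, atol=1e-6)

    @pytest.mark.parametrize("r,expected", [(2.0, 12), (3.0, 8), (2.5, 10)])
    def test_output_length(self, r, expected):
        v = Volume(np.zeros((24, 6, 6), dtype=np.float32))
        assert downsample_axis(v, 0, r).data.shape[0] == expected

    @pytest.mark.parametrize("axis", [0, 1, 2])
    @pytest.mark.parametrize("r", [2.0, 3.0, 2.5])
    def test_impulse_matches_direct_oracle(self, rng, axis, r):
        arr = np.zeros((10, 10, 10), dtype=np.float32)
        arr[5, 5, 5] = 1.0
        out = downsample_axis(Volume(arr), axis, r)
        np.testing.assert_allclose(out.data,
                                   box_average_oracle(arr, axis, r),
                                   atol=1e-6)

    def test_random_volume_matches_direct_oracle(self, rng):
        arr = rng.random((12, 9, 8), dtype=np.float32)
        out = downsample_axis(Volume(arr), 1, 3.0)
        np.testing.assert_allclose(out.data, box_average_oracle(arr, 1, 3.0),
                                   atol=1e-6)

    def test_spacing_scales(self):
        v = Volume(np.zeros((20, 20, 20), dtype=np.float32), (0.7, 0.7, 0.7))
        out = downsample_axis(v, 2, 5.0)
        assert out.spacing == pytest.approx((0.7, 0.7, 3.5))

    def test_argument_errors(self):
        v = Volume(np.zeros((8, 8, 8), dtype=np.float32))
        with pytest.raises(ValueError):
            downsample_axis(v, 0, 1.0)
        with pytest.raises(ValueError):
            downsample_axis(v, 0, 9.0)

    def test_mean_preserved_on_smooth_phantom(self, small_phantom):
        out = downsample_axis(small_phantom, 0, 3.0)
        assert out.data.mean() == pytest.approx(small_phantom.data.mean(),
                                                rel=0.01)


class TestUpsample:
    def test_same_length_is_identity(self, rng):
        v = Volume(rng.random((8, 8, 8), dtype=np.float32))
        out = upsample_axis(v, 1, 8)
        np.testing.assert_array_equal(out.data, v.data)

    def test_constant_preserved(self):
        v = Volume(np.full((6, 6, 6), 0.3, dtype=np.float32))
        out = upsample_axis(v, 0, 18)
        np.testing.assert_allclose(out.data, 0.3, atol=1e-6)

    def test_linear_ramp_preserved(self):
        ramp = np.tile(np.linspace(0, 1, 8, dtype=np.float32)[:, None, None],
                       (1, 4, 4))
        out = upsample_axis(Volume(ramp), 0, 16)
        # interior: cubic splines reproduce linear functions
        x_out = np.arange(16)
        rho = 16 / 8
        expected = ((x_out + 0.5) / rho - 0.5) / 7.0
        interior = slice(2, 14)
        np.testing.assert_allclose(out.data[interior, 0, 0],
                                   expected[interior], atol=1e-5)

    def test_shrink_request_raises(self):
        v = Volume(np.zeros((8, 8, 8), dtype=np.float32))
        with pytest.raises(ValueError):
            upsample_axis(v, 0, 4)

    def test_down_then_up_constant_round_trip(self):
        v = Volume(np.full((24, 8, 8), 0.6, dtype=np.float32))
        down = downsample_axis(v, 0, 3.0)
        up = upsample_axis(down, 0, 24)
        np.testing.assert_allclose(up.data, v.data, atol=1e-5)


class TestOrthogonalSimulation:
    def test_three_scan_shapes_at_factor_five(self):
        y = Volume(np.zeros((40, 40, 40), dtype=np.float32))
        s = simulate_orthogonal_scans(y, 5.0)
        shapes = {scan.axis: scan.volume.data.shape for scan in s.scans}
        assert shapes[0] == (8, 40, 40)
        assert shapes[1] == (40, 8, 40)
        assert shapes[2] == (40, 40, 8)

    def test_single_axis_subset(self, small_phantom):
        s = simulate_orthogonal_scans(small_phantom, 2.0, axes=(0,))
        assert len(s.scans) == 1 and s.scans[0].axis == 0

    def test_invalid_requests(self, small_phantom):
        with pytest.raises(ValueError):
            simulate_orthogonal_scans(small_phantom, 1.0)
        with pytest.raises(ValueError):
            simulate_orthogonal_scans(small_phantom, 2.0, axes=(0, 0))

    def test_crop_to_factor(self):
        y = Volume(np.zeros((25, 25, 25), dtype=np.float32))
        assert crop_to_factor(y, 2.0).data.shape == (24, 24, 24)
        assert crop_to_factor(y, 2.5).data.shape == (25, 25, 25)


class TestFusion:
    def test_single_scan_equals_upsampled_scan_exactly(self, small_phantom):
        s = simulate_orthogonal_scans(small_phantom, 2.0, axes=(1,))
        fused = fuse_scans(s)
        up = upsample_axis(s.scans[0].volume, 1, s.parent_shape[1])
        np.testing.assert_array_equal(fused.data, up.data)

    def test_constant_scans_fuse_to_constant(self):
        y = Volume(np.full((12, 12, 12), 0.7, dtype=np.float32))
        fused = fuse_scans(simulate_orthogonal_scans(y, 2.0))
        np.testing.assert_allclose(fused.data, 0.7, atol=1e-5)

    def test_three_scans_match_elementwise_mean_oracle(self, small_phantom):
        s = simulate_orthogonal_scans(small_phantom, 2.0)
        ups = [upsample_axis(sc.volume, sc.axis, s.parent_shape[sc.axis]).data
               for sc in s.scans]
        oracle = np.zeros_like(ups[0])
        for idx in np.ndindex(oracle.shape):
            oracle[idx] = (ups[0][idx] + ups[1][idx] + ups[2][idx]) / 3.0
        np.testing.assert_allclose(fuse_scans(s).data, oracle, atol=1e-6)

    def test_fusion_commutes_with_scan_order(self, small_phantom):
        s = simulate_orthogonal_scans(small_phantom, 2.0)
        reordered = OrthogonalScanSet(list(reversed(s.scans)), s.factor,
                                      s.parent_shape)
        np.testing.assert_allclose(fuse_scans(s).data,
                                   fuse_scans(reordered).data, atol=1e-7)

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            OrthogonalScanSet([], 2.0, (8, 8, 8))

    def test_fused_psnr_drops_with_scale(self, small_phantom):
        scores = []
        for r in (2.0, 4.0):
            s = simulate_orthogonal_scans(small_phantom, r)
            scores.append(ir.psnr(fuse_scans(s), crop_to_factor(small_phantom, r)))
        assert scores[0] > scores[1]


class TestRicianNoise:
    def test_sigma_zero_is_identity(self, small_phantom):
        out = add_rician_noise(small_phantom, 0.0, seed=1)
        np.testing.assert_array_equal(out.data, small_phantom.data)

    def test_zero_signal_mean_matches_rayleigh(self):
        sigma = 25.0
        v = Volume(np.zeros((50, 50, 40), dtype=np.float32))
        out = add_rician_noise(v, sigma, seed=0)
        n = out.data.size
        assert n >= 10**5
        s = sigma / 255.0
        expected = s * math.sqrt(math.pi / 2)
        stderr = s * math.sqrt((4 - math.pi) / 2) / math.sqrt(n)
        assert abs(out.data.mean() - expected) < 3 * stderr

    def test_seed_reproducibility(self, small_phantom):
        a = add_rician_noise(small_phantom, 10.0, seed=3)
        b = add_rician_noise(small_phantom, 10.0, seed=3)
        assert np.array_equal(a.data, b.data)

    def test_deviation_grows_with_sigma(self, small_phantom):
        mads = [np.abs(add_rician_noise(small_phantom, s, seed=5).data
                       - small_phantom.data).mean() for s in (5.0, 15.0, 25.0)]
        assert mads[0] < mads[1] < mads[2]

    def test_negative_sigma_raises(self, small_phantom):
        with pytest.raises(ValueError):
            add_rician_noise(small_phantom, -1.0)


class TestCubesAndFlips:
    def test_cube_shape_default(self, rng):
        x = Volume(rng.random((30, 30, 30), dtype=np.float32))
        pairs = extract_training_cubes(x, x, cube_size=24, n=3, seed=0)
        assert all(p.lr_cube.shape == (24, 24, 24) for p in pairs)
        assert all(np.array_equal(p.lr_cube, p.hr_cube) for p in pairs)

    def test_forced_corner_origin(self, rng):
        x = Volume(rng.random((10, 10, 10), dtype=np.float32))
        y = Volume(rng.random((10, 10, 10), dtype=np.float32))
        (pair,) = extract_training_cubes(x, y, cube_size=4,
                                         origins=[(0, 0, 0)])
        np.testing.assert_array_equal(pair.lr_cube, x.data[:4, :4, :4])
        np.testing.assert_array_equal(pair.hr_cube, y.data[:4, :4, :4])

    def test_small_volume_raises(self, rng):
        x = Volume(rng.random((8, 8, 8), dtype=np.float32))
        with pytest.raises(ValueError):
            extract_training_cubes(x, x, cube_size=24, n=1, seed=0)

    def test_flip_identity_and_involution(self, rng):
        pair = TrainingPair(rng.random((4, 4, 4), dtype=np.float32),
                            rng.random((4, 4, 4), dtype=np.float32), (0, 0, 0))
        same = augment_flip(pair, (False, False, False))
        np.testing.assert_array_equal(same.lr_cube, pair.lr_cube)
        for mask in [(True, False, True), (True, True, True)]:
            twice = augment_flip(augment_flip(pair, mask), mask)
            np.testing.assert_array_equal(twice.lr_cube, pair.lr_cube)
            np.testing.assert_array_equal(twice.hr_cube, pair.hr_cube)

    def test_flip_reverses_first_axis_indices(self, rng):
        cube = rng.random((5, 4, 3), dtype=np.float32)
        pair = TrainingPair(cube, cube.copy(), (0, 0, 0))
        flipped = augment_flip(pair, (True, False, False))
        for i in range(5):
            np.testing.assert_array_equal(flipped.lr_cube[i],
                                          cube[5 - 1 - i])
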