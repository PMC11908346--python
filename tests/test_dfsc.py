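import math

import numpy as np
import pytest

from ardecon import (
    VoxelGrid,
    compute_dfsc,
    cone_coverage,
    cone_partition_stats,
    conical_fsc,
    degrade,
    estimate_resolution,
    fft3,
    fibonacci_directions,
    global_fsc,
    make_phantom,
    render_dfsc_volume,
)
from ardecon.dfsc import FSCCurve


def brute_force_conical_fsc(f1, f2, direction, apex_angle):
    """Independent per-voxel triple-loop oracle for the conical FSC."""
    n = f1.data.shape[0]
    c = n // 2
    nshell = n // 2 + 1
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    cos_lim = math.cos(math.radians(apex_angle / 2.0))
    cross = np.zeros(nshell)
    p1 = np.zeros(nshell)
    p2 = np.zeros(nshell)
    counts = np.zeros(nshell, dtype=int)
    for i in range(n):  # z (slowest axis)
        for j in range(n):  # y
            for k in range(n):  # x
                v = np.array([k - c, j - c, i - c], float)  # (x, y, z)
                if min(v) <= -c:  # unpaired Nyquist-edge voxel
                    continue
                r = np.linalg.norm(v)
                s = int(round(r))
                if s >= nshell:
                    continue
                if r > 0:
                    cosang = abs(float(v @ d)) / r
                    if cosang < cos_lim - 1e-12:
                        continue
                a = f1.data[i, j, k]
                b = f2.data[i, j, k]
                cross[s] += (a * np.conj(b)).real
                p1[s] += abs(a) ** 2
                p2[s] += abs(b) ** 2
                counts[s] += 1
    corr = np.zeros(nshell)
    denom = np.sqrt(p1 * p2)
    good = denom > 0
    corr[good] = cross[good] / denom[good]
    return np.clip(corr, -1, 1), counts


class TestFibonacciDirections:
    def test_default_count(self):
        ds = fibonacci_directions(500)
        assert ds.count == 500
        np.testing.assert_allclose(
            np.linalg.norm(ds.vectors, axis=1), 1.0, atol=1e-9
        )

    def test_two_directions(self):
        ds = fibonacci_directions(2)
        assert ds.count == 2
        np.testing.assert_allclose(
            np.linalg.norm(ds.vectors, axis=1), 1.0, atol=1e-9
        )

    def test_min_pairwise_angle_near_ideal(self):
        n = 1000
        vecs = fibonacci_directions(n).vectors
        dots = np.clip(vecs @ vecs.T, -1, 1)
        np.fill_diagonal(dots, -1)
        min_angle = np.arccos(dots.max())
        ideal = math.sqrt(8 * math.pi / (math.sqrt(3) * n))
        assert abs(min_angle - ideal) < 0.2 * ideal

    def test_deterministic(self):
        np.testing.assert_array_equal(
            fibonacci_directions(77).vectors, fibonacci_directions(77).vectors
        )

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            fibonacci_directions(0)


class TestConicalFSC:
    @pytest.mark.parametrize("dir_seed", range(5))
    def test_matches_brute_force_oracle(self, dir_seed, rng):
        f1 = fft3(VoxelGrid(rng.standard_normal((16, 16, 16)), 1.0))
        f2 = fft3(VoxelGrid(rng.standard_normal((16, 16, 16)), 1.0))
        d_rng = np.random.default_rng(100 + dir_seed)
        d = d_rng.standard_normal(3)
        d /= np.linalg.norm(d)
        curve = conical_fsc(f1, f2, d, 40.0)
        oracle, counts = brute_force_conical_fsc(f1, f2, d, 40.0)
        np.testing.assert_allclose(curve.correlations, oracle, atol=1e-10)
        np.testing.assert_array_equal(curve.n_voxels, counts)

    def test_self_correlation_is_one(self, phantom32):
        fv = fft3(phantom32)
        curve = conical_fsc(fv, fv, (0, 0, 1), 40.0)
        valid = curve.valid
        np.testing.assert_allclose(curve.correlations[valid], 1.0, atol=1e-10)

    def test_sign_flip_gives_minus_one(self, phantom32):
        fv = fft3(phantom32)
        from ardecon.volume import FourierVolume

        neg = FourierVolume(-fv.data, fv.pixel_size)
        curve = conical_fsc(fv, neg, (0, 0, 1), 40.0)
        valid = curve.valid
        np.testing.assert_allclose(curve.correlations[valid], -1.0, atol=1e-10)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(42)
        f1 = fft3(VoxelGrid(rng.standard_normal((32, 32, 32)), 1.0))
        f2 = fft3(VoxelGrid(rng.standard_normal((32, 32, 32)), 1.0))
        curve = conical_fsc(f1, f2, (0, 0, 1), 40.0)
        for s in range(1, len(curve.correlations)):
            if curve.n_voxels[s] > 0:
                bound = 3.0 / math.sqrt(curve.n_voxels[s])
                assert abs(curve.correlations[s]) < bound

    def test_shape_mismatch(self, phantom32, random_grid):
        with pytest.raises(ValueError, match="mismatch"):
            conical_fsc(fft3(phantom32), fft3(random_grid), (0, 0, 1), 40.0)

    def test_bad_apex(self, phantom32):
        fv = fft3(phantom32)
        with pytest.raises(ValueError):
            conical_fsc(fv, fv, (0, 0, 1), 0.0)


class TestComputeDfsc:
    def test_identical_halves_all_one(self, phantom32):
        result = compute_dfsc(phantom32, phantom32, n_dirs=20)
        for curve in result.curves:
            np.testing.assert_allclose(
                curve.correlations[curve.valid], 1.0, atol=1e-10
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_isotropic_noise_small_resolution_spread(self, seed):
        from ardecon import VoxelGrid, lowpass_filter

        # lowpass pins the FSC falloff so the crossing is sharply defined
        truth = lowpass_filter(make_phantom(64, 1.0, n_blobs=30, seed=seed), 5.0)
        flat = VoxelGrid(np.ones((64, 64, 64)), 1.0)  # full coverage
        ds = degrade(truth, flat, noise_sigma=0.3, seed=seed)
        result = compute_dfsc(ds.half1, ds.half2, n_dirs=60)
        res = np.asarray(
            [estimate_resolution(c, 0.143) for c in result.curves]
        )
        assert res.max() - res.min() < 0.10 * res.mean()

    @pytest.mark.parametrize("seed", range(5))
    def test_cone_degraded_worse_inside(self, seed):
        truth = make_phantom(32, 1.0, n_blobs=12, seed=seed)
        ds = degrade(truth, cone_coverage(32, 30.0), noise_sigma=0.1, seed=seed)
        result = compute_dfsc(ds.half1, ds.half2, n_dirs=100)
        stats = cone_partition_stats(result, (0, 0, 1), 30.0, threshold=0.5)
        assert stats.resolution_inside > stats.resolution_outside

    def test_volume_centro_symmetric_and_bounded(self, phantom32, rng):
        noisy1 = VoxelGrid(
            phantom32.data + 0.3 * rng.standard_normal(phantom32.data.shape), 1.0
        )
        noisy2 = VoxelGrid(
            phantom32.data + 0.3 * rng.standard_normal(phantom32.data.shape), 1.0
        )
        vol = compute_dfsc(noisy1, noisy2, n_dirs=50).volume.data
        assert vol.min() >= 0.0 and vol.max() <= 1.0
        mate = np.roll(vol[::-1, ::-1, ::-1], (1, 1, 1), axis=(0, 1, 2))
        np.testing.assert_allclose(vol, mate, atol=1e-6)

    def test_pixel_size_mismatch(self, phantom32):
        other = VoxelGrid(phantom32.data, 2.0)
        with pytest.raises(ValueError, match="pixel size"):
            compute_dfsc(phantom32, other, n_dirs=5)


class TestRenderDfscVolume:
    def test_all_ones(self):
        ds = fibonacci_directions(10)
        curves = np.ones((10, 9))
        vol = render_dfsc_volume(curves, ds, 16, 1.0)
        from ardecon.volume import radius_grid

        inside = radius_grid(16) < 8  # strictly inside Nyquist, Friedel-paired
        assert np.all(vol.data[inside] == 1.0)

    def test_all_zeros(self):
        ds = fibonacci_directions(10)
        vol = render_dfsc_volume(np.zeros((10, 9)), ds, 16, 1.0)
        assert not vol.data.any()

    def test_antipodal_centro_symmetric(self):
        from ardecon.dfsc import DirectionSet

        ds = DirectionSet(np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]))
        curves = np.vstack(
            [np.linspace(1, 0, 9), np.linspace(1, 0.5, 9)]
        )
        vol = render_dfsc_volume(curves, ds, 16, 1.0).data
        mate = np.roll(vol[::-1, ::-1, ::-1], (1, 1, 1), axis=(0, 1, 2))
        np.testing.assert_allclose(vol, mate, atol=1e-6)


class TestGlobalFSC:
    def test_identical(self, phantom32):
        fv = fft3(phantom32)
        curve = global_fsc(fv, fv)
        np.testing.assert_allclose(
            curve.correlations[curve.valid], 1.0, atol=1e-12
        )

    def test_matches_mean_of_directional_curves(self, rng):
        phantom = make_phantom(48, 1.0, n_blobs=20, seed=0)
        noisy1 = VoxelGrid(
            phantom.data + 0.5 * rng.standard_normal(phantom.data.shape), 1.0
        )
        noisy2 = VoxelGrid(
            phantom.data + 0.5 * rng.standard_normal(phantom.data.shape), 1.0
        )
        g = global_fsc(fft3(noisy1), fft3(noisy2))
        d = compute_dfsc(noisy1, noisy2, n_dirs=500)
        # average each shell only over directions whose cone populated it;
        # residual disagreement reflects the uneven cone-coverage
        # multiplicity of individual voxels at small radii
        mat = d.curve_matrix()
        valid = np.stack([c.valid for c in d.curves])
        mean_curve = np.nanmean(np.where(valid, mat, np.nan), axis=0)
        np.testing.assert_allclose(
            mean_curve[1:], g.correlations[1:], atol=0.06
        )

    def test_orthogonal_support_zero(self):
        a = np.zeros((16, 16, 16))
        b = np.zeros((16, 16, 16))
        a[4, 4, 4] = 1.0
        b[10, 12, 6] = 1.0
        ga = VoxelGrid(a, 1.0)
        gb = VoxelGrid(b, 1.0)
        curve = global_fsc(fft3(ga), fft3(gb))
        # flat spectra of offset deltas: correlation per shell ~ 0 on average
        assert abs(curve.correlations[1:].mean()) < 0.05


class TestEstimateResolution:
    def test_never_crossing_returns_nyquist(self):
        curve = FSCCurve(np.linspace(0, 0.5, 17), np.ones(17), 1 / 32)
        assert estimate_resolution(curve, 0.143) == pytest.approx(2.0)

    def test_linear_interpolation(self):
        curve = FSCCurve(
            np.array([0.1, 0.2, 0.3]), np.array([1.0, 0.5, 0.0]), 0.1
        )
        # crossing of 0.143 between 0.2 and 0.3: f = 0.2 + 0.1 * 0.357/0.5
        assert estimate_resolution(curve, 0.143) == pytest.approx(
            1.0 / 0.2714, abs=1e-3
        )

    def test_exact_node_hit(self):
        curve = FSCCurve(
            np.array([0.1, 0.2, 0.3]), np.array([1.0, 0.5, 0.0]), 0.1
        )
        assert estimate_resolution(curve, 0.5) == pytest.approx(5.0)

    def test_starts_below_threshold(self, caplog):
        curve = FSCCurve(
            np.array([0.1, 0.2, 0.3]), np.array([0.05, 0.02, 0.0]), 0.1
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="ardecon.dfsc"):
            res = estimate_resolution(curve, 0.143)
        assert res == pytest.approx(10.0)
        assert any("below threshold" in m for m in caplog.messages)

    def test_bad_threshold(self):
        curve = FSCCurve(np.array([0.1]), np.array([1.0]), 0.1)
        with pytest.raises(ValueError):
            estimate_resolution(curve, 1.5)

    def test_empty_curve(self):
        curve = FSCCurve(np.array([]), np.array([]), 0.1)
        with pytest.raises(ValueError):
            estimate_resolution(curve, 0.143)


class TestConePartition:
    def test_equal_curves_equal_resolutions(self, phantom32):
        result = compute_dfsc(phantom32, phantom32, n_dirs=50)
        stats = cone_partition_stats(result, (0, 0, 1), 30.0, threshold=0.5)
        assert stats.resolution_inside == stats.resolution_outside

    def test_partition_disjoint_exhaustive(self, phantom32):
        result = compute_dfsc(phantom32, phantom32, n_dirs=50)
        stats = cone_partition_stats(result, (0, 0, 1), 30.0)
        combined = np.union1d(stats.inside_indices, stats.outside_indices)
        np.testing.assert_array_equal(combined, np.arange(50))
        assert not np.intersect1d(
            stats.inside_indices, stats.outside_indices
        ).size

    def test_empty_inside_errors(self, phantom32):
        result = compute_dfsc(phantom32, phantom32, n_dirs=4)
        # directions of a 4-point spiral: none within 1 degree of x-axis
        with pytest.raises(ValueError, match="inside"):
            cone_partition_stats(result, (1, 0, 0), 1.0)

    def test_bad_half_angle(self, phantom32):
        result = compute_dfsc(phantom32, phantom32, n_dirs=4)
        with pytest.raises(ValueError):
            cone_partition_stats(result, (0, 0, 1), 95.0)
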