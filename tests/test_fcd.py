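"""Tests of the FCD core: neighbourhood geometry, the blocked degree
computation against the brute-force oracle, normalization and smoothing."""

import numpy as np
import pytest

from fcdensity.core import BoldRun, GridGeometry
from fcdensity.fcd import (
    FcdMap,
    FcdParams,
    brute_force_fcd,
    compute_fcd,
    fwhm_to_sigma,
    neighborhood_offsets,
    normalize_fcd,
    smooth_map,
)


def make_run(data, voxel_mm=3.0):
    data = np.asarray(data, float)
    geom = GridGeometry.isotropic(data.shape[:3], voxel_mm)
    return BoldRun(data=data, geometry=geom, tr_s=2.0)


class TestNeighborhoodOffsets:
    def test_3mm_grid_6mm_radius_has_32_offsets(self):
        offs = neighborhood_offsets((3.0, 3.0, 3.0), 6.0)
        assert len(offs) == 32
        # exhaustive lattice check: dx^2+dy^2+dz^2 <= 4, origin excluded
        expected = {
            (dx, dy, dz)
            for dx in range(-2, 3)
            for dy in range(-2, 3)
            for dz in range(-2, 3)
            if (dx, dy, dz) != (0, 0, 0) and dx**2 + dy**2 + dz**2 <= 4
        }
        assert {tuple(o) for o in offs} == expected

    def test_zero_radius_empty(self):
        assert len(neighborhood_offsets((3.0, 3.0, 3.0), 0.0)) == 0

    def test_unit_ball_face_neighbors(self):
        offs = neighborhood_offsets((1.0, 1.0, 1.0), 1.0)
        assert {tuple(o) for o in offs} == {
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
        }

    def test_anisotropic_voxels(self):
        # 2 mm in x, 4 mm in z: radius 4 reaches 2 voxels in x, 1 in z
        offs = {tuple(o) for o in neighborhood_offsets((2.0, 4.0, 4.0), 4.0)}
        assert (2, 0, 0) in offs
        assert (0, 0, 1) in offs
        assert (0, 1, 1) not in offs  # sqrt(32) mm > 4


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_random_instances_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        dims = tuple(rng.integers(4, 9, 3))
        T = int(rng.choice([20, 50, 230]))
        run = make_run(rng.standard_normal(dims + (T,)))
        gray = rng.random(dims) < 0.5
        gray[dims[0] // 2, dims[1] // 2, dims[2] // 2] = True
        params = FcdParams(
            r_threshold=float(rng.choice([0.25, 0.3])),
            radius_mm=float(rng.choice([3.0, 6.0, 9.0])),
        )
        l1, g1 = compute_fcd(run, gray, params)
        l2, g2 = brute_force_fcd(run, gray, params)
        assert np.array_equal(l1.values, l2.values)
        assert np.array_equal(g1.values, g2.values)

    def test_distance_partition_hand_case(self):
        # 1x1x4 line at 3 mm spacing: v0 and v3 share a sinusoid (9 mm
        # apart -> long-range); v1, v2 weakly correlated noise.
        T = 100
        t = np.arange(T)
        rng = np.random.default_rng(5)
        data = np.zeros((1, 1, 4, T))
        tone = np.sin(2 * np.pi * t / 20)
        data[0, 0, 0] = tone
        data[0, 0, 3] = tone
        # independent noise, verified below to stay under the threshold
        data[0, 0, 1] = rng.standard_normal(T)
        data[0, 0, 2] = rng.standard_normal(T)
        run = make_run(data)
        gray = np.ones((1, 1, 4), bool)
        R = np.corrcoef(data[0, 0])
        assert np.all(np.abs(R[[0, 3]][:, [1, 2]]) < 0.3)
        local, long_range = compute_fcd(run, gray, FcdParams())
        assert local.values[0, 0, 0] == 0
        assert long_range.values[0, 0, 0] == 1
        assert long_range.values[0, 0, 3] == 1

    def test_constant_series_have_no_edges(self):
        run = make_run(np.ones((3, 3, 3, 20)))
        gray = np.ones((3, 3, 3), bool)
        local, long_range = compute_fcd(run, gray, FcdParams())
        assert np.all(local.values == 0)
        assert np.all(long_range.values == 0)

    def test_two_perfectly_correlated_neighbors(self):
        T = 30
        tone = np.sin(np.arange(T))
        data = np.zeros((2, 1, 1, T))
        data[0, 0, 0] = tone
        data[1, 0, 0] = 2 * tone  # r = 1, 3 mm apart
        run = make_run(data)
        gray = np.ones((2, 1, 1), bool)
        local, long_range = compute_fcd(run, gray, FcdParams())
        assert local.values[0, 0, 0] == 1 and local.values[1, 0, 0] == 1
        assert np.all(long_range.values == 0)

    def test_single_gray_voxel_zero_maps(self, rng):
        run = make_run(rng.standard_normal((3, 3, 3, 20)))
        gray = np.zeros((3, 3, 3), bool)
        gray[1, 1, 1] = True
        local, long_range = brute_force_fcd(run, gray)
        assert np.all(local.values == 0) and np.all(long_range.values == 0)


class TestDegreeProperties:
    def _instance(self, seed):
        rng = np.random.default_rng(seed)
        dims = (6, 6, 6)
        run = make_run(rng.standard_normal(dims + (40,)))
        gray = rng.random(dims) < 0.6
        gray[3, 3, 3] = True
        return run, gray

    @pytest.mark.parametrize("seed", range(3))
    def test_conservation_local_plus_long_equals_total(self, seed):
        run, gray = self._instance(seed)
        params = FcdParams(r_threshold=0.25, radius_mm=6.0)
        local, long_range = compute_fcd(run, gray, params)
        # total degree: local sphere big enough to cover the whole grid
        big = FcdParams(r_threshold=0.25, radius_mm=1e3)
        total, beyond = compute_fcd(run, gray, big)
        assert np.all(beyond.values == 0)
        assert np.array_equal(local.values + long_range.values, total.values)

    @pytest.mark.parametrize("seed", range(3))
    def test_threshold_monotonicity(self, seed):
        run, gray = self._instance(seed)
        lo_l, lo_g = compute_fcd(run, gray, FcdParams(r_threshold=0.2))
        hi_l, hi_g = compute_fcd(run, gray, FcdParams(r_threshold=0.4))
        assert np.all(hi_l.values <= lo_l.values)
        assert np.all(hi_g.values <= lo_g.values)

    @pytest.mark.parametrize("seed", range(3))
    def test_radius_monotonicity(self, seed):
        run, gray = self._instance(seed)
        s_l, s_g = compute_fcd(run, gray, FcdParams(radius_mm=3.0))
        b_l, b_g = compute_fcd(run, gray, FcdParams(radius_mm=9.0))
        assert np.all(b_l.values >= s_l.values)
        assert np.all(b_g.values <= s_g.values)

    def test_axis_permutation_equivariance(self, rng):
        dims = (5, 5, 5)
        data = rng.standard_normal(dims + (30,))
        gray = rng.random(dims) < 0.6
        gray[2, 2, 2] = True
        run = make_run(data)
        local, long_range = compute_fcd(run, gray)
        perm = (1, 2, 0)
        run_p = make_run(np.transpose(data, perm + (3,)))
        gray_p = np.transpose(gray, perm)
        local_p, long_p = compute_fcd(run_p, gray_p)
        assert np.array_equal(local_p.values, np.transpose(local.values, perm))
        assert np.array_equal(long_p.values, np.transpose(long_range.values, perm))


class TestNormalize:
    def _raw(self, counts, mask=None):
        counts = np.asarray(counts, float)
        mask = np.ones(counts.shape, bool) if mask is None else mask
        return FcdMap(values=counts, kind="local", params=FcdParams(),
                      mask=mask, stage="raw_count")

    def test_three_value_example(self):
        raw = self._raw(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1))
        z = normalize_fcd(raw)
        expect = np.array([-1.2247, 0.0, 1.2247])
        assert np.allclose(z.values[:, 0, 0], expect, atol=1e-4)
        assert z.values[z.mask].mean() == pytest.approx(0.0, abs=1e-12)
        assert z.values[z.mask].std() == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        counts = rng.integers(1, 10, (4, 4, 4)).astype(float)
        z1 = normalize_fcd(self._raw(counts))
        z2 = normalize_fcd(self._raw(2 * counts))
        assert np.allclose(z1.values, z2.values)

    def test_all_zero_map_errors(self):
        with pytest.raises(ValueError, match="no connections"):
            normalize_fcd(self._raw(np.zeros((3, 3, 3))))

    def test_constant_positive_map_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            normalize_fcd(self._raw(np.full((3, 3, 3), 5.0)))

    def test_outside_mask_zero(self, rng):
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 1:3] = True
        counts = np.where(mask, rng.integers(1, 5, mask.shape), 0).astype(float)
        z = normalize_fcd(self._raw(counts, mask))
        assert np.all(z.values[~mask] == 0)


class TestSmoothing:
    def _norm_map(self, values, mask=None):
        mask = np.ones(values.shape, bool) if mask is None else mask
        return FcdMap(values=values, kind="local", params=FcdParams(),
                      mask=mask, stage="normalized")

    def test_impulse_profile_matches_gaussian(self):
        dims = (21, 21, 21)
        vals = np.zeros(dims)
        vals[10, 10, 10] = 1.0
        geom = GridGeometry.isotropic(dims, 3.0)
        out = smooth_map(self._norm_map(vals), geom, fwhm_mm=6.0)
        sigma_vox = fwhm_to_sigma(6.0) / 3.0
        ratio = out.values[11, 10, 10] / out.values[10, 10, 10]
        assert ratio == pytest.approx(np.exp(-1.0 / (2 * sigma_vox**2)), rel=1e-6)
        # symmetric across the 6 face neighbours
        faces = [out.values[11, 10, 10], out.values[9, 10, 10],
                 out.values[10, 11, 10], out.values[10, 9, 10],
                 out.values[10, 10, 11], out.values[10, 10, 9]]
        assert np.allclose(faces, faces[0])

    def test_constant_map_unchanged_inside_mask(self):
        # Mask renormalization keeps a constant map constant everywhere
        # inside the mask, including at the boundary.
        dims = (12, 12, 12)
        mask = np.zeros(dims, bool)
        mask[2:10, 2:10, 2:10] = True
        vals = np.where(mask, 3.14, 0.0)
        geom = GridGeometry.isotropic(dims, 3.0)
        out = smooth_map(self._norm_map(vals, mask), geom, fwhm_mm=6.0)
        assert np.allclose(out.values[mask], 3.14)
        assert np.all(out.values[~mask] == 0)

    def test_tiny_fwhm_is_identity(self, rng):
        vals = rng.standard_normal((8, 8, 8))
        geom = GridGeometry.isotropic((8, 8, 8), 3.0)
        out = smooth_map(self._norm_map(vals), geom, fwhm_mm=1e-6)
        assert np.allclose(out.values, vals, atol=1e-9)


def test_planted_hub_recovered_in_smoothed_local_map(planted_cohort,
                                                     planted_result):
    """With a planted local hub at share 0.8, the hub centre's group-A mean
    smoothed local FCD stands > 2 within-mask SDs above the gray median."""
    from fcdensity.synthetic import default_two_group_spec

    spec = default_two_group_spec(dims=(20, 20, 20), n_per_group=10, seed=42)
    hub_center = spec.local_hubs["A"][0].center
    gray = planted_cohort.masks.gray
    maps_a = planted_result.kinds["local"].subject_maps["A"]
    mean_map = np.mean([m.values for m in maps_a], axis=0)
    vals = mean_map[gray]
    z_hub = (mean_map[hub_center] - np.median(vals)) / vals.std()
    assert z_hub > 2.0
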