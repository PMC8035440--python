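"""Tests of the group statistics: t formulas against hand computation and
scipy, the Monte-Carlo cluster-extent null, and cluster extraction."""

import numpy as np
import pytest
from scipy import ndimage, stats

from fcdensity.core import GridGeometry
from fcdensity.group_stats import (
    CorrectionParams,
    StatMap,
    cluster_extent_threshold,
    estimate_map_fwhm,
    extract_clusters,
    one_sample_t,
    two_sample_t,
)


def maps_from(values):
    """values: (n_subjects, ...) -> list of 3D maps."""
    arr = np.asarray(values, float)
    return [m for m in arr]


ONES = np.ones((1, 1, 1), bool)


class TestOneSampleT:
    def test_hand_example(self):
        maps = maps_from(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1, 1))
        sm = one_sample_t(maps, ONES)
        assert sm.t_values[0, 0, 0] == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-4)
        assert sm.t_values[0, 0, 0] == pytest.approx(3.4641, abs=1e-4)
        assert sm.df == 2

    def test_zero_variance_flagged_zero(self):
        maps = maps_from(np.zeros((4, 2, 2, 2)))
        sm = one_sample_t(maps, np.ones((2, 2, 2), bool))
        assert np.all(sm.t_values == 0)

    def test_negation_antisymmetry(self, rng):
        vals = rng.standard_normal((5, 3, 3, 3))
        mask = np.ones((3, 3, 3), bool)
        t1 = one_sample_t(maps_from(vals), mask).t_values
        t2 = one_sample_t(maps_from(-vals), mask).t_values
        assert np.allclose(t1, -t2)

    def test_single_subject_errors(self):
        with pytest.raises(ValueError):
            one_sample_t(maps_from(np.zeros((1, 1, 1, 1))), ONES)


class TestTwoSampleT:
    def test_hand_example(self):
        a = maps_from(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1, 1))
        b = maps_from(np.array([4.0, 5.0, 6.0]).reshape(3, 1, 1, 1))
        sm = two_sample_t(a, b, ONES)
        assert sm.t_values[0, 0, 0] == pytest.approx(-3.6742, abs=1e-4)
        assert sm.df == 4

    def test_matches_scipy_pooled_t(self, rng):
        a = rng.standard_normal((6, 4, 4, 4))
        b = rng.standard_normal((8, 4, 4, 4)) + 0.3
        sm = two_sample_t(maps_from(a), maps_from(b), np.ones((4, 4, 4), bool))
        ref = stats.ttest_ind(a, b, axis=0, equal_var=True)
        assert np.allclose(sm.t_values, ref.statistic, atol=1e-10)

    def test_identical_groups_zero(self, rng):
        a = rng.standard_normal((4, 2, 2, 2))
        sm = two_sample_t(maps_from(a), maps_from(a.copy()),
                          np.ones((2, 2, 2), bool))
        assert np.allclose(sm.t_values, 0)

    def test_swap_antisymmetry(self, rng):
        a = rng.standard_normal((5, 3, 3, 3))
        b = rng.standard_normal((5, 3, 3, 3))
        mask = np.ones((3, 3, 3), bool)
        t_ab = two_sample_t(maps_from(a), maps_from(b), mask).t_values
        t_ba = two_sample_t(maps_from(b), maps_from(a), mask).t_values
        assert np.allclose(t_ab, -t_ba)


class TestExtentThreshold:
    def test_deterministic_given_seed(self):
        mask = np.ones((6, 6, 6), bool)
        geom = GridGeometry.isotropic((6, 6, 6), 3.0)
        p = CorrectionParams(n_simulations=200, fwhm_mm=6.0, seed=11)
        assert cluster_extent_threshold(mask, geom, p) == cluster_extent_threshold(
            mask, geom, p
        )

    def test_unsmoothed_null_matches_independent_mc(self):
        # With fwhm 0 on a tiny mask, the null is suprathreshold Bernoulli
        # voxels (approximately; standardization couples them weakly).
        # Cross-check the extent threshold against an independent
        # simulation written directly in the test.
        mask = np.ones((4, 4, 4), bool)
        geom = GridGeometry.isotropic((4, 4, 4), 3.0)
        p = CorrectionParams(n_simulations=2000, fwhm_mm=0.0, seed=3)
        thr = cluster_extent_threshold(mask, geom, p)
        # P(any voxel beyond the z cutoff) = 1-(1-0.01)^64 ~ 0.47 >> 0.05,
        # so a threshold of 1 can never control FWER here.
        assert thr >= 2
        rng = np.random.default_rng(99)
        z = stats.norm.isf(0.005)
        struct = ndimage.generate_binary_structure(3, 3)
        mx = []
        for _ in range(2000):
            f = rng.standard_normal((4, 4, 4))
            f = (f - f.mean()) / f.std()
            best = 0
            for supra in (f > z, f < -z):
                lab, n = ndimage.label(supra, structure=struct)
                if n:
                    best = max(best, np.bincount(lab.ravel())[1:].max())
            mx.append(best)
        mx = np.array(mx)
        ref = 1
        while np.mean(mx >= ref) > 0.05:
            ref += 1
        assert abs(thr - ref) <= 1

    def test_threshold_nondecreasing_in_smoothness(self):
        mask = np.ones((10, 10, 10), bool)
        geom = GridGeometry.isotropic((10, 10, 10), 3.0)
        means = []
        for fwhm in (0.0, 6.0, 12.0):
            thrs = [
                cluster_extent_threshold(
                    mask, geom,
                    CorrectionParams(n_simulations=200, fwhm_mm=fwhm, seed=s),
                )
                for s in range(5)
            ]
            means.append(np.mean(thrs))
        assert means[0] <= means[1] <= means[2]
        assert means[2] > means[0]

    def test_empty_mask_errors(self):
        geom = GridGeometry.isotropic((4, 4, 4), 3.0)
        with pytest.raises(ValueError):
            cluster_extent_threshold(np.zeros((4, 4, 4), bool), geom,
                                     CorrectionParams(fwhm_mm=6.0))

    def test_unresolved_smoothness_errors(self):
        geom = GridGeometry.isotropic((4, 4, 4), 3.0)
        with pytest.raises(ValueError, match="fwhm"):
            cluster_extent_threshold(np.ones((4, 4, 4), bool), geom,
                                     CorrectionParams(fwhm_mm=None))


class TestFwhmEstimator:
    @pytest.mark.parametrize("fwhm", [4.0, 8.0])
    def test_recovers_known_smoothness(self, rng, fwhm):
        # Smooth white noise with a known kernel; the first-difference
        # estimator should recover the total field FWHM within ~15%.
        dims = (24, 24, 24)
        geom = GridGeometry.isotropic(dims, 3.0)
        sigma_vox = fwhm / (2 * np.sqrt(2 * np.log(2))) / 3.0
        maps = [
            ndimage.gaussian_filter(rng.standard_normal(dims), sigma_vox)
            for _ in range(10)
        ]
        mask = np.ones(dims, bool)
        est = estimate_map_fwhm(maps, mask, geom)
        assert np.allclose(est, fwhm, rtol=0.15)


class TestExtractClusters:
    def _stat(self, t, df=18):
        return StatMap(t_values=t, df=df, mask=np.ones(t.shape, bool))

    def test_zero_map_empty_table(self):
        table = extract_clusters(
            self._stat(np.zeros((5, 5, 5))), CorrectionParams(fwhm_mm=6.0), 2,
            GridGeometry.isotropic((5, 5, 5), 3.0),
        )
        assert len(table) == 0
        assert table.to_dataframe().empty

    def test_extent_filter_drops_small_blob(self):
        t = np.zeros((8, 8, 8))
        t[2:4, 2:4, 2:4] = 10.0  # 8 voxels
        table = extract_clusters(
            self._stat(t), CorrectionParams(fwhm_mm=6.0), 50,
            GridGeometry.isotropic((8, 8, 8), 3.0),
        )
        assert len(table) == 0

    def test_signs_and_peak_metadata(self):
        t = np.zeros((8, 8, 8))
        t[1:3, 1:3, 1:3] = 5.0
        t[1, 1, 1] = 6.0
        t[5:7, 5:7, 5:7] = -4.0
        geom = GridGeometry.isotropic((8, 8, 8), 3.0)
        table = extract_clusters(self._stat(t), CorrectionParams(fwhm_mm=6.0),
                                 2, geom)
        assert len(table) == 2
        pos = table.clusters[0]
        assert pos.sign == "positive" and pos.peak_t == 6.0
        assert pos.peak_voxel == (1, 1, 1)
        assert pos.size == 8
        assert np.allclose(
            pos.peak_world_mm, geom.voxel_to_world(np.array([1, 1, 1]))
        )
        assert table.clusters[1].sign == "negative"
        assert table.clusters[1].peak_t == -4.0

    def test_all_cluster_voxels_above_threshold(self):
        rngl = np.random.default_rng(0)
        t = 3.5 * rngl.standard_normal((10, 10, 10))
        stat = self._stat(t, df=18)
        params = CorrectionParams(fwhm_mm=6.0)
        table = extract_clusters(stat, params, 1,
                                 GridGeometry.isotropic((10, 10, 10), 3.0))
        t_crit = stats.t.isf(params.voxel_p / 2, stat.df)
        for c in table:
            for v in c.voxels:
                assert abs(t[v]) > t_crit
            assert c.size >= 1


def test_planted_group_difference_yields_hub_cluster(planted_result):
    """The two-sample contrast on the planted cohort produces a positive
    local-FCD cluster containing the hub centre and a positive long-range
    cluster intersecting the planted pair regions."""
    from fcdensity.synthetic import default_two_group_spec

    spec = default_two_group_spec(dims=(20, 20, 20), n_per_group=10, seed=42)
    hub_center = spec.local_hubs["A"][0].center
    local = planted_result.kinds["local"].clusters
    assert any(c.sign == "positive" and c.contains(hub_center) for c in local)

    pair = spec.long_pairs["A"][0]
    pair_vox = set(pair.region_a) | set(pair.region_b)
    longr = planted_result.kinds["long_range"].clusters
    assert any(
        c.sign == "positive" and pair_vox & set(c.voxels) for c in longr
    )
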