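"""Group inference: t maps, smoothness, Monte-Carlo null, clusters."""

from collections import deque

import numpy as np
import pytest
from scipy import ndimage

from perafkit import (
    apply_cluster_correction,
    estimate_smoothness,
    extract_clusters,
    simulate_cluster_null,
    summary_t,
    voxelwise_t,
)
from perafkit.inference import ClusterNullDistribution, StatMap, connectivity_structure
from perafkit.peraf import PerAFMap


def _maps(arrays, mask):
    return [PerAFMap(values=a, mask=mask, affine=np.eye(4)) for a in arrays]


def flood_fill_components(binary, connectivity):
    """Exhaustive BFS labelling oracle for 3D binary fields."""
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if (connectivity == 6 and order == 1) or \
                   (connectivity == 18 and order <= 2) or connectivity == 26:
                    offs.append((dx, dy, dz))
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        comp = []
        q = deque([start])
        seen[start] = True
        while q:
            v = q.popleft()
            comp.append(v)
            for o in offs:
                w = tuple(np.add(v, o))
                if all(0 <= w[i] < binary.shape[i] for i in range(3)) \
                        and binary[w] and not seen[w]:
                    seen[w] = True
                    q.append(w)
        comps.append(frozenset(comp))
    return set(comps)


class TestVoxelwiseT:
    def test_identical_groups_give_zero_t(self, rng):
        mask = np.ones((4, 4, 3), dtype=bool)
        arrs = [rng.uniform(1, 2, mask.shape) for _ in range(3)]
        stat = voxelwise_t(_maps(arrs, mask), _maps(arrs, mask), mask)
        assert np.allclose(stat.t[mask], 0.0, atol=1e-10)
        assert stat.df == 4

    def test_agrees_with_summary_oracle_per_voxel(self, rng):
        mask = np.ones((5, 4, 3), dtype=bool)
        a = [rng.normal(2.0, 0.3, mask.shape) for _ in range(5)]
        b = [rng.normal(2.2, 0.4, mask.shape) for _ in range(7)]
        stat = voxelwise_t(_maps(a, mask), _maps(b, mask), mask)
        A, B = np.asarray(a), np.asarray(b)
        for idx in map(tuple, np.argwhere(mask)):
            xa, xb = A[(slice(None),) + idx], B[(slice(None),) + idx]
            t_ref, df_ref, _ = summary_t(
                xa.mean(), xa.std(ddof=1), 5, xb.mean(), xb.std(ddof=1), 7
            )
            assert stat.t[idx] == pytest.approx(t_ref, rel=1e-10)
            assert stat.df == df_ref

    def test_sign_convention_positive_when_b_larger(self, rng):
        mask = np.ones((3, 3, 3), dtype=bool)
        a = [rng.normal(1.0, 0.05, mask.shape) for _ in range(4)]
        b = [rng.normal(2.0, 0.05, mask.shape) for _ in range(4)]
        stat = voxelwise_t(_maps(a, mask), _maps(b, mask), mask)
        assert (stat.t[mask] > 0).all()

    def test_zero_variance_voxel_is_masked_undefined(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        a = [np.full(mask.shape, 1.0) for _ in range(3)]
        b = [np.full(mask.shape, 1.0) for _ in range(3)]
        stat = voxelwise_t(_maps(a, mask), _maps(b, mask), mask)
        assert not stat.defined.any()

    def test_covariate_contrast_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        mask = np.ones((2, 2, 1), dtype=bool)
        a = [rng.normal(1, 0.2, mask.shape) for _ in range(6)]
        b = [rng.normal(1.4, 0.2, mask.shape) for _ in range(6)]
        age = rng.uniform(40, 60, 12)
        stat = voxelwise_t(_maps(a, mask), _maps(b, mask), mask, covariates=age)
        y = np.array([m[0, 0, 0] for m in a + b])
        X = sm.add_constant(
            np.column_stack([np.r_[np.zeros(6), np.ones(6)], age])
        )
        fit = sm.OLS(y, X).fit()
        assert stat.t[0, 0, 0] == pytest.approx(fit.tvalues[1], rel=1e-8)
        assert stat.df == int(fit.df_resid)


class TestSmoothness:
    def test_white_noise_recovers_voxel_size(self, rng):
        mask = np.ones((24, 24, 24), dtype=bool)
        maps = [rng.standard_normal(mask.shape) for _ in range(10)]
        est = estimate_smoothness(maps, mask, (3.0, 3.0, 3.0))
        assert np.all(np.abs(est.fwhm_mm - 3.0) / 3.0 < 0.15)

    def test_smoothed_noise_recovers_applied_fwhm(self, rng):
        mask = np.ones((24, 24, 24), dtype=bool)
        sigma = 6.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        maps = [ndimage.gaussian_filter(rng.standard_normal(mask.shape), sigma)
                for _ in range(10)]
        est = estimate_smoothness(maps, mask, (3.0, 3.0, 3.0))
        assert np.all(np.abs(est.fwhm_mm - 6.0) <= 1.5)

    def test_constant_maps_are_an_error(self):
        mask = np.ones((6, 6, 6), dtype=bool)
        with pytest.raises(ValueError):
            estimate_smoothness([np.ones(mask.shape)] * 3, mask, (3, 3, 3))


class TestClusterNull:
    def test_unsmoothed_null_threshold_is_small(self):
        # independent-voxel intuition: at p=0.005 isolated exceedances
        # dominate, so the 5% max-extent threshold is a handful of voxels
        mask = np.ones((24, 24, 24), dtype=bool)
        null = simulate_cluster_null(mask, (0, 0, 0), (3, 3, 3), 0.005,
                                     connectivity=18, n_iter=500, seed=1)
        assert null.threshold(0.05) <= 5

    def test_threshold_grows_with_smoothness(self):
        mask = np.ones((20, 20, 16), dtype=bool)
        lo = simulate_cluster_null(mask, (3, 3, 3), (3, 3, 3), 0.005,
                                   n_iter=300, seed=2)
        hi = simulate_cluster_null(mask, (12, 12, 12), (3, 3, 3), 0.005,
                                   n_iter=300, seed=2)
        assert hi.threshold(0.05) > lo.threshold(0.05)

    def test_alpha_one_threshold_is_one_voxel(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        null = simulate_cluster_null(mask, (6, 6, 6), (3, 3, 3), 0.005,
                                     n_iter=50, seed=3)
        assert null.threshold(1.0) == 1

    def test_threshold_nonincreasing_in_alpha(self):
        mask = np.ones((16, 16, 12), dtype=bool)
        null = simulate_cluster_null(mask, (6, 6, 6), (3, 3, 3), 0.005,
                                     n_iter=200, seed=4)
        ts = [null.threshold(a) for a in (0.01, 0.05, 0.1, 0.5, 1.0)]
        assert all(x >= y for x, y in zip(ts, ts[1:]))

    def test_deterministic_given_seed(self):
        mask = np.ones((12, 12, 8), dtype=bool)
        a = simulate_cluster_null(mask, (6, 6, 6), (3, 3, 3), 0.005, n_iter=50, seed=9)
        b = simulate_cluster_null(mask, (6, 6, 6), (3, 3, 3), 0.005, n_iter=50, seed=9)
        assert np.array_equal(a.max_sizes, b.max_sizes)

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError):
            simulate_cluster_null(np.zeros((4, 4, 4), dtype=bool),
                                  (6, 6, 6), (3, 3, 3), 0.005, n_iter=10, seed=0)


def _stat_from_t(t, mask, df=30):
    from scipy import stats as sps

    p = np.where(np.isfinite(t), 2 * sps.t.sf(np.abs(t), df), np.nan)
    return StatMap(t=t, df=df, p_voxel=p, mask=mask, affine=np.diag([3, 3, 3, 1.0]))


class TestExtractClusters:
    def test_single_blob_reports_size_and_peak(self):
        mask = np.ones((6, 6, 6), dtype=bool)
        t = np.zeros(mask.shape)
        t[2, 2, 2] = 6.0
        t[2, 2, 3] = 5.0
        t[2, 3, 2] = 4.5
        t[3, 2, 2] = 4.4
        t[2, 3, 3] = 4.2
        cl = extract_clusters(_stat_from_t(t, mask), 0.005, connectivity=6)
        assert len(cl) == 1
        assert cl[0].size == 5
        assert cl[0].peak_t == pytest.approx(6.0)
        assert cl[0].sign == "increase"
        assert cl[0].peak_xyz_mm == (6.0, 6.0, 6.0)

    def test_corner_touching_blobs_split_by_connectivity(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        t = np.zeros(mask.shape)
        t[0, 0, 0] = 6.0
        t[1, 1, 1] = 6.0  # touches only at a corner
        faces = extract_clusters(_stat_from_t(t, mask), 0.005, connectivity=6)
        full = extract_clusters(_stat_from_t(t, mask), 0.005, connectivity=26)
        assert len(faces) == 2
        assert len(full) == 1

    def test_opposite_signs_never_merge(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        t = np.zeros(mask.shape)
        t[1, 1, 1], t[1, 1, 2] = 6.0, -6.0
        cl = extract_clusters(_stat_from_t(t, mask), 0.005, connectivity=26)
        assert len(cl) == 2
        assert {c.sign for c in cl} == {"increase", "decrease"}

    def test_empty_suprathreshold_set(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        assert extract_clusters(_stat_from_t(np.zeros(mask.shape), mask), 0.005) == []

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_labelling_agrees_with_flood_fill_oracle(self, connectivity, rng):
        mask = np.ones((6, 6, 6), dtype=bool)
        for _ in range(30):
            blob = rng.random(mask.shape) < 0.25
            t = np.where(blob, 8.0, 0.0)
            clusters = extract_clusters(_stat_from_t(t, mask), 0.005, connectivity)
            got = {frozenset(map(tuple, c.voxels)) for c in clusters}
            assert got == flood_fill_components(blob, connectivity)


class TestClusterCorrection:
    def _null(self, max_sizes, p_thresh=0.005, connectivity=18):
        sizes = np.asarray(max_sizes)
        return ClusterNullDistribution(
            n_iter=len(sizes), p_thresh=p_thresh, fwhm_mm=np.array([6.0] * 3),
            connectivity=connectivity, max_sizes=sizes,
        )

    def _cluster(self, size, p_thresh=0.005, connectivity=18):
        from perafkit.inference import Cluster

        return Cluster(voxels=np.zeros((size, 3), dtype=int), size=size,
                       peak_t=5.0, peak_xyz_mm=(0, 0, 0), sign="increase",
                       p_thresh=p_thresh, connectivity=connectivity)

    def test_cluster_at_threshold_minus_one_is_removed(self):
        # null calibrated so the extent threshold is 104: a 103-voxel
        # cluster ("over 103" strict rule) does not survive, 104 does
        sizes = [103] * 6 + [10] * 94
        null = self._null(sizes)
        assert null.threshold(0.05) == 104
        kept = apply_cluster_correction([self._cluster(103)], null, 0.05)
        assert kept == []
        kept = apply_cluster_correction([self._cluster(104)], null, 0.05)
        assert len(kept) == 1

    def test_huge_cluster_has_minimal_corrected_p(self):
        null = self._null([3] * 200)
        kept = apply_cluster_correction([self._cluster(50)], null, 0.05)
        assert kept[0].corrected_p <= 1.0 / 200

    def test_alpha_one_keeps_all_clusters(self):
        null = self._null([5] * 100)
        clusters = [self._cluster(1), self._cluster(2)]
        assert len(apply_cluster_correction(clusters, null, 1.0)) == 2

    def test_mismatched_p_thresh_is_refused(self):
        null = self._null([5] * 100, p_thresh=0.01)
        with pytest.raises(ValueError, match="does not match"):
            apply_cluster_correction([self._cluster(10)], null, 0.05)

    def test_invalid_connectivity_is_an_error(self):
        with pytest.raises(ValueError):
            connectivity_structure(7)
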