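import numpy as np
import pytest
from scipy import ndimage, stats

from erprep.glm import build_design, fit_glm
from erprep.group import (GroupSample, estimate_smoothness, expected_ec, extract_clusters,
                          f_to_z, fwe_threshold, one_sample_F, pool_blocks, resel_counts)

DF = (1, 16)


class TestPooling:
    def test_pooled_mean_of_block_betas(self, rng):
        d = build_design("exponential")
        fit = fit_glm(rng.normal(size=(24, 7)), d)
        pooled = pool_blocks(fit)
        assert np.allclose(pooled, fit.betas[4:8].mean(axis=0))

    def test_examples_and_linearity(self):
        d = build_design("exponential")
        fit = fit_glm(np.zeros((24, 2)), d)
        fit.betas = np.zeros((8, 2))
        fit.betas[4:8, 0] = [1, 1, 1, 1]
        fit.betas[4:8, 1] = [2, 0, 0, 0]
        assert np.allclose(pool_blocks(fit), [1.0, 0.5])


class TestOneSampleF:
    def test_zero_mean_antisymmetric_sample(self):
        x = np.array([[1.0], [-1.0], [2.0], [-2.0]])
        spm = one_sample_F(GroupSample(x, "m"))
        assert np.isclose(spm.F[0], 0.0)

    def test_equal_nonzero_values_flagged_infinite(self):
        x = np.full((17, 1), 3.0)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            spm = one_sample_F(GroupSample(x, "m"))
        assert np.isinf(spm.F[0]) and spm.n_infinite == 1

    def test_matches_direct_t_squared(self, rng):
        x = rng.normal(size=(17, 40))
        spm = one_sample_F(GroupSample(x, "m"))
        t = x.mean(axis=0) / (x.std(axis=0, ddof=1) / np.sqrt(17))
        assert np.allclose(spm.F, t ** 2, atol=1e-10)
        assert spm.df == (1, 16)

    def test_monotone_z(self, rng):
        F = np.sort(rng.uniform(0.1, 60.0, size=20))
        z = f_to_z(F, DF)
        assert np.all(np.diff(z) > 0)


class TestFToZ:
    def test_median_f_maps_to_zero(self):
        f_med = stats.f.ppf(0.5, *DF)
        assert abs(f_to_z(f_med, DF)) < 1e-9

    def test_round_trip_f_range(self):
        for F in np.linspace(1.0, 100.0, 25):
            z = f_to_z(F, DF)
            p = stats.norm.sf(z)
            back = stats.f.isf(p, *DF)
            assert abs(back - F) / F < 1e-6

    def test_negative_f_rejected(self):
        with pytest.raises(ValueError):
            f_to_z(-1.0, DF)


class TestSmoothness:
    def test_white_noise_near_one_voxel(self, rng):
        res = rng.standard_normal((17, 12, 12, 30))
        mask = np.ones((12, 12, 30), bool)
        fwhm = estimate_smoothness(res, mask)
        assert np.all(fwhm > 0.8) and np.all(fwhm < 1.25)

    def test_recovers_known_smoothing(self, rng):
        target = 8.0
        sigma = target / np.sqrt(8 * np.log(2))
        res = ndimage.gaussian_filter(
            rng.standard_normal((17, 40, 40, 40)), sigma=(0, sigma, sigma, sigma)
        )
        mask = np.ones((40, 40, 40), bool)
        fwhm = estimate_smoothness(res, mask)
        assert np.all(np.abs(fwhm - target) / target < 0.15)

    def test_monotone_in_applied_smoothing(self, rng):
        base = rng.standard_normal((10, 24, 24, 24))
        mask = np.ones((24, 24, 24), bool)
        estimates = []
        for s in (0.8, 1.6, 3.2):
            res = ndimage.gaussian_filter(base, sigma=(0, s, s, s))
            estimates.append(estimate_smoothness(res, mask).mean())
        assert estimates[0] < estimates[1] < estimates[2]

    def test_tiny_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="mask too small"):
            estimate_smoothness(rng.standard_normal((3, 2, 2, 2)), np.zeros((2, 2, 2), bool))


class TestResels:
    def test_cuboid_counts(self):
        mask = np.ones((4, 5, 6), bool)
        f = np.array([2.0, 2.0, 2.0])
        R = resel_counts(mask, f)
        # Worsley lattice counts for a full cuboid with a, b, c voxel edges
        a, b, c = 3, 4, 5  # edge lengths in links
        assert R[0] == 1
        assert np.isclose(R[1], (a + b + c) / 2.0)
        assert np.isclose(R[2], (a * b + a * c + b * c) / 4.0)
        assert np.isclose(R[3], a * b * c / 8.0)

    def test_two_disjoint_components_euler(self):
        mask = np.zeros((10, 4, 4), bool)
        mask[:3], mask[6:] = True, True
        R = resel_counts(mask, np.ones(3))
        assert R[0] == 2


class TestFweThreshold:
    def test_plug_back_equals_alpha(self):
        mask = np.ones((16, 16, 64), bool)
        fwhm = np.array([3.0, 3.0, 3.0])
        thr, resels = fwe_threshold(DF, fwhm, mask, alpha=0.05)
        assert abs(expected_ec(thr, DF, resels) - 0.05) < 1e-4

    def test_threshold_increases_with_search_volume(self):
        fwhm = np.array([3.0, 3.0, 3.0])
        t_small, _ = fwe_threshold(DF, fwhm, np.ones((8, 8, 32), bool))
        t_big, _ = fwe_threshold(DF, fwhm, np.ones((16, 16, 64), bool))
        assert t_big > t_small

    def test_threshold_decreases_with_smoothness(self):
        mask = np.ones((16, 16, 64), bool)
        t_rough, _ = fwe_threshold(DF, np.array([2.0, 2.0, 2.0]), mask)
        t_smooth, _ = fwe_threshold(DF, np.array([4.0, 4.0, 4.0]), mask)
        assert t_smooth < t_rough

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            fwe_threshold(DF, np.ones(3), np.ones((4, 4, 4), bool), alpha=1.5)


class TestClusters:
    def _table(self, F_vol, thr=10.0):
        times = 50.0 + 2.0 * np.arange(F_vol.shape[2])
        resels = np.array([1.0, 5.0, 10.0, 20.0])
        return extract_clusters(F_vol, thr, DF, resels, times, pixel_size_mm=4.25)

    def test_empty_when_nothing_supra(self):
        table = self._table(np.full((8, 8, 10), 1.0))
        assert len(table) == 0
        assert list(table.columns[:6]) == ["activation", "size", "latency_ms", "p_fwe", "F", "Z"]

    def test_single_voxel_cluster(self):
        F = np.full((8, 8, 10), 1.0)
        F[4, 4, 5] = 30.0
        table = self._table(F)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["size"] == 1 and row["F"] == 30.0
        assert row["latency_ms"] == 50.0 + 2.0 * 5
        assert np.isclose(row["Z"], f_to_z(30.0, DF))

    def test_two_blobs_sorted_by_size(self):
        F = np.full((12, 12, 12), 1.0)
        F[1:4, 1:4, 1:4] = 20.0  # 27 voxels
        F[8:10, 8:10, 8:10] = 40.0  # 8 voxels
        table = self._table(F)
        acts = table.groupby("activation")["size"].first()
        assert list(acts) == [27, 8]  # descending size, renumbered 1..n

    def test_at_most_three_separated_peaks(self):
        F = np.full((20, 20, 30), 1.0)
        F[2:18, 2:18, 2:28] = 15.0
        for k, (x, t) in enumerate([(3, 4), (9, 12), (15, 20), (16, 26)]):
            F[x, 10, t] = 50.0 + k
        table = self._table(F)
        assert table["activation"].nunique() == 1
        assert len(table) == 3  # capped at three peaks
        assert list(table["F"]) == sorted(table["F"], reverse=True)

    def test_nan_background_ignored(self):
        F = np.full((8, 8, 8), np.nan)
        F[2, 2, 2] = 25.0
        table = self._table(F)
        assert len(table) == 1
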