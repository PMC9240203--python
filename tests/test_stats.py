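"""Group statistics: t maps, chi-square, smoothness, GRF clusters, tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats as sps

from nethom.core import BrainMask
from nethom.homogeneity import NHMap
from nethom.stats import (
    NHGroupModel,
    chi_square_2x2,
    demographics_table,
    estimate_smoothness,
    extract_cluster_means,
    grf_cluster_inference,
    grf_cluster_p,
    label_clusters,
    pearson_corr,
    resel_counts,
    ttest_from_summary,
    voxelwise_two_sample_t,
)

SHAPE = (8, 8, 8)
AFFINE = np.diag([3.0, 3.0, 3.0, 1.0])


def std_map(values_3d, mask=None, sid=""):
    mask = np.ones(SHAPE, bool) if mask is None else mask
    data = np.where(mask, values_3d, np.nan)
    return NHMap(data=data, mask=mask, affine=AFFINE, stage="standardized", subject_id=sid)


def random_maps(rng, n, mask=None):
    return [std_map(rng.standard_normal(SHAPE), mask) for _ in range(n)]


class TestVoxelwiseT:
    def test_matches_scipy_per_voxel(self, rng):
        a = random_maps(rng, 10)
        b = random_maps(rng, 10)
        tmap = voxelwise_two_sample_t(a, b)
        A = np.stack([m.data for m in a])
        B = np.stack([m.data for m in b])
        expected_t, expected_p = sps.ttest_ind(A, B, axis=0, equal_var=True)
        np.testing.assert_allclose(tmap.t[tmap.mask], expected_t[tmap.mask], atol=1e-10)
        np.testing.assert_allclose(tmap.p[tmap.mask], expected_p[tmap.mask], atol=1e-10)
        assert tmap.df == 18

    def test_identical_groups_zero_t(self, rng):
        a = random_maps(rng, 5)
        tmap = voxelwise_two_sample_t(a, [std_map(m.data) for m in a])
        np.testing.assert_allclose(tmap.t[tmap.mask], 0.0, atol=1e-12)

    def test_group_swap_negates(self, rng):
        a, b = random_maps(rng, 6), random_maps(rng, 7)
        t1 = voxelwise_two_sample_t(a, b)
        t2 = voxelwise_two_sample_t(b, a)
        np.testing.assert_allclose(t1.t[t1.mask], -t2.t[t2.mask], atol=1e-12)

    def test_zero_variance_voxel_gets_t_zero(self):
        const = np.ones(SHAPE)
        a = [std_map(const) for _ in range(3)]
        b = [std_map(const) for _ in range(3)]
        tmap = voxelwise_two_sample_t(a, b)
        np.testing.assert_array_equal(tmap.t[tmap.mask], 0.0)


class TestSummaryT:
    def test_reported_age_row(self):
        """Pooled t on the published demographics reproduces the printed 0.74."""
        t, df, p = ttest_from_summary(43, 27.91, 6.48, 42, 26.96, 5.31)
        assert round(t, 2) == 0.74
        assert df == 83
        assert 0.4 < p < 0.5

    def test_matches_raw_data_oracle(self, rng):
        x = rng.normal(3, 2, 20)
        y = rng.normal(2.5, 1.5, 25)
        t, df, p = ttest_from_summary(
            20, x.mean(), x.std(ddof=1), 25, y.mean(), y.std(ddof=1)
        )
        t_ref, p_ref = sps.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_equal_means_and_bad_n(self):
        t, _, p = ttest_from_summary(5, 1.0, 1.0, 5, 1.0, 1.0)
        assert t == 0.0 and p == 1.0
        with pytest.raises(ValueError):
            ttest_from_summary(1, 0, 1, 5, 0, 1)


class TestChiSquare:
    def test_known_values(self):
        assert chi_square_2x2([[10, 10], [10, 10]])[0] == pytest.approx(0.0)
        assert chi_square_2x2([[10, 0], [0, 10]])[0] == pytest.approx(20.0)

    def test_matches_expected_count_oracle(self, rng):
        obs = rng.integers(1, 30, size=(2, 2)).astype(float)
        chi2, df, p = chi_square_2x2(obs)
        row, col = obs.sum(1, keepdims=True), obs.sum(0, keepdims=True)
        exp = row @ col / obs.sum()
        assert chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum(), abs=1e-12)
        assert df == 1

    def test_zero_marginal(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestSmoothness:
    def test_recovers_known_kernel(self):
        """White noise smoothed with an 8 mm kernel on a 3 mm grid: recovered
        FWHM within 15% per axis."""
        rng = np.random.default_rng(0)
        fwhm_vox = 8.0 / 3.0
        sigma = fwhm_vox / (2 * np.sqrt(2 * np.log(2)))
        shape = (24, 24, 24)
        maps = [ndimage.gaussian_filter(rng.standard_normal(shape), sigma) for _ in range(12)]
        mask = np.zeros(shape, bool)
        mask[4:-4, 4:-4, 4:-4] = True  # avoid the zero-padded borders
        est = estimate_smoothness(maps, mask, np.array([3.0, 3.0, 3.0]))
        assert np.all(np.abs(est.fwhm_mm - 8.0) / 8.0 < 0.15)

    def test_unsmoothed_noise_floors_at_voxel_size(self):
        rng = np.random.default_rng(1)
        maps = [rng.standard_normal((12, 12, 12)) for _ in range(10)]
        mask = np.ones((12, 12, 12), bool)
        est = estimate_smoothness(maps, mask, np.array([3.0, 3.0, 3.0]))
        np.testing.assert_allclose(est.fwhm_voxels, 1.0, atol=0.15)

    def test_voxel_size_scaling(self):
        rng = np.random.default_rng(2)
        maps = [ndimage.gaussian_filter(rng.standard_normal((16, 16, 16)), 1.5) for _ in range(8)]
        mask = np.ones((16, 16, 16), bool)
        a = estimate_smoothness(maps, mask, np.array([3.0, 3.0, 3.0]))
        b = estimate_smoothness(maps, mask, np.array([6.0, 6.0, 6.0]))
        np.testing.assert_allclose(b.fwhm_mm, 2 * a.fwhm_mm, rtol=1e-12)
        assert b.resels == pytest.approx(a.resels)  # resels live in voxel units

    def test_needs_three_maps(self):
        with pytest.raises(ValueError):
            estimate_smoothness([np.zeros((4, 4, 4))] * 2, np.ones((4, 4, 4), bool), np.ones(3))


class TestResels:
    def test_full_box_r3(self):
        mask = np.ones((10, 10, 10), bool)
        counts = resel_counts(mask, np.array([2.0, 2.0, 2.0]))
        assert counts[3] == pytest.approx(9**3 / 8.0)
        assert counts[0] == pytest.approx(1.0)  # Euler characteristic of a box


class TestLabelClusters:
    def test_connectivity_semantics(self):
        vol = np.zeros((4, 4, 4), bool)
        vol[0, 0, 0] = vol[1, 1, 1] = True  # diagonal neighbours
        assert len(label_clusters(vol, connectivity=6)) == 2
        assert len(label_clusters(vol, connectivity=26)) == 1

    def test_single_voxel(self):
        vol = np.zeros((3, 3, 3), bool)
        vol[1, 2, 0] = True
        (c,) = label_clusters(vol, 26, affine=AFFINE)
        assert c["extent"] == 1 and c["peak_index"] == (1, 2, 0)
        assert c["peak_mm"] == (3.0, 6.0, 0.0)

    def test_extents_match_flood_fill_oracle(self, rng):
        vol = rng.random((10, 10, 10)) > 0.7
        clusters = label_clusters(vol, connectivity=6)
        # brute-force flood fill with 6-connectivity
        seen = np.zeros_like(vol)
        sizes = []
        for start in np.argwhere(vol):
            if seen[tuple(start)]:
                continue
            stack, size = [tuple(start)], 0
            seen[tuple(start)] = True
            while stack:
                x, y, z = stack.pop()
                size += 1
                for dx, dy, dz in ((1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)):
                    p = (x+dx, y+dy, z+dz)
                    if all(0 <= c < 10 for c in p) and vol[p] and not seen[p]:
                        seen[p] = True
                        stack.append(p)
            sizes.append(size)
        assert sorted(sizes) == sorted(c["extent"] for c in clusters)

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            label_clusters(np.ones((2, 2, 2), bool), connectivity=8)


class TestGrfInference:
    @staticmethod
    def smoothness_for(mask):
        rng = np.random.default_rng(5)
        maps = [ndimage.gaussian_filter(rng.standard_normal(mask.shape), 1.2) for _ in range(8)]
        return estimate_smoothness(maps, mask, np.array([3.0, 3.0, 3.0]))

    def test_zero_map_empty(self, rng):
        a = [std_map(np.zeros(SHAPE) + 1e-6 * rng.standard_normal(SHAPE)) for _ in range(4)]
        b = [std_map(np.zeros(SHAPE) + 1e-6 * rng.standard_normal(SHAPE)) for _ in range(4)]
        tmap = voxelwise_two_sample_t(a, b)
        sm = self.smoothness_for(tmap.mask)
        assert grf_cluster_inference(tmap, sm) == []

    def test_cluster_p_monotone_in_extent(self):
        mask = np.ones(SHAPE, bool)
        sm = self.smoothness_for(mask)
        u = 3.1
        ps = [grf_cluster_p(k, u, sm, mask.sum()) for k in (1, 5, 20, 80, 200)]
        assert all(b < a for a, b in zip(ps, ps[1:]))
        assert all(0 < p <= 1 for p in ps)

    def test_cluster_p_monotone_in_threshold(self):
        mask = np.ones(SHAPE, bool)
        sm = self.smoothness_for(mask)
        ps = [grf_cluster_p(30, u, sm, mask.sum()) for u in (2.5, 3.0, 3.5, 4.0)]
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_directions_and_label_swap(self, rng):
        """An injected positive blob yields a patients>controls cluster; swapping
        group labels flips the direction but keeps extent and corrected p."""
        effect = np.zeros(SHAPE)
        effect[2:5, 2:5, 2:5] = 3.0
        a = [std_map(effect + 0.5 * ndimage.gaussian_filter(rng.standard_normal(SHAPE), 1.0)) for _ in range(8)]
        b = [std_map(0.5 * ndimage.gaussian_filter(rng.standard_normal(SHAPE), 1.0)) for _ in range(8)]
        t1 = voxelwise_two_sample_t(a, b)
        sm = self.smoothness_for(t1.mask)
        c1 = grf_cluster_inference(t1, sm, voxel_p=0.001, cluster_p=0.05)
        t2 = voxelwise_two_sample_t(b, a)
        c2 = grf_cluster_inference(t2, sm, voxel_p=0.001, cluster_p=0.05)
        assert c1 and c1[0].direction == "patients>controls"
        assert c2 and c2[0].direction == "patients<controls"
        assert c1[0].extent == c2[0].extent
        assert c1[0].p_corrected == pytest.approx(c2[0].p_corrected)
        assert c1[0].peak_t == pytest.approx(-c2[0].peak_t)


class TestClusterMeansAndCorr:
    def test_cluster_means_oracle(self, rng):
        maps = random_maps(rng, 6)
        vol = np.zeros(SHAPE, bool)
        vol[1:3, 1:3, 1] = True
        from nethom.stats import ClusterResult

        cluster = ClusterResult(1, "patients>controls", int(vol.sum()), 1.0, (1, 1, 1), None, 0.001, np.argwhere(vol))
        means = extract_cluster_means(maps, cluster)
        expected = [m.data[vol].mean() for m in maps]
        np.testing.assert_allclose(means, expected, atol=1e-12)

    def test_pearson_examples_and_oracle(self, rng):
        x = rng.standard_normal(30)
        assert pearson_corr(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_corr(x, -x)[0] == pytest.approx(-1.0)
        y = rng.standard_normal(30)
        r, p = pearson_corr(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_oracle = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert r == pytest.approx(r_oracle, abs=1e-12)

    def test_missing_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.1, 2.2, 3.0, 4.1, np.nan]
        r, _ = pearson_corr(x, y)
        assert r == pytest.approx(1.0, abs=0.01)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            pearson_corr([1, 2], [3, 4])
        with pytest.raises(ValueError):
            pearson_corr([1, 1, 1], [1, 2, 3])


class TestDemographics:
    @staticmethod
    def records(rng, n=20, shift=0.0):
        rows = []
        for i in range(n):
            g = "patient" if i < n // 2 else "control"
            rows.append(
                {
                    "subject_id": f"s{i}",
                    "group": g,
                    "age": rng.normal(30 + (shift if g == "patient" else 0), 5),
                    "sex": "M" if rng.random() < 0.5 else "F",
                    "education_years": rng.normal(13, 2),
                    "illness_duration": rng.normal(8, 3) if g == "patient" else np.nan,
                    "reaction_time": rng.normal(90, 20),
                    "mmse": rng.normal(28, 1),
                }
            )
        return pd.DataFrame(rows)

    def test_identical_groups_zero_stats(self, rng):
        df = self.records(rng)
        half = df[df.group == "patient"].copy()
        mirror = half.copy()
        mirror["group"] = "control"
        table = demographics_table(pd.concat([half, mirror]))
        numeric = table[table.test == "t"]
        np.testing.assert_allclose(numeric["statistic"].astype(float), 0.0, atol=1e-10)

    def test_row_count_and_chi2_row(self, rng):
        table = demographics_table(self.records(rng))
        assert (table.test == "chi2").sum() == 1
        assert len(table) == 1 + 5  # sex + five numeric variables


class TestModelResults:
    def test_summary_and_cluster_table(self, rng):
        effect = np.zeros(SHAPE)
        effect[4:7, 4:7, 4:7] = 2.5
        maps, groups = [], []
        for i in range(16):
            g = "patient" if i < 8 else "control"
            base = effect if g == "patient" else 0.0
            noise = ndimage.gaussian_filter(rng.standard_normal(SHAPE), 1.0)
            maps.append(std_map(base + 0.6 * noise, sid=f"s{i}"))
            groups.append(g)
        res = NHGroupModel(maps, groups).fit(voxel_p=0.005, cluster_p=0.05)
        text = res.summary()
        assert "patients: 8" in text and "GRF" in text
        table = res.cluster_table()
        assert set(table.columns) >= {"direction", "extent_voxels", "peak_t", "p_corrected"}
        if len(table):
            assert (table.p_corrected < 0.05).all()
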