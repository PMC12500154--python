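import numpy as np
import pytest
from scipy import stats

from saccatt.perm_cluster import (
    find_clusters,
    find_clusters_2d,
    permutation_test,
    permutation_test_2d,
)


class TestFindClusters:
    def test_all_zero_series_no_clusters(self):
        clusters, t = find_clusters(np.zeros((5, 50)))
        assert clusters == []
        np.testing.assert_array_equal(t, 0.0)

    def test_saturated_effect_single_full_span_cluster(self, rng):
        data = 1.0 + rng.normal(0, 1e-3, (6, 40))
        clusters, _ = find_clusters(data)
        assert len(clusters) == 1
        c = clusters[0]
        assert (c.start, c.stop, c.sign) == (0, 39, 1)

    def test_toy_matches_pointwise_t_oracle(self):
        # 3 participants × 5 points; independent oracle via scipy per point
        data = np.array([
            [2.0, 1.5, 0.1, -2.0, -1.5],
            [1.8, 1.2, -0.1, -1.7, -1.9],
            [2.2, 1.8, 0.2, -2.3, -1.6],
        ])
        t_oracle = np.array([stats.ttest_1samp(data[:, j], 0).statistic
                             for j in range(5)])
        p_oracle = np.array([stats.ttest_1samp(data[:, j], 0).pvalue
                             for j in range(5)])
        clusters, t = find_clusters(data, alpha=0.05)
        np.testing.assert_allclose(t, t_oracle, atol=1e-12)
        sig = p_oracle < 0.05
        # expected clusters: columns 0-1 positive, 3-4 negative (col 2 n.s.)
        assert sig.tolist() == [True, True, False, True, True]
        assert [(c.start, c.stop, c.sign) for c in clusters] == [(0, 1, 1), (3, 4, -1)]
        np.testing.assert_allclose(clusters[0].mass, t_oracle[:2].sum(), atol=1e-12)
        np.testing.assert_allclose(clusters[1].mass, t_oracle[3:].sum(), atol=1e-12)

    def test_zero_variance_point_treated_nonsignificant(self):
        data = np.ones((4, 3))
        data[:, 1] = [1.0, 2.0, -1.0, -2.0]
        clusters, t = find_clusters(data)
        assert t[0] == 0.0 and t[2] == 0.0  # undefined → set to 0

    def test_matches_mne_cluster_masses(self, rng):
        # independent implementation cross-check on the observed clusters
        mne_stats = pytest.importorskip("mne.stats")
        data = rng.normal(0.3, 1.0, (10, 120))
        n = data.shape[0]
        tcrit = stats.t.ppf(1 - 0.025, n - 1)
        t_obs, mne_clusters, _, _ = mne_stats.permutation_cluster_1samp_test(
            data, threshold=tcrit, n_permutations=10, tail=0, t_power=1,
            seed=0, out_type="mask", verbose=False)
        ours, t = find_clusters(data)
        mne_masses = sorted(float(t_obs[m].sum()) for m in mne_clusters)
        our_masses = sorted(c.mass for c in ours)
        np.testing.assert_allclose(our_masses, mne_masses, atol=1e-8)


class TestPermutationTest:
    def test_strong_effect_reported_below_resolution(self, rng):
        data = 2.0 + rng.normal(0, 0.2, (12, 60))
        res = permutation_test(data, n_perm=500, seed=0)
        assert res.min_p is not None and res.min_p <= 1.0 / 500
        assert "1/n_perm" in res.clusters[0].p_str or res.min_p > 0

    def test_sign_flip_symmetry_of_p_values(self, rng):
        data = rng.normal(0.5, 1.0, (8, 80))
        p1 = permutation_test(data, n_perm=400, seed=3).min_p
        p2 = permutation_test(-data, n_perm=400, seed=3).min_p
        assert p1 == p2

    def test_deterministic_under_seed(self, rng):
        data = rng.normal(0.2, 1.0, (8, 80))
        r1 = permutation_test(data, n_perm=300, seed=11)
        r2 = permutation_test(data, n_perm=300, seed=11)
        np.testing.assert_array_equal(r1.null_max_mass, r2.null_max_mass)
        assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]

    def test_exhaustive_matches_manual_enumeration(self, rng):
        data = rng.normal(0.8, 1.0, (4, 12))
        res = permutation_test(data, exhaustive=True)
        assert res.n_permutations == 16
        # manual enumeration oracle
        from itertools import product

        from saccatt.perm_cluster import _max_cluster_mass_rows, _t_onesample

        tcrit = stats.t.ppf(1 - 0.025, 3)
        null = []
        for signs in product((1.0, -1.0), repeat=4):
            t = _t_onesample(data * np.asarray(signs)[:, None])
            null.append(_max_cluster_mass_rows(t[None, :], tcrit)[0])
        np.testing.assert_allclose(np.sort(res.null_max_mass), np.sort(null), atol=1e-10)
        for c in res.clusters:
            expect = np.mean(np.asarray(null) >= abs(c.mass))
            assert c.p_value == pytest.approx(expect, abs=1e-12)

    def test_monte_carlo_close_to_exhaustive_at_n4(self, rng):
        data = rng.normal(0.8, 1.0, (4, 12))
        exact = permutation_test(data, exhaustive=True).min_p
        mc = permutation_test(data, n_perm=4000, seed=5).min_p
        se = np.sqrt(exact * (1 - exact) / 4000) if 0 < exact < 1 else 0.02
        assert abs(mc - exact) <= 3 * se + 1e-9

    def test_monotone_power_in_effect_size(self):
        # scaling a planted effect up never increases cluster p on average
        effect = np.concatenate([np.zeros(30), np.ones(30), np.zeros(30)])
        p_small, p_large = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noise = rng.normal(0, 1, (10, 90))
            small = noise + 0.4 * effect
            large = noise + 1.2 * effect
            ps = permutation_test(small, n_perm=300, seed=seed).min_p
            pl = permutation_test(large, n_perm=300, seed=seed).min_p
            p_small.append(1.0 if ps is None else ps)
            p_large.append(1.0 if pl is None else pl)
        assert np.mean(p_large) <= np.mean(p_small)

    def test_needs_two_participants(self):
        with pytest.raises(ValueError):
            permutation_test(np.zeros((1, 10)))


class TestClusters2D:
    def test_blob_found_with_4_connectivity(self, rng):
        maps = rng.normal(0, 1, (8, 10, 12))
        maps[:, 3:6, 4:8] += 3.0
        clusters, t = find_clusters_2d(maps)
        big = max(clusters, key=lambda c: abs(c.mass))
        assert big.sign == 1
        rows, cols = np.unravel_index(big.indices, (10, 12))
        assert set(rows) >= {3, 4, 5} and set(cols) >= {4, 5, 6, 7}

    def test_diagonal_cells_not_connected(self):
        t_map = np.zeros((6, 2, 2))
        t_map[:, 0, 0] = 5.0
        t_map[:, 1, 1] = 5.0
        noise = np.random.default_rng(0).normal(0, 0.1, (6, 2, 2))
        clusters, _ = find_clusters_2d(t_map + noise)
        assert len(clusters) == 2  # 4-connectivity keeps the diagonal apart

    def test_permutation_2d_runs_and_is_seeded(self, rng):
        maps = rng.normal(0, 1, (6, 8, 9))
        maps[:, 2:5, 3:6] += 2.0
        r1 = permutation_test_2d(maps, n_perm=200, seed=4)
        r2 = permutation_test_2d(maps, n_perm=200, seed=4)
        assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]
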