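import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from defectometer import (assign_microstates, bootstrap_stability,
                          cut_macroclusters, farthest_point_sample,
                          fit_microclusters, kde_density, mode_cluster)


def two_blobs(n=2000, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n // 2, 3)),
                   rng.normal(sep, 1, (n - n // 2, 3))])
    gt = np.repeat([0, 1], [n // 2, n - n // 2])
    return X, gt


class TestFarthestPointSampling:
    def test_full_grid_is_all_points(self):
        X = np.random.default_rng(0).normal(size=(40, 3))
        g = farthest_point_sample(X, 40, seed=1)
        assert sorted(g.indices) == list(range(40))

    def test_colinear_selects_extremes(self):
        X = np.arange(10.0)[:, None]
        # find a seed whose uniform draw starts at index 0
        seed = next(s for s in range(100)
                    if np.random.default_rng(s).integers(10) == 0)
        g = farthest_point_sample(X, 2, seed=seed)
        assert list(g.indices) == [0, 9]  # brute-force max-min from 0 is 9

    def test_seeded_determinism(self):
        X = np.random.default_rng(3).normal(size=(200, 3))
        a = farthest_point_sample(X, 50, seed=7)
        b = farthest_point_sample(X, 50, seed=7)
        np.testing.assert_array_equal(a.indices, b.indices)

    def test_oversized_grid_rejected(self):
        with pytest.raises(ValueError):
            farthest_point_sample(np.zeros((5, 2)), 6, seed=0)


class TestKDE:
    def test_positive_finite_and_symmetric(self):
        rng = np.random.default_rng(1)
        half = rng.normal(size=(2000, 3)) + [3.0, 0, 0]
        X = np.vstack([half, half * [-1.0, 1.0, 1.0]])  # mirror in x
        grid_pts = np.array([[3.0, 0, 0], [-3.0, 0, 0], [1.5, 0.5, 0], [-1.5, 0.5, 0]])
        from defectometer.pamm import GridSample
        grid = GridSample(indices=np.arange(4), points=grid_pts)
        dens = kde_density(X, grid)
        assert np.all(dens > 0) and np.all(np.isfinite(dens))
        assert dens[0] == pytest.approx(dens[1], rel=0.02)
        assert dens[2] == pytest.approx(dens[3], rel=0.02)

    def test_peak_matches_analytic_standard_normal(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10000, 3))
        grid = farthest_point_sample(X, 400, seed=0)
        dens = kde_density(X, grid)
        peak = dens.max()
        analytic = (2 * np.pi) ** -1.5
        assert peak == pytest.approx(analytic, rel=0.20)


class TestModeSeeking:
    def test_unimodal_gives_one_cluster(self):
        X = np.random.default_rng(2).normal(size=(3000, 3))
        grid = farthest_point_sample(X, 300, seed=0)
        labels, modes = mode_cluster(grid, kde_density(X, grid))
        assert len(modes) == 1 and np.all(labels == 0)

    def test_two_distant_blobs_give_two_modes_near_means(self):
        X, _ = two_blobs(seed=4)
        grid = farthest_point_sample(X, 400, seed=0)
        labels, modes = mode_cluster(grid, kde_density(X, grid))
        assert len(modes) == 2
        mode_pts = grid.points[modes]
        assert np.linalg.norm(mode_pts - np.zeros(3), axis=1).min() < 1.5
        assert np.linalg.norm(mode_pts - np.full(3, 10.0), axis=1).min() < 1.5
        assert len(set(labels)) == len(modes)

    def test_three_blobs_partition_grid(self):
        rng = np.random.default_rng(9)
        mu = np.array([[0, 0, 0], [8, 0, 0], [0, 8, 0]], float)
        X = np.vstack([rng.normal(m, 1.0, (800, 3)) for m in mu])
        grid = farthest_point_sample(X, 450, seed=1)
        labels, modes = mode_cluster(grid, kde_density(X, grid))
        assert len(modes) == 3
        assert set(labels) == {0, 1, 2}


class TestAssignment:
    def test_grid_points_keep_their_labels(self):
        X, _ = two_blobs(n=600, seed=6)
        grid = farthest_point_sample(X, 120, seed=0)
        labels, _ = mode_cluster(grid, kde_density(X, grid))
        point_labels = assign_microstates(X, grid, labels)
        np.testing.assert_array_equal(point_labels[grid.indices], labels)

    def test_planted_mixture_recovery(self):
        X, gt = two_blobs(n=3000, sep=8.0, seed=7)
        grid = farthest_point_sample(X, 500, seed=2)
        labels, _ = mode_cluster(grid, kde_density(X, grid))
        pl = assign_microstates(X, grid, labels)
        assert adjusted_rand_score(gt, pl) >= 0.9

    def test_row_permutation_equivariance(self):
        X, _ = two_blobs(n=500, seed=8)
        grid = farthest_point_sample(X, 100, seed=0)
        labels, _ = mode_cluster(grid, kde_density(X, grid))
        pl = assign_microstates(X, grid, labels)
        perm = np.random.default_rng(0).permutation(len(X))
        np.testing.assert_array_equal(assign_microstates(X[perm], grid, labels),
                                      pl[perm])


class TestBootstrapAndMacro:
    def test_separated_blobs_are_stable(self):
        X, gt = two_blobs(n=1500, sep=10.0, seed=3)
        mc = fit_microclusters(X, seed=2, n_boot=25)
        stab = mc.stability
        assert np.allclose(np.diag(stab), 1.0)
        assert np.all((stab >= 0) & (stab <= 1))
        assert np.allclose(stab, stab.T)
        # microclusters on different planted blobs are never confused
        blob_of_micro = [gt[mc.point_labels == m].mean() > 0.5
                         for m in range(mc.n_micro)]
        for a in range(mc.n_micro):
            for b in range(a + 1, mc.n_micro):
                if blob_of_micro[a] != blob_of_micro[b]:
                    assert stab[a, b] < 0.05

    def test_seeded_determinism(self):
        X, _ = two_blobs(n=800, seed=1)
        m1 = fit_microclusters(X, seed=9, n_boot=10)
        m2 = fit_microclusters(X, seed=9, n_boot=10)
        np.testing.assert_array_equal(m1.point_labels, m2.point_labels)
        np.testing.assert_array_equal(m1.stability, m2.stability)

    def test_macro_cut_identity_and_total(self):
        X, _ = two_blobs(n=1000, seed=5)
        mc = fit_microclusters(X, seed=1, n_boot=10)
        C = mc.n_micro
        ident = cut_macroclusters(mc.merge_tree, C)
        np.testing.assert_array_equal(ident.micro_to_macro, np.arange(C))
        allone = cut_macroclusters(mc.merge_tree, 1)
        assert set(allone.micro_to_macro) == {0}
        with pytest.raises(ValueError):
            cut_macroclusters(mc.merge_tree, C + 1)

    def test_three_blob_macro_recovery(self):
        rng = np.random.default_rng(13)
        mu = np.array([[0, 0, 0], [8, 0, 0], [0, 8, 0]], float)
        X = np.vstack([rng.normal(m, 1.0, (700, 3)) for m in mu])
        gt = np.repeat([0, 1, 2], 700)
        mc = fit_microclusters(X, seed=3, n_boot=25)
        mm = cut_macroclusters(mc.merge_tree, 3)
        assert adjusted_rand_score(gt, mm.apply(mc.point_labels)) >= 0.9

    def test_row_shuffle_invariance_up_to_relabeling(self):
        X, _ = two_blobs(n=900, seed=2)
        mc1 = fit_microclusters(X, seed=4, n_boot=5)
        perm = np.random.default_rng(1).permutation(len(X))
        mc2 = fit_microclusters(X[perm], seed=4, n_boot=5)
        # same macro partition of the same points, labels possibly renamed
        mm1 = cut_macroclusters(mc1.merge_tree, 2)
        mm2 = cut_macroclusters(mc2.merge_tree, 2)
        assert adjusted_rand_score(mm1.apply(mc1.point_labels)[perm],
                                   mm2.apply(mc2.point_labels)) == 1.0
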