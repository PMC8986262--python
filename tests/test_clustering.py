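import numpy as np
import pytest
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

from ltedyn import (
    center_trajectories,
    generate_timecourse,
    ihc_cluster,
    module_share,
    select_lambda,
    smooth_trajectories,
    spearman_distance,
)
from ltedyn.clustering import ModuleSet, Module

from conftest import GRID


def smoothed_fit(matrix_truth, lam=None):
    m, truth = matrix_truth
    c = center_trajectories(m)
    if lam is None:
        lam = select_lambda(c, top_n=min(200, c.n_rows))
    return smooth_trajectories(c, lam), truth


class TestSpearmanDistance:
    def test_identical_rows_distance_zero(self):
        x = np.tile(np.arange(8.0), (3, 1))
        D = spearman_distance(x)
        np.testing.assert_allclose(D, np.zeros((3, 3)), atol=1e-12)

    def test_reversed_trajectories_distance_two(self):
        x = np.vstack([np.arange(8.0), -np.arange(8.0)])
        assert spearman_distance(x)[0, 1] == pytest.approx(2.0)

    def test_matches_pearson_on_ranks_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 8))
        D = spearman_distance(X)
        for i in range(10):
            for j in range(10):
                ri, rj = rankdata(X[i]), rankdata(X[j])
                rho = np.corrcoef(ri, rj)[0, 1]
                assert D[i, j] == pytest.approx(1 - rho, abs=1e-10)

    def test_symmetric_zero_diagonal_bounded(self):
        rng = np.random.default_rng(10)
        D = spearman_distance(rng.normal(size=(15, 8)))
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-12)
        assert (D >= 0).all() and (D <= 2).all()

    def test_constant_trajectory_gets_distance_one(self):
        x = np.vstack([np.arange(8.0), np.full(8, 3.0)])
        with pytest.warns(UserWarning, match="constant"):
            D = spearman_distance(x)
        assert D[0, 1] == pytest.approx(1.0)

    def test_too_few_rows_or_points(self):
        with pytest.raises(ValueError):
            spearman_distance(np.zeros((1, 8)))
        with pytest.raises(ValueError):
            spearman_distance(np.zeros((3, 2)))


class TestIHCCluster:
    def test_identical_trajectories_single_module(self):
        fit, _ = smoothed_fit(
            generate_timecourse(0, {"A1": 20}, amplitude=2.0, sigma=1e-6, seed=0),
            lam=1.0,
        )
        ms = ihc_cluster(fit)
        assert ms.n_modules == 1
        assert len(ms.modules[0]) == 20

    def test_two_anticorrelated_archetypes_fully_recovered(self):
        fit, truth = smoothed_fit(
            generate_timecourse(
                0, {"A1": 50, "A2": 50}, amplitude=2.0, sigma=0.2, seed=4
            )
        )
        ms = ihc_cluster(fit)
        assert ms.n_modules == 2
        labels = ms.labels_for(fit.row_ids)
        ari = adjusted_rand_score(
            [truth.labels[g] for g in fit.row_ids],
            [labels[g] for g in fit.row_ids],
        )
        assert ari == 1.0

    def test_four_planted_archetypes_recovered(self):
        """Planted-partition recovery at the scale of the spec'd module
        structure (downsampled sizes): the four dominant modules match
        truth and extra modules are small."""
        fit, truth = smoothed_fit(
            generate_timecourse(
                10,
                {"A1": 80, "A2": 60, "A3": 40, "A4": 20},
                amplitude=2.0,
                sigma=0.4,
                seed=13,
            )
        )
        ms = ihc_cluster(fit)
        labels = ms.labels_for()
        top4 = {m.label for m in ms.modules[:4]}
        in4 = [g for g in fit.row_ids if labels[g] in top4]
        ari = adjusted_rand_score(
            [truth.labels[g] for g in in4], [labels[g] for g in in4]
        )
        assert ari >= 0.95
        assert all(len(m) < 20 for m in ms.modules[4:])

    def test_partition_covers_input_disjointly(self):
        fit, _ = smoothed_fit(
            generate_timecourse(30, {"A1": 30}, amplitude=1.0, sigma=1.0, seed=2)
        )
        ms = ihc_cluster(fit)
        all_members = [g for m in ms.modules for g in m.members]
        assert sorted(all_members) == sorted(fit.row_ids)

    def test_sizes_non_increasing_and_centers_are_means(self):
        fit, _ = smoothed_fit(
            generate_timecourse(20, {"A1": 40, "A2": 30}, amplitude=2.0, sigma=0.5, seed=3)
        )
        ms = ihc_cluster(fit)
        assert ms.sizes == sorted(ms.sizes, reverse=True)
        pos = {r: i for i, r in enumerate(fit.row_ids)}
        for m in ms.modules:
            idx = [pos[g] for g in m.members]
            np.testing.assert_allclose(m.center, fit.fitted[idx].mean(axis=0), atol=1e-12)

    def test_tau_minus_one_single_module(self):
        fit, _ = smoothed_fit(
            generate_timecourse(30, {}, amplitude=0.0, sigma=1.0, seed=1), lam=10.0
        )
        ms = ihc_cluster(fit, tau=-1.0)
        assert ms.n_modules == 1

    def test_tau_near_one_on_noise_gives_singletons(self):
        fit, _ = smoothed_fit(
            generate_timecourse(30, {}, amplitude=0.0, sigma=1.0, seed=6), lam=1.0
        )
        ms = ihc_cluster(fit, tau=0.999)
        assert all(len(m) == 1 for m in ms.modules)

    def test_membership_invariant_to_input_order(self):
        m, truth = generate_timecourse(
            5, {"A1": 25, "A2": 20}, amplitude=2.0, sigma=0.3, seed=8
        )
        c = center_trajectories(m)
        lam = select_lambda(c, top_n=50)
        fit = smooth_trajectories(c, lam)
        perm = np.random.default_rng(0).permutation(c.n_rows)
        c_perm = c.subset_rows([c.row_ids[i] for i in perm])
        fit_perm = smooth_trajectories(c_perm, lam)
        p1 = {frozenset(mod.members) for mod in ihc_cluster(fit).modules}
        p2 = {frozenset(mod.members) for mod in ihc_cluster(fit_perm).modules}
        assert p1 == p2

    def test_iteration_count_bounded(self):
        fit, _ = smoothed_fit(
            generate_timecourse(40, {"A1": 20}, amplitude=1.0, sigma=1.0, seed=9)
        )
        ms = ihc_cluster(fit, max_iter=3)
        assert 1 <= ms.n_iterations_run <= 3

    def test_invalid_args(self):
        fit, _ = smoothed_fit(
            generate_timecourse(10, {}, amplitude=0.0, sigma=1.0, seed=0), lam=1.0
        )
        with pytest.raises(ValueError):
            ihc_cluster(fit, max_iter=0)
        with pytest.raises(ValueError):
            ihc_cluster(fit.subset(fit.row_ids[:1]))


class TestModuleShare:
    def _ms(self, sizes):
        modules, start = [], 0
        for lab, s in enumerate(sizes, 1):
            modules.append(
                Module(lab, tuple(f"g{start + i}" for i in range(s)), np.zeros(8))
            )
            start += s
        return ModuleSet(modules, threshold=0.7, n_iterations_run=1, time_points=GRID)

    def test_basic_fraction(self):
        assert module_share(self._ms([5, 3, 2]), 2) == pytest.approx(0.8)

    def test_all_modules_give_one(self):
        assert module_share(self._ms([4, 2, 1]), 3) == 1.0

    def test_matches_brute_force_on_random_partitions(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            sizes = sorted(rng.integers(1, 30, size=6), reverse=True)
            m = int(rng.integers(1, 7))
            got = module_share(self._ms(sizes), m)
            assert got == pytest.approx(sum(sizes[:m]) / sum(sizes))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            module_share(self._ms([3, 2]), 3)
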