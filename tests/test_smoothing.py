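import numpy as np
import pytest
from scipy.interpolate import CubicSpline, make_smoothing_spline

from ltedyn import (
    ArchetypeLibrary,
    center_trajectories,
    generate_timecourse,
    select_lambda,
    smooth_trajectories,
    smoother_matrix,
    top_responsive_genes,
)
from ltedyn.smoothing import default_lambda_grid

from conftest import make_matrix


def dense_smoother_oracle(t, lam):
    """Independent construction of the smoothing-spline hat matrix.

    Basis: the j-th natural cubic spline interpolating the j-th unit
    vector at the knots (built with scipy's CubicSpline, bc_type
    'natural'); penalty: exact integral of products of the (piecewise
    linear) second derivatives via Simpson's rule per interval.
    """
    t = np.asarray(t, dtype=float)
    n = t.size
    splines = [CubicSpline(t, np.eye(n)[j], bc_type="natural") for j in range(n)]
    omega = np.zeros((n, n))
    for a in range(n - 1):
        lo, hi = t[a], t[a + 1]
        xs = np.array([lo, (lo + hi) / 2, hi])
        w = (hi - lo) / 6 * np.array([1, 4, 1])  # Simpson: exact for quadratics
        d2 = np.vstack([s(xs, 2) for s in splines])
        omega += (d2 * w) @ d2.T
    return np.linalg.inv(np.eye(n) + lam * omega)


class TestCentering:
    def test_simple_row(self):
        m = make_matrix([[1, 2, 3, 4, 5, 6, 7, 8]])
        c = center_trajectories(m)
        np.testing.assert_allclose(c.values[0], np.arange(8) - 3.5)

    def test_constant_row_becomes_zero(self):
        m = make_matrix([[5.0] * 8])
        np.testing.assert_array_equal(center_trajectories(m).values, np.zeros((1, 8)))

    def test_row_means_vanish(self, random_matrix):
        c = center_trajectories(random_matrix)
        assert np.abs(c.values.mean(axis=1)).max() < 1e-12

    def test_idempotent(self, random_matrix):
        c1 = center_trajectories(random_matrix)
        c2 = center_trajectories(c1)
        np.testing.assert_allclose(c2.values, c1.values, atol=1e-14)

    def test_replicates_averaged_per_time_point(self, grid):
        from ltedyn import ExpressionMatrix, TimeCourseDesign

        # two samples at every time point
        samples = [f"S{k}_{r}" for k in range(8) for r in (1, 2)]
        design = TimeCourseDesign(
            time_points=tuple(grid),
            sample_to_time={f"S{k}_{r}": grid[k] for k in range(8) for r in (1, 2)},
            n_subjects=2,
        )
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(3, 16))
        m = ExpressionMatrix([f"g{i}" for i in range(3)], samples, vals, design)
        c = center_trajectories(m)
        expected = vals.reshape(3, 8, 2).mean(axis=2)
        expected -= expected.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(c.values, expected, atol=1e-14)


class TestTopResponsiveGenes:
    def test_orders_by_descending_iqr(self):
        rows = np.vstack(
            [
                0.1 * np.arange(8),  # g0: small IQR
                5.0 * np.arange(8),  # g1: large
                1.0 * np.arange(8),  # g2: middle
            ]
        )
        m = make_matrix(rows)
        assert top_responsive_genes(m, 2) == ["g1", "g2"]

    def test_ties_keep_input_order(self):
        m = make_matrix(np.tile(np.arange(8.0), (5, 1)))
        assert top_responsive_genes(m, 3) == ["g0", "g1", "g2"]

    def test_matches_brute_force_iqr_sort(self):
        rng = np.random.default_rng(42)
        m = make_matrix(rng.normal(size=(500, 8)) * rng.gamma(2, size=(500, 1)))
        got = top_responsive_genes(m, 200)
        centered = m.values - m.values.mean(1, keepdims=True)
        iqrs = {
            rid: np.percentile(row, 75) - np.percentile(row, 25)
            for rid, row in zip(m.row_ids, centered)
        }
        expected = sorted(m.row_ids, key=lambda r: -iqrs[r])[:200]
        assert got == expected

    def test_invalid_n(self, random_matrix):
        with pytest.raises(ValueError):
            top_responsive_genes(random_matrix, 0)
        with pytest.raises(ValueError):
            top_responsive_genes(random_matrix, 101)


class TestSmootherMatrix:
    def test_matches_dense_basis_construction(self, grid):
        for lam in (0.5, 1.0, 50.0):
            S = smoother_matrix(grid, lam)
            np.testing.assert_allclose(S, dense_smoother_oracle(grid, lam), atol=1e-8)

    def test_matches_scipy_make_smoothing_spline(self, grid):
        rng = np.random.default_rng(1)
        y = rng.normal(size=8)
        for lam in (1.0, 100.0, 1e4):
            ours = smoother_matrix(grid, lam) @ y
            theirs = make_smoothing_spline(grid, y, lam=lam)(grid)
            np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_interpolation_limit(self, random_matrix):
        c = center_trajectories(random_matrix)
        fit = smooth_trajectories(c, 1e-12)
        np.testing.assert_allclose(fit.fitted, c.values, atol=1e-6)
        assert fit.rss.max() < 1e-10
        assert abs(fit.smoother_trace - 8) < 1e-6

    def test_heavy_penalty_limit_is_line_fit(self, grid, random_matrix):
        c = center_trajectories(random_matrix)
        fit = smooth_trajectories(c, 1e12)
        assert abs(fit.smoother_trace - 2) < 1e-3
        for i in range(5):
            coef = np.polyfit(grid, c.values[i], 1)
            np.testing.assert_allclose(fit.fitted[i], np.polyval(coef, grid), atol=1e-4)

    def test_linear_smoother_superposition(self, grid):
        rng = np.random.default_rng(2)
        y1, y2 = rng.normal(size=(2, 8))
        m = make_matrix(np.vstack([y1, y2, 3 * y1 - 2 * y2]))
        # bypass centering to test pure linearity of the smoother
        S = smoother_matrix(grid, 7.0)
        np.testing.assert_allclose(
            S @ (3 * y1 - 2 * y2), 3 * (S @ y1) - 2 * (S @ y2), atol=1e-8
        )

    def test_rss_and_trace_monotone_in_lambda(self, random_matrix):
        c = center_trajectories(random_matrix)
        lams = np.logspace(-4, 6, 30)
        fits = [smooth_trajectories(c, lam) for lam in lams]
        traces = np.array([f.smoother_trace for f in fits])
        rss_sums = np.array([f.rss.sum() for f in fits])
        assert (np.diff(traces) <= 1e-9).all()
        assert (np.diff(rss_sums) >= -1e-9).all()
        assert (traces > 2).all() and (traces <= 8 + 1e-9).all()


class TestSelectLambda:
    def test_single_candidate(self, random_matrix):
        c = center_trajectories(random_matrix)
        assert select_lambda(c, [0.1], top_n=50) == 0.1

    def test_pure_noise_prefers_heaviest_smoothing(self):
        """On null data GCV is minimized (in expectation) by the grid
        maximum; allow a few Monte-Carlo exceptions."""
        grid_lams = default_lambda_grid()
        hits = 0
        for seed in range(20):
            m, _ = generate_timecourse(200, {}, amplitude=0.0, sigma=1.0, seed=seed)
            c = center_trajectories(m)
            lam = select_lambda(c, grid_lams, top_n=200)
            hits += lam == grid_lams[-1]
        assert hits >= 16

    def test_matches_grid_scan_oracle_on_noise_free_signal(self, grid):
        lib = ArchetypeLibrary()
        m, _ = generate_timecourse(0, {"A1": 50}, amplitude=2.0, sigma=1e-9, seed=0)
        c = center_trajectories(m)
        lams = default_lambda_grid(1e-4, 1e4, 20)
        got = select_lambda(c, lams, top_n=50)
        # oracle: evaluate the mean GCV curve with independently built matrices
        K = 8
        gcvs = []
        for lam in lams:
            S = dense_smoother_oracle(grid, lam)
            rss = ((c.values - c.values @ S.T) ** 2).sum(axis=1)
            gcvs.append(np.mean(K * rss / (K - np.trace(S)) ** 2))
        assert got == lams[int(np.argmin(gcvs))]

    def test_invalid_grids(self, random_matrix):
        c = center_trajectories(random_matrix)
        with pytest.raises(ValueError):
            select_lambda(c, [], top_n=10)
        with pytest.raises(ValueError):
            select_lambda(c, [-1.0, 1.0], top_n=10)
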