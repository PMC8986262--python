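"""Trajectory centering and natural cubic smoothing-spline fits.

Model
-----
Each gene's centered trajectory is treated as noisy observations of a
smooth function of time,

    y_g(t_k) - mean_k y_g = x_g(t_k) + e_g(t_k),   e ~ N(0, sigma^2) iid,

and x_g is estimated by the natural cubic smoothing spline minimizing

    sum_k (y_k - x(t_k))^2 + lambda * int x''(t)^2 dt

with knots at the observed (possibly uneven) time points.  The solution
at the knots is linear in the data, fitted = S_lambda @ y, where

    S_lambda = (I + lambda * K)^(-1),    K = D' W^(-1) D

is the classical Reinsch / Green-Silverman form: D is the second-divided-
difference matrix and W the tridiagonal Gram matrix of the knot spacings.
Forming S_lambda explicitly keeps its trace — the smoother's effective
degrees of freedom — exact, which the downstream F-test needs.

The single smoothing parameter shared by all genes is chosen by
generalized cross-validation, GCV(lambda) = K * RSS / (K - tr S)^2,
averaged over the most-responsive genes (largest interquartile range).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import ExpressionMatrix, TimeCourseDesign

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothFit",
    "roughness_matrix",
    "smoother_matrix",
    "center_trajectories",
    "top_responsive_genes",
    "default_lambda_grid",
    "select_lambda",
    "smooth_trajectories",
]


def roughness_matrix(time_points: Sequence[float]) -> np.ndarray:
    """Penalty matrix K with f' K f = int f''(t)^2 dt for the natural cubic
    spline interpolating values f at ``time_points``."""
    t = np.asarray(time_points, dtype=float)
    n = t.size
    if n < 3:
        raise ValueError("need >=3 time points for a curvature penalty")
    h = np.diff(t)
    D = np.zeros((n - 2, n))
    W = np.zeros((n - 2, n - 2))
    for i in range(n - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -(1.0 / h[i] + 1.0 / h[i + 1])
        D[i, i + 2] = 1.0 / h[i + 1]
        W[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < n - 3:
            W[i, i + 1] = W[i + 1, i] = h[i + 1] / 6.0
    return D.T @ np.linalg.solve(W, D)


def smoother_matrix(time_points: Sequence[float], lam: float) -> np.ndarray:
    """Hat matrix S_lambda = (I + lambda K)^(-1) of the smoothing spline."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    K = roughness_matrix(time_points)
    n = K.shape[0]
    return np.linalg.inv(np.eye(n) + lam * K)


def _timecourse_design(matrix: ExpressionMatrix) -> TimeCourseDesign:
    if not isinstance(matrix.design, TimeCourseDesign):
        raise ValueError("matrix needs a time-course design for this operation")
    return matrix.design


def center_trajectories(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average replicate samples per time point, then subtract each gene's
    mean over the time grid.

    Returns a matrix with one column per time point (labels ``t<d>``) whose
    rows each have mean zero.  Centering is idempotent.
    """
    design = _timecourse_design(matrix)
    cols = []
    for t in design.time_points:
        samples = design.samples_at(t)
        if not samples:
            raise ValueError(f"no sample observed at time {t}")
        idx = [matrix.sample_ids.index(s) for s in samples]
        cols.append(matrix.values[:, idx].mean(axis=1))
    values = np.column_stack(cols)
    values = values - values.mean(axis=1, keepdims=True)
    new_ids = [f"t{t:g}" for t in design.time_points]
    new_design = TimeCourseDesign(
        time_points=design.time_points,
        sample_to_time={s: t for s, t in zip(new_ids, design.time_points)},
        n_subjects=1,
    )
    return ExpressionMatrix(
        row_ids=list(matrix.row_ids),
        sample_ids=new_ids,
        values=values,
        design=new_design,
        gene_symbols=dict(matrix.gene_symbols) if matrix.gene_symbols else None,
    )


def top_responsive_genes(matrix: ExpressionMatrix, n: int = 200) -> list[str]:
    """Row ids of the ``n`` genes with largest interquartile range of their
    centered values (descending IQR; ties keep input order)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > matrix.n_rows:
        raise ValueError(f"n={n} exceeds {matrix.n_rows} rows")
    centered = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    q75, q25 = np.percentile(centered, [75, 25], axis=1)
    iqr = q75 - q25
    order = np.argsort(-iqr, kind="stable")
    return [matrix.row_ids[i] for i in order[:n]]


def default_lambda_grid(
    lo: float = 1e-4, hi: float = 1e4, count: int = 50
) -> np.ndarray:
    return np.logspace(np.log10(lo), np.log10(hi), count)


def select_lambda(
    matrix: ExpressionMatrix,
    candidate_lambdas: Sequence[float] | None = None,
    top_n: int = 200,
) -> float:
    """Choose the smoothing parameter minimizing mean GCV over the top-IQR
    genes.

    Per-gene GCV(lambda) = K * RSS(lambda) / (K - tr S_lambda)^2; candidates
    whose trace reaches K (no residual df) are skipped with a warning.  Ties
    resolve to the smaller lambda.
    """
    design = _timecourse_design(matrix)
    if candidate_lambdas is None:
        candidate_lambdas = default_lambda_grid()
    lams = np.asarray(sorted(candidate_lambdas), dtype=float)
    if lams.size == 0:
        raise ValueError("candidate_lambdas is empty")
    if (lams <= 0).any():
        raise ValueError("candidate lambdas must be positive")
    top = top_responsive_genes(matrix, n=min(top_n, matrix.n_rows))
    sub = matrix.subset_rows(top)
    Y = sub.values - sub.values.mean(axis=1, keepdims=True)
    K = len(design.time_points)
    best_lam, best_gcv = None, np.inf
    for lam in lams:
        S = smoother_matrix(design.time_points, lam)
        tr = float(np.trace(S))
        if K - tr < 1e-10:
            warnings.warn(
                f"lambda={lam:g} leaves no residual df (tr S = {tr:.3f}); skipped"
            )
            continue
        fitted = Y @ S.T
        rss = ((Y - fitted) ** 2).sum(axis=1)
        gcv = float(np.mean(K * rss / (K - tr) ** 2))
        if gcv < best_gcv:
            best_lam, best_gcv = float(lam), gcv
    if best_lam is None:
        raise ValueError("every candidate lambda exhausted the residual df")
    logger.info("selected lambda=%g (mean GCV %.6g)", best_lam, best_gcv)
    return best_lam


@dataclass
class SmoothFit:
    """Per-gene smoothing-spline fit on a shared time grid."""

    row_ids: list[str]
    time_points: tuple[float, ...]
    fitted: np.ndarray          # genes x K fitted values at the grid
    lam: float                  # smoothing parameter used
    smoother_trace: float       # tr(S_lambda), effective df
    rss: np.ndarray             # per-gene residual sum of squares
    rss0: np.ndarray            # per-gene null (zero-function) sum of squares

    def __post_init__(self) -> None:
        self.fitted = np.asarray(self.fitted, dtype=float)
        self.rss = np.asarray(self.rss, dtype=float)
        self.rss0 = np.asarray(self.rss0, dtype=float)
        K = len(self.time_points)
        if not (0 < self.smoother_trace <= K):
            raise ValueError(f"smoother trace {self.smoother_trace} outside (0, {K}]")
        if (self.rss < -1e-12).any():
            raise ValueError("negative residual sum of squares")

    @property
    def n_genes(self) -> int:
        return len(self.row_ids)

    def subset(self, row_ids: Sequence[str]) -> "SmoothFit":
        pos = {r: i for i, r in enumerate(self.row_ids)}
        idx = [pos[r] for r in row_ids]
        return dataclasses.replace(
            self,
            row_ids=list(row_ids),
            fitted=self.fitted[idx],
            rss=self.rss[idx],
            rss0=self.rss0[idx],
        )


def smooth_trajectories(matrix: ExpressionMatrix, lam: float) -> SmoothFit:
    """Fit the shared-lambda natural cubic smoothing spline to every
    (centered) gene trajectory.

    The smoother matrix is identical for all genes, so the whole matrix is
    fitted with one dense solve; rss0 is each gene's squared norm (the
    residual of the zero function, i.e. of the null hypothesis x(t) = 0).
    """
    design = _timecourse_design(matrix)
    if len(design.time_points) < 4:
        raise ValueError("need >=4 time points to smooth")
    Y = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    S = smoother_matrix(design.time_points, lam)
    fitted = Y @ S.T
    rss = ((Y - fitted) ** 2).sum(axis=1)
    rss0 = (Y**2).sum(axis=1)
    return SmoothFit(
        row_ids=list(matrix.row_ids),
        time_points=design.time_points,
        fitted=fitted,
        lam=float(lam),
        smoother_trace=float(np.trace(S)),
        rss=rss,
        rss0=rss0,
    )
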