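"""Iterative hierarchical clustering (IHC) of DRG trajectories into gene
response modules (GRMs).

Genes whose smoothed trajectories are strongly rank-correlated
(Spearman rho >= tau, default 0.7) are grouped together by a loop of

    1. initialize: average-linkage agglomeration on d = 1 - rho_S,
       cutting the tree at height 1 - tau;
    2. merge: while any two cluster centers correlate at rho >= tau,
       merge the best-correlated pair and recompute its center;
    3. reassign: move every gene to the center it correlates with most;
       genes whose best center correlation falls below tau become
       singletons;
    4. repeat from 2 until the partition repeats (a hash of every seen
       partition is kept, so cycles terminate) or max_iter is reached.

Because membership is threshold- rather than count-controlled, modules
come out at many scales — a few dominating modules plus a tail down to
singletons, which are retained.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .smoothing import SmoothFit

__all__ = ["Module", "ModuleSet", "spearman_distance", "ihc_cluster", "module_share"]


def _rank_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise average ranks, standardized; flags constant rows.

    Returns (Z, constant) where Z has zero-mean unit-norm rows (zero rows
    where constant) so that Z @ Z.T is the Spearman correlation matrix.
    """
    R = rankdata(X, axis=1)
    R = R - R.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(R, axis=1)
    constant = norms < 1e-12
    safe = np.where(constant, 1.0, norms)
    Z = R / safe[:, None]
    Z[constant] = 0.0
    return Z, constant


def spearman_correlation(A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    """Spearman rank correlation between rows of A and rows of B (or A).

    Ties get average ranks.  Rows with zero rank variance are flagged with
    a warning and given correlation 0 against everything.
    """
    ZA, constA = _rank_rows(np.asarray(A, dtype=float))
    if B is None:
        ZB, constB = ZA, constA
    else:
        ZB, constB = _rank_rows(np.asarray(B, dtype=float))
    if constA.any() or constB.any():
        warnings.warn(
            "constant trajectory: Spearman correlation undefined, set to 0"
        )
    return ZA @ ZB.T


def spearman_distance(trajs: np.ndarray) -> np.ndarray:
    """Pairwise d = 1 - rho_S distance matrix (symmetric, zero diagonal,
    entries in [0, 2])."""
    trajs = np.asarray(trajs, dtype=float)
    if trajs.ndim != 2 or trajs.shape[0] < 2:
        raise ValueError("need >=2 trajectories")
    if trajs.shape[1] < 3:
        raise ValueError("need >=3 points per trajectory")
    C = spearman_correlation(trajs)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


@dataclass(frozen=True)
class Module:
    label: int
    members: tuple[str, ...]
    center: np.ndarray

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ModuleSet:
    """A disjoint partition of clustered genes into labeled modules,
    ordered by non-increasing size (label 1 = largest)."""

    modules: list[Module]
    threshold: float
    n_iterations_run: int
    time_points: tuple[float, ...] = ()
    row_ids: list[str] = field(default_factory=list)
    trajectories: np.ndarray | None = None  # genes x K, aligned to row_ids

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.modules:
            for g in m.members:
                if g in seen:
                    raise ValueError(f"gene {g!r} appears in more than one module")
                seen.add(g)

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @property
    def sizes(self) -> list[int]:
        return [len(m) for m in self.modules]

    def module(self, label: int) -> Module:
        for m in self.modules:
            if m.label == label:
                return m
        raise KeyError(f"no module labeled {label}")

    def labels_for(self, row_ids: list[str] | None = None) -> dict[str, int]:
        out = {g: m.label for m in self.modules for g in m.members}
        if row_ids is not None:
            return {g: out[g] for g in row_ids}
        return out

    def member_trajectories(self, label: int) -> np.ndarray:
        if self.trajectories is None:
            raise ValueError("ModuleSet carries no trajectories")
        pos = {r: i for i, r in enumerate(self.row_ids)}
        idx = [pos[g] for g in self.module(label).members]
        return self.trajectories[idx]


def _partition_key(clusters: list[list[int]]) -> str:
    canon = sorted(tuple(sorted(c)) for c in clusters)
    return hashlib.sha1(repr(canon).encode()).hexdigest()


def _merge_phase(clusters: list[list[int]], X: np.ndarray, tau: float) -> list[list[int]]:
    clusters = [list(c) for c in clusters]
    while len(clusters) > 1:
        centers = np.vstack([X[c].mean(axis=0) for c in clusters])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            C = spearman_correlation(centers)
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if C[i, j] < tau:
            break
        a, b = (i, j) if i < j else (j, i)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return clusters


def ihc_cluster(
    fit: SmoothFit,
    tau: float = 0.7,
    max_iter: int = 100,
) -> ModuleSet:
    """Cluster smoothed trajectories into gene response modules.

    Parameters
    ----------
    fit
        Smoothing fit restricted to the selected top DRGs; clustering
        operates on the fitted values at the observed grid.
    tau
        Spearman correlation threshold controlling module tightness.
    max_iter
        Upper bound on merge/reassign rounds.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    X = np.asarray(fit.fitted, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need >=2 genes to cluster")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        D = spearman_distance(X)
    Z = linkage(squareform(D, checks=False), method="average")
    init_labels = fcluster(Z, t=1.0 - tau, criterion="distance")
    clusters: list[list[int]] = [
        list(np.flatnonzero(init_labels == lab)) for lab in np.unique(init_labels)
    ]

    seen = {_partition_key(clusters)}
    n_iter = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for n_iter in range(1, max_iter + 1):
            clusters = _merge_phase(clusters, X, tau)
            # reassign every gene to its best-correlated center
            centers = np.vstack([X[c].mean(axis=0) for c in clusters])
            C = spearman_correlation(X, centers)  # n x n_clusters
            best = np.argmax(C, axis=1)
            best_corr = C[np.arange(n), best]
            new: dict[int, list[int]] = {}
            singles: list[list[int]] = []
            for g in range(n):
                if best_corr[g] < tau:
                    singles.append([g])
                else:
                    new.setdefault(int(best[g]), []).append(g)
            clusters = [c for c in new.values() if c] + singles
            key = _partition_key(clusters)
            if key in seen:
                break
            seen.add(key)

    order = sorted(range(len(clusters)), key=lambda i: (-len(clusters[i]), min(clusters[i])))
    modules = []
    for lab, ci in enumerate(order, start=1):
        idx = sorted(clusters[ci])
        modules.append(
            Module(
                label=lab,
                members=tuple(fit.row_ids[g] for g in idx),
                center=X[idx].mean(axis=0),
            )
        )
    return ModuleSet(
        modules=modules,
        threshold=tau,
        n_iterations_run=n_iter,
        time_points=fit.time_points,
        row_ids=list(fit.row_ids),
        trajectories=X,
    )


def module_share(ms: ModuleSet, m: int) -> float:
    """Fraction of clustered genes captured by the ``m`` largest modules."""
    if not 1 <= m <= ms.n_modules:
        raise ValueError(f"m must be in [1, {ms.n_modules}]")
    sizes = sorted(ms.sizes, reverse=True)
    return sum(sizes[:m]) / sum(sizes)
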