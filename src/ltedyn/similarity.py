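"""Cell-model similarity ranking on log-fold-change (LFC) profiles.

Candidate model systems (e.g. different resistant cell lines) are each
summarized by a per-gene log2 fold change between two conditions; the
profiles are restricted to the genes shared by every dataset, compared
by Euclidean distance and agglomerated by complete linkage, and the
candidate closest to a designated reference (typically a patient
contrast) is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .types import ExpressionMatrix, GroupDesign

logger = logging.getLogger(__name__)

__all__ = [
    "LFCProfile",
    "compute_lfc",
    "similarity_dendrogram",
    "SimilarityResult",
    "two_group_ttest",
]


@dataclass
class LFCProfile:
    """Per-gene log2 fold change of one dataset's contrast."""

    name: str
    genes: list[str]
    lfc: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [str(g).upper() for g in self.genes]
        self.lfc = np.asarray(self.lfc, dtype=float)
        if len(self.genes) != self.lfc.shape[0]:
            raise ValueError("genes and lfc lengths differ")
        if np.isnan(self.lfc).any():
            raise ValueError("LFC profile contains missing values")

    def as_series(self) -> pd.Series:
        return pd.Series(self.lfc, index=self.genes, name=self.name)


def compute_lfc(
    matrix: ExpressionMatrix,
    group1: str | None = None,
    group2: str | None = None,
    name: str | None = None,
) -> LFCProfile:
    """Difference of group means on the log2 scale, lfc = mean(g2) - mean(g1).

    With no explicit groups, the design's first two groups are used in
    order (first = baseline).
    """
    if not isinstance(matrix.design, GroupDesign):
        raise ValueError("matrix needs a group design to compute LFC")
    groups = matrix.design.groups
    g1 = group1 if group1 is not None else groups[0]
    g2 = group2 if group2 is not None else groups[1]
    s1 = matrix.design.samples_in(g1)
    s2 = matrix.design.samples_in(g2)
    if not s1 or not s2:
        raise ValueError(f"empty group: {g1 if not s1 else g2!r}")
    i1 = [matrix.sample_ids.index(s) for s in s1]
    i2 = [matrix.sample_ids.index(s) for s in s2]
    lfc = matrix.values[:, i2].mean(axis=1) - matrix.values[:, i1].mean(axis=1)
    return LFCProfile(name=name or f"{g2}_vs_{g1}", genes=list(matrix.row_ids), lfc=lfc)


def two_group_ttest(
    matrix: ExpressionMatrix,
    group1: str | None = None,
    group2: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch two-sample t-test between two groups.

    Plumbing for synthetic end-to-end runs (real differential-expression
    lists are pipeline inputs): returns a DataFrame with ``lfc``, ``t``,
    ``p``, BH ``q`` and the direction call ``up``/``down``/``ns``.
    """
    from scipy import stats as _stats
    from statsmodels.stats.multitest import multipletests

    if not isinstance(matrix.design, GroupDesign):
        raise ValueError("matrix needs a group design")
    groups = matrix.design.groups
    g1 = group1 if group1 is not None else groups[0]
    g2 = group2 if group2 is not None else groups[1]
    i1 = [matrix.sample_ids.index(s) for s in matrix.design.samples_in(g1)]
    i2 = [matrix.sample_ids.index(s) for s in matrix.design.samples_in(g2)]
    if not i1 or not i2:
        raise ValueError("empty group")
    a, b = matrix.values[:, i1], matrix.values[:, i2]
    t, p = _stats.ttest_ind(b, a, axis=1, equal_var=False)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    lfc = b.mean(axis=1) - a.mean(axis=1)
    call = np.where(q < alpha, np.where(lfc > 0, "up", "down"), "ns")
    return pd.DataFrame(
        {"lfc": lfc, "t": t, "p": p, "q": q, "call": call},
        index=pd.Index(matrix.row_ids, name="gene"),
    )


@dataclass
class SimilarityResult:
    names: list[str]
    shared_genes: list[str]
    distance_matrix: np.ndarray
    linkage_matrix: np.ndarray
    leaf_order: list[str]
    reference: str
    nearest: str
    newick: str


def _to_newick(Z: np.ndarray, labels: list[str]) -> str:
    from scipy.cluster.hierarchy import to_tree

    def rec(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

    return rec(to_tree(Z)) + ";"


def similarity_dendrogram(
    profiles: list[LFCProfile],
    reference: str,
    metric: str = "euclidean",
    min_shared: int = 10,
) -> SimilarityResult:
    """Cluster LFC profiles and find the candidate nearest the reference.

    Profiles are restricted to the intersection of their gene universes
    (genes missing from any profile are dropped and logged); pairwise
    distances are Euclidean (or 1 - Pearson with ``metric='correlation'``)
    and the tree uses complete linkage.
    """
    if len(profiles) < 2:
        raise ValueError("need >=2 profiles")
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("profile names must be unique")
    if reference not in names:
        raise ValueError(f"reference {reference!r} not among profiles")
    shared = set(profiles[0].genes)
    union = set(profiles[0].genes)
    for p in profiles[1:]:
        shared &= set(p.genes)
        union |= set(p.genes)
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} genes shared across profiles (need >= {min_shared})"
        )
    n_dropped = len(union) - len(shared)
    if n_dropped:
        logger.info("dropped %d genes absent from at least one profile", n_dropped)
    shared_genes = sorted(shared)
    M = np.vstack([p.as_series().loc[shared_genes].to_numpy() for p in profiles])
    cond = pdist(M, metric=metric)
    D = squareform(cond)
    Z = linkage(cond, method="complete")
    order = [names[i] for i in leaves_list(Z)]
    ref_i = names.index(reference)
    d_ref = D[ref_i].copy()
    d_ref[ref_i] = np.inf
    nearest = names[int(np.argmin(d_ref))]
    return SimilarityResult(
        names=names,
        shared_genes=shared_genes,
        distance_matrix=D,
        linkage_matrix=Z,
        leaf_order=order,
        reference=reference,
        nearest=nearest,
        newick=_to_newick(Z, names),
    )
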