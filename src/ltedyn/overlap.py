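"""Gene-set intersection (Venn decomposition) and network-degree
candidate ranking.

The candidate-refinement logic: intersect the dynamic response genes
with externally derived differential-expression sets, then rank the
surviving candidates by their number of neighbors in a supplied
interaction network — high-degree candidates ("master regulators")
head the list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .clustering import ModuleSet
from .types import GeneSet, InteractionNetwork

__all__ = ["OverlapResult", "venn", "overlap_fraction", "CandidateRanking", "rank_by_degree"]


@dataclass
class OverlapResult:
    """Exact Venn-region decomposition of 2 or 3 named gene sets.

    Regions are keyed by the sorted tuple of set names a gene belongs to,
    e.g. ``("A",)`` for genes exclusive to A, ``("A", "B")`` for genes in
    A and B but no other set.
    """

    set_names: tuple[str, ...]
    region_members: dict[tuple[str, ...], frozenset[str]]

    @property
    def region_counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.region_members.items()}

    def count(self, *names: str) -> int:
        return len(self.region_members[tuple(sorted(names))])

    def members(self, *names: str) -> frozenset[str]:
        return self.region_members[tuple(sorted(names))]


def venn(sets: list[GeneSet]) -> OverlapResult:
    """Decompose 2 or 3 gene sets into their exclusive Venn regions."""
    if not 2 <= len(sets) <= 3:
        raise ValueError(f"venn supports 2 or 3 sets, got {len(sets)}")
    names = tuple(s.name for s in sets)
    if len(set(names)) != len(names):
        raise ValueError("set names must be unique")
    by_name = {s.name: s.members for s in sets}
    regions: dict[tuple[str, ...], set[str]] = {
        tuple(sorted(combo)): set()
        for r in range(1, len(sets) + 1)
        for combo in combinations(names, r)
    }
    universe = set().union(*by_name.values())
    for g in universe:
        membership = tuple(sorted(n for n in names if g in by_name[n]))
        regions[membership].add(g)
    return OverlapResult(
        set_names=names,
        region_members={k: frozenset(v) for k, v in regions.items()},
    )


def overlap_fraction(a: GeneSet, b: GeneSet) -> float:
    """Fraction of ``a`` contained in ``b``: |a & b| / |a|."""
    if not a.members:
        raise ValueError(f"gene set {a.name!r} is empty")
    return len(a.members & b.members) / len(a.members)


@dataclass
class CandidateRanking:
    """Degree-ranked candidate genes (optionally per module of origin)."""

    table: pd.DataFrame  # columns: gene, degree, [module]
    top_n: int | None = None


def rank_by_degree(
    network: InteractionNetwork,
    candidates: GeneSet,
    per_module: ModuleSet | None = None,
    top_n: int | None = None,
) -> CandidateRanking:
    """Rank candidate genes by their number of network neighbors.

    Degrees are computed over the full network (neighbors need not be
    candidates).  Candidates absent from the network get degree 0 with a
    warning.  Ties break alphabetically.  With ``per_module``, each
    candidate is annotated with its module of origin and ``top_n`` is
    applied within each module.
    """
    if top_n is not None and top_n < 1:
        raise ValueError("top_n must be >= 1")
    degs: dict[str, int] = {g: 0 for g in candidates.members}
    nodes = network.nodes
    absent = sorted(g for g in candidates.members if g not in nodes)
    if absent:
        warnings.warn(
            f"{len(absent)} candidates absent from network (degree 0): "
            + ", ".join(absent[:5])
        )
    for e in network.edges:
        for g in e:
            if g in degs:
                degs[g] += 1
    rows = sorted(degs.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(rows, columns=["gene", "degree"])
    if per_module is not None:
        labels = per_module.labels_for()
        df["module"] = [labels.get(g) for g in df["gene"]]
        if top_n is not None:
            df = (
                df.groupby("module", dropna=False, group_keys=False, sort=False)
                .head(top_n)
                .reset_index(drop=True)
            )
    elif top_n is not None:
        df = df.head(top_n).reset_index(drop=True)
    return CandidateRanking(table=df, top_n=top_n)
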