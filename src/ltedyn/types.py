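"""Shared domain types for the time-course expression analysis pipeline.

The central container is :class:`ExpressionMatrix` — a genes (or probes)
x samples table of log2-scale intensities together with a design that
assigns each sample either a time point (:class:`TimeCourseDesign`) or a
group label (:class:`GroupDesign`).  Gene sets and interaction networks
are lightweight wrappers around uppercased-symbol sets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "TimeCourseDesign",
    "GroupDesign",
    "ExpressionMatrix",
    "GeneSet",
    "InteractionNetwork",
]


@dataclass(frozen=True)
class TimeCourseDesign:
    """Assignment of samples to acquisition times (days).

    Parameters
    ----------
    time_points
        Strictly increasing acquisition times in days.  At least four
        distinct time points are required so the trajectory F-test has
        positive residual degrees of freedom.
    sample_to_time
        Map from sample id to one of ``time_points``.  Several samples
        may share a time point (replicate series); they are averaged
        per time point before smoothing.
    n_subjects
        Number of replicate series (>= 1).
    """

    time_points: tuple[float, ...]
    sample_to_time: Mapping[str, float]
    n_subjects: int = 1

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.time_points)
        object.__setattr__(self, "time_points", tp)
        object.__setattr__(self, "sample_to_time", dict(self.sample_to_time))
        if len(tp) < 4:
            raise ValueError(
                f"need >=4 distinct time points, got {len(tp)}"
            )
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError(f"time points must be strictly increasing: {tp}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        known = set(tp)
        for sample, t in self.sample_to_time.items():
            if float(t) not in known:
                raise ValueError(
                    f"sample {sample!r} maps to time {t}, not a listed time point"
                )

    @property
    def n_times(self) -> int:
        return len(self.time_points)

    def samples_at(self, t: float) -> list[str]:
        """Sample ids acquired at time ``t``, in insertion order."""
        return [s for s, st in self.sample_to_time.items() if float(st) == float(t)]


@dataclass(frozen=True)
class GroupDesign:
    """Two-(or more-)group assignment of samples, for contrast analyses."""

    sample_to_group: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_to_group", dict(self.sample_to_group))
        if not self.sample_to_group:
            raise ValueError("empty group design")

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.sample_to_group.values():
            seen.setdefault(g)
        return tuple(seen)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.sample_to_group.items() if g == group]


@dataclass
class ExpressionMatrix:
    """Probes/genes x samples matrix of log2-scale expression values."""

    row_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    design: TimeCourseDesign | GroupDesign | None = None
    gene_symbols: dict[str, str] | None = None
    dropped_rows: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.row_ids = list(self.row_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.sample_ids)} samples"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            seen: set[str] = set()
            for rid in self.row_ids:
                if rid in seen:
                    raise ValueError(f"duplicate row id: {rid!r}")
                seen.add(rid)
        if np.isnan(self.values).any():
            raise ValueError("ExpressionMatrix must not contain missing values")

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row_index(self, row_id: str) -> int:
        try:
            return self.row_ids.index(row_id)
        except ValueError:
            raise KeyError(f"unknown row id {row_id!r}") from None

    def subset_rows(self, row_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.row_index(r) for r in row_ids]
        symbols = None
        if self.gene_symbols is not None:
            symbols = {r: self.gene_symbols[r] for r in row_ids if r in self.gene_symbols}
        return dataclasses.replace(
            self,
            row_ids=list(row_ids),
            values=self.values[idx],
            gene_symbols=symbols,
            dropped_rows=(),
        )


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols.  Symbols are uppercased on construction
    so that cross-dataset comparisons are symbol-case insensitive."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet name must be nonempty")
        object.__setattr__(
            self, "members", frozenset(str(m).upper() for m in self.members)
        )

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return str(symbol).upper() in self.members


@dataclass(frozen=True)
class InteractionNetwork:
    """An undirected gene-gene / protein-protein interaction network.

    Edges are unordered symbol pairs; self-loops and duplicates are
    rejected at construction.
    """

    edges: frozenset[frozenset[str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        clean: set[frozenset[str]] = set()
        for e in self.edges:
            pair = frozenset(str(x).upper() for x in e)
            if len(pair) != 2:
                raise ValueError(f"self-loop or malformed edge: {sorted(e)}")
            clean.add(pair)
        object.__setattr__(self, "edges", frozenset(clean))

    @property
    def nodes(self) -> frozenset[str]:
        out: set[str] = set()
        for e in self.edges:
            out.update(e)
        return frozenset(out)

    def degree(self, symbol: str) -> int:
        s = str(symbol).upper()
        return sum(1 for e in self.edges if s in e)

    def __len__(self) -> int:
        return len(self.edges)
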