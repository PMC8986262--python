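"""Readers and writers for expression tables, designs, gene lists and
edge lists.

Expression tables are plain TSV in the style of a GEO series matrix:
row ids in the first column, sample ids in the header.  The design
(time in days or group label per sample) travels in a YAML sidecar.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    ExpressionMatrix,
    GeneSet,
    GroupDesign,
    InteractionNetwork,
    TimeCourseDesign,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_design",
    "write_design",
    "collapse_probes_to_genes",
    "read_gene_set",
    "write_gene_set",
    "read_edge_list",
    "write_edge_list",
]


def read_design(path: str | Path) -> TimeCourseDesign | GroupDesign:
    """Load a sample design from a YAML sidecar.

    Expected layout::

        kind: timecourse            # or "groups"
        samples: {S1: 0, S2: 3, ...}   # sample -> time in days (or group)
        n_subjects: 1               # timecourse only, optional
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    kind = doc.get("kind", "timecourse")
    samples = doc["samples"]
    if kind == "timecourse":
        times = tuple(sorted({float(t) for t in samples.values()}))
        return TimeCourseDesign(
            time_points=times,
            sample_to_time={s: float(t) for s, t in samples.items()},
            n_subjects=int(doc.get("n_subjects", 1)),
        )
    if kind == "groups":
        return GroupDesign(sample_to_group={s: str(g) for s, g in samples.items()})
    raise ValueError(f"unknown design kind {kind!r}")


def write_design(design: TimeCourseDesign | GroupDesign, path: str | Path) -> None:
    if isinstance(design, TimeCourseDesign):
        doc = {
            "kind": "timecourse",
            "samples": {s: float(t) for s, t in design.sample_to_time.items()},
            "n_subjects": design.n_subjects,
        }
    else:
        doc = {"kind": "groups", "samples": dict(design.sample_to_group)}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_expression_table(
    path: str | Path,
    design: TimeCourseDesign | GroupDesign | str | Path | None = None,
) -> ExpressionMatrix:
    """Read a TSV expression table (row ids in column 1, samples in header).

    Rows containing any missing value are dropped; the count is logged.
    Every sample named in the design must appear in the header.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip"
    )
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate row id: {dup!r}")
    if isinstance(design, (str, Path)):
        design = read_design(design)
    if design is not None:
        design_samples = (
            design.sample_to_time
            if isinstance(design, TimeCourseDesign)
            else design.sample_to_group
        )
        missing = [s for s in design_samples if s not in df.columns]
        if missing:
            raise ValueError(
                f"sample {missing[0]!r} in design is absent from table header"
            )
        df = df[list(design_samples)]
    values = df.apply(pd.to_numeric, errors="coerce")
    keep = ~values.isna().any(axis=1)
    dropped = tuple(df.index[~keep])
    if dropped:
        logger.info("dropped %d rows with missing values", len(dropped))
    values = values.loc[keep]
    return ExpressionMatrix(
        row_ids=list(values.index),
        sample_ids=list(values.columns),
        values=values.to_numpy(dtype=float),
        design=design,
        dropped_rows=dropped,
    )


def write_expression_table(
    matrix: ExpressionMatrix,
    path: str | Path,
    design_path: str | Path | None = None,
) -> None:
    """Write a TSV expression table at full float precision (round-trip safe)."""
    df = pd.DataFrame(matrix.values, index=matrix.row_ids, columns=matrix.sample_ids)
    df.index.name = "id"
    df.to_csv(path, sep="\t", float_format="%.17g")
    if design_path is not None and matrix.design is not None:
        write_design(matrix.design, design_path)


def collapse_probes_to_genes(
    matrix: ExpressionMatrix, scores: Sequence[float] | Mapping[str, float]
) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene symbol.

    For each symbol the probe with the maximal score is kept (ties go to
    the probe earliest in input order); rows without a symbol annotation
    are dropped and counted.  Scores are typically the probes' F
    statistics, so gene-level sets are deterministic given a DRG table.
    """
    if matrix.gene_symbols is None or not matrix.gene_symbols:
        raise ValueError("matrix has no gene_symbols annotation")
    if isinstance(scores, Mapping):
        score_arr = np.array([scores.get(r, -np.inf) for r in matrix.row_ids])
    else:
        score_arr = np.asarray(list(scores), dtype=float)
        if score_arr.shape[0] != matrix.n_rows:
            raise ValueError(
                f"scores length {score_arr.shape[0]} != {matrix.n_rows} rows"
            )
    best: dict[str, int] = {}
    n_unannotated = 0
    for i, rid in enumerate(matrix.row_ids):
        sym = matrix.gene_symbols.get(rid)
        if not sym:
            n_unannotated += 1
            continue
        sym = sym.upper()
        if sym not in best or score_arr[i] > score_arr[best[sym]]:
            best[sym] = i
    if n_unannotated:
        logger.info("dropped %d unannotated probes", n_unannotated)
    # preserve input order of the winning probes
    order = sorted(best.items(), key=lambda kv: kv[1])
    symbols = [sym for sym, _ in order]
    idx = [i for _, i in order]
    return ExpressionMatrix(
        row_ids=symbols,
        sample_ids=list(matrix.sample_ids),
        values=matrix.values[idx],
        design=matrix.design,
        gene_symbols=None,
    )


def read_gene_set(path: str | Path, name: str) -> GeneSet:
    """Read a one-symbol-per-line gene list; symbols are uppercased and
    deduplicated."""
    members = []
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym:
                members.append(sym.upper())
    if not members:
        raise ValueError(f"empty gene-set file: {path}")
    return GeneSet(name=name, members=frozenset(members))


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sym in sorted(gs.members):
            fh.write(sym + "\n")


def read_edge_list(path: str | Path) -> InteractionNetwork:
    """Read a two-column TSV edge list into an undirected network.

    Self-loop lines are skipped with a warning; duplicate edges (in either
    orientation) collapse to one.
    """
    edges: set[frozenset[str]] = set()
    n_lines = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise ValueError(f"malformed edge line: {line.strip()!r}")
            n_lines += 1
            a, b = parts[0].upper(), parts[1].upper()
            if a == b:
                logger.warning("skipping self-loop edge %s-%s", a, b)
                continue
            edges.add(frozenset((a, b)))
    if n_lines == 0:
        raise ValueError(f"empty edge-list file: {path}")
    return InteractionNetwork(edges=frozenset(edges))


def write_edge_list(network: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{e[0]}\t{e[1]}\n")
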