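"""Synthetic time-course and two-group expression data.

The generator reproduces the statistical structure the pipeline assumes:
a majority of flat null genes plus planted dynamic genes following a
small library of smooth trajectory archetypes, all observed on the
(uneven) 8-point day grid 0/3/15/30/90/120/150/180 and distorted by
iid Gaussian noise with mean 0 and variance sigma^2.  Baseline levels
are drawn N(8, 1) on the log2 scale — a typical microarray range —
and are irrelevant after centering.

Archetypes are cubic curves through control points at days 0/30/150/180,
normalized to zero mean and unit peak amplitude over the default grid:

* ``A1`` — gradual downregulation to day 30, then sharp upregulation to
  day 150 (the dominant resistance-development pattern);
* ``A2`` — the mirror image (up to day 30, sharp down after);
* ``A3`` — late transient peak: slow decline, sharp rise to day 150,
  drop at the end of the course;
* ``A4`` — early downregulation with partial late recovery.

The four shapes are mutually distinguishable at the default clustering
threshold: every pairwise Spearman correlation magnitude on the default
grid is below 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .types import ExpressionMatrix, GeneSet, GroupDesign, TimeCourseDesign

__all__ = [
    "DEFAULT_TIME_POINTS",
    "ArchetypeLibrary",
    "SyntheticTruth",
    "generate_timecourse",
    "generate_two_group",
    "generate_overlapping_sets",
]

DEFAULT_TIME_POINTS: tuple[float, ...] = (0.0, 3.0, 15.0, 30.0, 90.0, 120.0, 150.0, 180.0)

# control values at days 0 / 30 / 150 / 180 for each archetype shape
_CONTROL_DAYS = np.array([0.0, 30.0, 150.0, 180.0])
_CONTROL_VALUES: dict[str, tuple[float, float, float, float]] = {
    "A1": (0.0, -1.0, 1.5, 1.5),
    "A2": (0.0, 1.0, -1.5, -1.5),
    "A3": (-0.3, -0.5, 1.0, -1.0),
    "A4": (1.0, -1.0, 0.0, 0.3),
}


class ArchetypeLibrary:
    """Named smooth unit-amplitude trajectory shapes on [0, 180] days.

    Each archetype is a monotone-piecewise-cubic interpolant through its
    control points, shifted and scaled so that over ``grid`` it has mean
    zero and max |value| = 1.
    """

    def __init__(
        self,
        control_values: Mapping[str, Sequence[float]] | None = None,
        grid: Sequence[float] = DEFAULT_TIME_POINTS,
    ) -> None:
        self.grid = np.asarray(grid, dtype=float)
        raw = dict(_CONTROL_VALUES if control_values is None else control_values)
        self._interp: dict[str, PchipInterpolator] = {}
        self._shift: dict[str, float] = {}
        self._scale: dict[str, float] = {}
        for name, vals in raw.items():
            f = PchipInterpolator(_CONTROL_DAYS, np.asarray(vals, dtype=float))
            on_grid = f(self.grid)
            shift = float(on_grid.mean())
            scale = float(np.abs(on_grid - shift).max())
            if scale == 0:
                raise ValueError(f"archetype {name!r} is constant on the grid")
            self._interp[name] = f
            self._shift[name] = shift
            self._scale[name] = scale

    @property
    def names(self) -> list[str]:
        return list(self._interp)

    def curve(self, name: str, t: Sequence[float] | None = None) -> np.ndarray:
        """Archetype values at times ``t`` (default: the library grid)."""
        if name not in self._interp:
            raise KeyError(f"unknown archetype {name!r} (have {self.names})")
        tt = self.grid if t is None else np.asarray(t, dtype=float)
        return (self._interp[name](tt) - self._shift[name]) / self._scale[name]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth labels of a simulated time-course dataset."""

    labels: Mapping[str, str]  # gene id -> archetype name or "null"
    amplitude: float
    sigma: float
    seed: int | None

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", dict(self.labels))
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def planted(self) -> list[str]:
        return [g for g, lab in self.labels.items() if lab != "null"]

    def nulls(self) -> list[str]:
        return [g for g, lab in self.labels.items() if lab == "null"]


def generate_timecourse(
    n_null: int,
    module_sizes: Mapping[str, int] | None = None,
    amplitude: float = 2.0,
    sigma: float = 1.0,
    time_points: Sequence[float] = DEFAULT_TIME_POINTS,
    seed: int | None = None,
    archetypes: ArchetypeLibrary | None = None,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a time-course expression matrix with planted dynamic genes.

    Each null gene is a constant baseline plus noise; each planted gene
    additionally follows ``amplitude * archetype(t)``.  The same seed
    reproduces the matrix bit for bit.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n_null < 0:
        raise ValueError("n_null must be >= 0")
    module_sizes = dict(module_sizes or {})
    lib = archetypes or ArchetypeLibrary(grid=time_points)
    for name in module_sizes:
        if name not in lib.names:
            raise KeyError(f"unknown archetype {name!r} (have {lib.names})")
    t = np.asarray(time_points, dtype=float)
    K = t.size
    rng = np.random.default_rng(seed)

    gene_ids: list[str] = []
    labels: dict[str, str] = {}
    signal_rows: list[np.ndarray] = []
    counter = 0
    for name, count in module_sizes.items():
        shape = lib.curve(name, t)
        for _ in range(count):
            counter += 1
            gid = f"G{counter:05d}"
            gene_ids.append(gid)
            labels[gid] = name
            signal_rows.append(amplitude * shape)
    for _ in range(n_null):
        counter += 1
        gid = f"G{counter:05d}"
        gene_ids.append(gid)
        labels[gid] = "null"
        signal_rows.append(np.zeros(K))

    n = len(gene_ids)
    baseline = rng.normal(baseline_mean, baseline_sd, size=n)
    noise = rng.normal(0.0, sigma, size=(n, K))
    values = baseline[:, None] + np.vstack(signal_rows) + noise

    sample_ids = [f"S{k + 1}" for k in range(K)]
    design = TimeCourseDesign(
        time_points=tuple(t),
        sample_to_time={s: tp for s, tp in zip(sample_ids, t)},
    )
    matrix = ExpressionMatrix(
        row_ids=gene_ids, sample_ids=sample_ids, values=values, design=design
    )
    truth = SyntheticTruth(labels=labels, amplitude=amplitude, sigma=sigma, seed=seed)
    return matrix, truth


def generate_two_group(
    n_genes: int,
    n_up: int,
    n_down: int,
    lfc: float = 1.0,
    sigma: float = 1.0,
    n_per_group: int = 10,
    seed: int | None = None,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.0,
    name_prefix: str = "GENE",
) -> tuple[ExpressionMatrix, GeneSet, GeneSet]:
    """Simulate a two-group contrast with planted up/down genes.

    Group-2 samples of up genes are shifted +lfc on the log2 scale, down
    genes -lfc, all other genes 0.  Returns the matrix plus the planted
    up- and down-regulated gene sets.
    """
    if min(n_genes, n_up, n_down, n_per_group) < 0 or n_per_group == 0:
        raise ValueError("counts must be non-negative and n_per_group positive")
    if n_up + n_down > n_genes:
        raise ValueError(f"n_up + n_down = {n_up + n_down} exceeds n_genes = {n_genes}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"{name_prefix}{i + 1:05d}" for i in range(n_genes)]
    shift = np.zeros(n_genes)
    shift[:n_up] = lfc
    shift[n_up : n_up + n_down] = -lfc
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    g1 = baseline[:, None] + rng.normal(0, sigma, size=(n_genes, n_per_group))
    g2 = (
        baseline[:, None]
        + shift[:, None]
        + rng.normal(0, sigma, size=(n_genes, n_per_group))
    )
    values = np.hstack([g1, g2])
    samples = [f"C{i + 1}" for i in range(n_per_group)] + [
        f"T{i + 1}" for i in range(n_per_group)
    ]
    design = GroupDesign(
        sample_to_group={
            **{s: "group1" for s in samples[:n_per_group]},
            **{s: "group2" for s in samples[n_per_group:]},
        }
    )
    matrix = ExpressionMatrix(
        row_ids=genes, sample_ids=samples, values=values, design=design
    )
    up = GeneSet(name="up", members=frozenset(genes[:n_up]))
    down = GeneSet(name="down", members=frozenset(genes[n_up : n_up + n_down]))
    return matrix, up, down


def generate_overlapping_sets(
    universe_size: int,
    sizes: Sequence[int],
    pairwise: int | Sequence[int] | None = None,
    triple: int = 0,
    seed: int | None = None,
    names: Sequence[str] = ("A", "B", "C"),
) -> list[GeneSet]:
    """Build 2 or 3 gene sets realizing exact Venn-region cardinalities.

    For two sets ``pairwise`` is |A & B|; for three sets it is the triple
    (|A & B|, |A & C|, |B & C|) and ``triple`` is |A & B & C|.  Region
    counts are derived by inclusion-exclusion and must all be feasible
    (non-negative, fitting in the universe); the first violated constraint
    is reported otherwise.
    """
    k = len(sizes)
    if k not in (2, 3):
        raise ValueError("sizes must list 2 or 3 set sizes")
    if any(s < 0 for s in sizes):
        raise ValueError("set sizes must be non-negative")
    nm = tuple(names[:k])
    if k == 2:
        ab = int(pairwise if pairwise is not None else 0)
        if ab > min(sizes):
            raise ValueError(
                f"overlap {ab} exceeds smallest set size {min(sizes)}"
            )
        regions = {
            (nm[0],): sizes[0] - ab,
            (nm[1],): sizes[1] - ab,
            (nm[0], nm[1]): ab,
        }
    else:
        if pairwise is None:
            pairwise = (0, 0, 0)
        ab, ac, bc = (int(x) for x in pairwise)
        t = int(triple)
        for label, pair_count in (
            (f"{nm[0]}&{nm[1]}", ab),
            (f"{nm[0]}&{nm[2]}", ac),
            (f"{nm[1]}&{nm[2]}", bc),
        ):
            if t > pair_count:
                raise ValueError(
                    f"triple overlap {t} exceeds pairwise overlap |{label}| = {pair_count}"
                )
        regions = {
            (nm[0], nm[1], nm[2]): t,
            (nm[0], nm[1]): ab - t,
            (nm[0], nm[2]): ac - t,
            (nm[1], nm[2]): bc - t,
            (nm[0],): sizes[0] - ab - ac + t,
            (nm[1],): sizes[1] - ab - bc + t,
            (nm[2],): sizes[2] - ac - bc + t,
        }
    for region, count in regions.items():
        if count < 0:
            raise ValueError(
                f"infeasible configuration: region {'&'.join(region)} "
                f"would need {count} genes"
            )
    total = sum(regions.values())
    if total > universe_size:
        raise ValueError(
            f"union size {total} exceeds universe size {universe_size}"
        )
    rng = np.random.default_rng(seed)
    pool = rng.choice(universe_size, size=total, replace=False)
    symbols = iter(f"GENE{i + 1:05d}" for i in pool)
    members: dict[str, set[str]] = {n: set() for n in nm}
    for region, count in regions.items():
        for _ in range(count):
            sym = next(symbols)
            for setname in region:
                members[setname].add(sym)
    return [GeneSet(name=n, members=frozenset(members[n])) for n in nm]
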