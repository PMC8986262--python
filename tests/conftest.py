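import numpy as np
import pytest

from ltedyn import ExpressionMatrix, TimeCourseDesign
from ltedyn.simulate import DEFAULT_TIME_POINTS

GRID = DEFAULT_TIME_POINTS


@pytest.fixture
def grid():
    return np.asarray(GRID)


@pytest.fixture
def design():
    samples = [f"S{k + 1}" for k in range(len(GRID))]
    return TimeCourseDesign(
        time_points=GRID,
        sample_to_time={s: t for s, t in zip(samples, GRID)},
    )


@pytest.fixture
def random_matrix(design):
    """100 random gene trajectories on the default 8-point grid."""
    rng = np.random.default_rng(0)
    n = 100
    return ExpressionMatrix(
        row_ids=[f"g{i}" for i in range(n)],
        sample_ids=list(design.sample_to_time),
        values=rng.normal(8.0, 1.0, size=(n, len(GRID))),
        design=design,
    )


def make_matrix(values, design=None, prefix="g"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, k = values.shape
    if design is None:
        tp = GRID[:k] if k <= len(GRID) else tuple(float(i) for i in range(k))
        samples = [f"S{j + 1}" for j in range(k)]
        design = TimeCourseDesign(
            time_points=tp, sample_to_time={s: t for s, t in zip(samples, tp)}
        )
    return ExpressionMatrix(
        row_ids=[f"{prefix}{i}" for i in range(n)],
        sample_ids=list(design.sample_to_time),
        values=values,
        design=design,
    )
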