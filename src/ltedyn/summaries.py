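"""Module temporal summaries: mean trends and bootstrap mean-trend bands.

The band (a "multiple-sampling" display) is a nonparametric bootstrap
over module members: B resamples of the member set with replacement,
a mean trajectory per resample, and pointwise percentiles of those
resampled means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import ModuleSet

__all__ = ["ModuleTrend", "module_mean_trend", "msm_trend"]


@dataclass
class ModuleTrend:
    label: int
    time_points: tuple[float, ...]
    mean_trend: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    B: int
    level: float
    seed: int | None
    boot_mean: np.ndarray | None = None  # mean of the bootstrap mean trends
    boot_se: np.ndarray | None = None    # bootstrap SE of the mean trend


def module_mean_trend(ms: ModuleSet, module_label: int) -> np.ndarray:
    """Pointwise arithmetic mean of the member trajectories."""
    trajs = ms.member_trajectories(module_label)
    return trajs.mean(axis=0)


def msm_trend(
    ms: ModuleSet,
    module_label: int,
    B: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> ModuleTrend:
    """Bootstrap band for a module's mean expression trend.

    ``level`` is the central coverage of the band; level=0 collapses the
    band to the bootstrap median trend.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 <= level <= 1:
        raise ValueError("level must be in [0, 1]")
    trajs = ms.member_trajectories(module_label)
    n = trajs.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    boot_means = trajs[idx].mean(axis=1)  # B x K
    lo_pct = 100.0 * (1.0 - level) / 2.0
    hi_pct = 100.0 * (1.0 + level) / 2.0
    band_low, band_high = np.percentile(boot_means, [lo_pct, hi_pct], axis=0)
    return ModuleTrend(
        label=module_label,
        time_points=ms.time_points,
        mean_trend=trajs.mean(axis=0),
        band_low=band_low,
        band_high=band_high,
        B=B,
        level=level,
        seed=seed,
        boot_mean=boot_means.mean(axis=0),
        boot_se=boot_means.std(axis=0, ddof=1) if B > 1 else np.zeros(trajs.shape[1]),
    )
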