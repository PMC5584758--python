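"""Structural-complexity summaries of reef transect profiles.

Two rugosity measures are computed from each (distance, depth) profile:

* digital reef rugosity (DRR) — the standard deviation of depths along the
  transect (m); and
* chain rugosity C = D / L, where D is the along-contour distance (the sum of
  hypotenuses between successive depth measurements) and L the linear transect
  distance.  C = 1 for a flat reef.

Semivariograms decompose the spatial variability of a profile among lag
classes: gamma(d) = sum_i (y_i - y_{i+d})^2 / (2 N(d)) over all admissible
pairs, reported in 10 cm lag classes up to half the transect length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trace_processing import TransectProfile


@dataclass
class ComplexityMetrics:
    """Per-transect structural-complexity summary."""

    drr: float              # SD of depths, m
    c: float                # chain rugosity D/L, dimensionless, >= 1
    d: float                # contour distance, m
    l: float                # linear distance, m
    vertical_relief: float  # depth_max - depth_min, m
    depth_mean: float
    depth_min: float
    depth_max: float


@dataclass
class Semivariogram:
    lags: np.ndarray         # lag distance d, m
    gamma: np.ndarray        # semivariance, m^2
    pair_counts: np.ndarray  # N(d)
    max_lag: float


def digital_reef_rugosity(profile: TransectProfile) -> float:
    """Sample standard deviation (n-1 denominator) of profile depths, in m."""
    if len(profile) < 2:
        raise ValueError("DRR requires at least 2 depth samples")
    return float(np.std(profile.depth, ddof=1))


def chain_rugosity(profile: TransectProfile) -> tuple[float, float, float]:
    """Chain rugosity C = D/L.

    Returns (C, D, L) where D is the summed hypotenuse length between
    successive (distance, depth) samples and L the linear transect distance.
    """
    if len(profile) < 2:
        raise ValueError("chain rugosity requires at least 2 samples")
    dd = np.diff(profile.distance)
    dz = np.diff(profile.depth)
    d_contour = float(np.sum(np.hypot(dd, dz)))
    l_linear = float(profile.distance[-1] - profile.distance[0])
    if l_linear <= 0:
        raise ValueError("zero linear transect distance")
    return d_contour / l_linear, d_contour, l_linear


def vertical_relief(profile: TransectProfile) -> float:
    """Difference between maximum and minimum depth, m."""
    if len(profile) < 1:
        raise ValueError("empty profile")
    return float(np.max(profile.depth) - np.min(profile.depth))


def compute_metrics(profile: TransectProfile) -> ComplexityMetrics:
    c, d, l = chain_rugosity(profile)
    return ComplexityMetrics(
        drr=digital_reef_rugosity(profile),
        c=c, d=d, l=l,
        vertical_relief=vertical_relief(profile),
        depth_mean=float(np.mean(profile.depth)),
        depth_min=float(np.min(profile.depth)),
        depth_max=float(np.max(profile.depth)),
    )


def resample_uniform(profile: TransectProfile, step: float) -> TransectProfile:
    """Linearly interpolate depth onto a uniform distance grid over [0, L].

    Needed because realized diver swim speed varies: raw samples are uniform in
    time, not distance.  Depths outside the sampled span clamp to the nearest
    sample.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round(profile.transect_length / step))
    grid = np.linspace(0.0, profile.transect_length, n + 1)
    depth = np.interp(grid, profile.distance, profile.depth)
    return TransectProfile(distance=grid, depth=depth,
                           transect_length=profile.transect_length)


def semivariogram(profile: TransectProfile, lag_step: float = 0.1,
                  max_lag: float | None = None,
                  enforce_half_length: bool = True) -> Semivariogram:
    """Empirical semivariogram of a profile on a uniform lag grid.

    The profile is resampled to a uniform ``lag_step`` grid so lag classes are
    exact multiples of the step even under variable swim speed.  Lags run up to
    ``max_lag`` (default L/2 — the spatially structured component; larger
    values require ``enforce_half_length=False``).
    """
    L = profile.transect_length
    if lag_step <= 0 or lag_step > (profile.distance[-1] - profile.distance[0]):
        raise ValueError("lag_step must be positive and smaller than the profile extent")
    if max_lag is None:
        max_lag = L / 2.0
    elif enforce_half_length and max_lag > L / 2.0:
        raise ValueError("max_lag beyond L/2; pass enforce_half_length=False to override")
    uni = resample_uniform(profile, lag_step)
    y = uni.depth
    kmax = int(np.floor(max_lag / lag_step + 1e-9))
    kmax = min(kmax, len(y) - 1)
    lags = np.arange(1, kmax + 1) * lag_step
    gamma = np.empty(kmax)
    counts = np.empty(kmax, dtype=int)
    for k in range(1, kmax + 1):
        diffs = y[:-k] - y[k:]
        counts[k - 1] = len(diffs)
        gamma[k - 1] = np.sum(diffs * diffs) / (2.0 * len(diffs))
    return Semivariogram(lags=lags, gamma=gamma, pair_counts=counts, max_lag=max_lag)


def rugosity_density(values_by_group: dict, bandwidth_rule: str = "silverman",
                     grid_size: int = 512):
    """Gaussian-kernel density of DRR values per reef type.

    Returns {group: (grid, density)}; each density integrates to ~1 over its
    grid.  Requires at least 2 values per group.
    """
    out = {}
    for group, values in values_by_group.items():
        v = np.asarray(values, dtype=float)
        if len(v) < 2:
            raise ValueError(f"group {group!r} needs >= 2 values for a density")
        kde = stats.gaussian_kde(v, bw_method=bandwidth_rule)
        pad = 3.0 * v.std(ddof=1) if v.std(ddof=1) > 0 else 1.0
        grid = np.linspace(v.min() - pad, v.max() + pad, grid_size)
        out[group] = (grid, kde(grid))
    return out


def metric_correlation(metric_a, metric_b) -> float:
    """Pearson correlation between two per-transect metric series."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need equal-length series with at least 3 values")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a metric series")
    return float(stats.pearsonr(a, b)[0])


# ---------------------------------------------------------------------------
# delimited-text IO

def write_metrics_csv(rows: list[dict], path) -> None:
    """Write per-transect metrics (site, season, transect + ComplexityMetrics)."""
    records = []
    for r in rows:
        m: ComplexityMetrics = r["metrics"]
        records.append({
            "site": r["site"], "season": r["season"], "transect": r["transect"],
            "drr_m": m.drr, "c": m.c, "relief_m": m.vertical_relief,
            "depth_mean_m": m.depth_mean, "depth_min_m": m.depth_min,
            "depth_max_m": m.depth_max,
        })
    pd.DataFrame(records).to_csv(path, index=False)


def write_variogram_csv(vg: Semivariogram, path) -> None:
    pd.DataFrame({"lag_m": vg.lags, "gamma_m2": vg.gamma,
                  "n_pairs": vg.pair_counts}).to_csv(path, index=False)
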