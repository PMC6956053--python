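"""Variance-based single-changepoint statistics.

The colonization monitor reduces every raw electrochemical record (a cyclic
voltammogram of M current values, an impedance spectrum of M |Z| or phase
values) to one number per acquisition: the unbiased variance of the M values.
The resulting variance-vs-time series is min-max normalized and scanned for a
single step change by minimizing the segment-length-weighted log variance
cost

    J(k) = (k-1) * log var(V_1..V_{k-1}) + (n-k+1) * log var(V_k..V_n)

over admissible split indices k (1-based, each segment >= 2 points).  The
variance inside J is the population (maximum-likelihood) variance; the
per-sample signal variance uses the unbiased 1/(M-1) estimator.

A change ratio R = mean(x_k..x_n) / mean(x_1..x_{k-1}) quantifies whether the
detected step reflects a large or a small change.  Because normalization maps
every series onto [0, 1] regardless of its physical scale, R is computed on
the raw variance series by default so that a quiet control run yields R near
1 while a colonization event yields R far from 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SampleSeries",
    "VarianceSeries",
    "ChangepointResult",
    "sample_mean",
    "sample_variance",
    "normalize_series",
    "single_changepoint",
    "change_ratio",
    "variance_pipeline",
]

#: floor applied to segment variances before taking the logarithm, so that
#: noiseless (piecewise-constant) series remain well defined
VARIANCE_FLOOR = 1e-12


@dataclass
class SampleSeries:
    """Ordered collection of n measurement vectors with timestamps."""

    samples: list[np.ndarray]
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.samples = [np.asarray(s, dtype=float) for s in self.samples]
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.samples) < 2:
            raise ValueError("SampleSeries needs at least 2 samples")
        if any(s.size < 2 for s in self.samples):
            raise ValueError("every sample needs at least 2 values")
        if len(self.samples) != self.timestamps.size:
            raise ValueError("one timestamp per sample required")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class VarianceSeries:
    """Per-sample variance and its min-max normalization."""

    sigma2: np.ndarray
    normalized: np.ndarray
    timestamps: np.ndarray
    degenerate: bool = False


@dataclass
class ChangepointResult:
    """Detected single step: 1-based index k, cost profile and change ratio."""

    k: int
    time_s: float
    objective: np.ndarray            # J(k) for admissible k (see k_grid)
    change_ratio: float
    k_grid: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    no_split_cost: float = float("nan")
    degenerate: bool = False

    @property
    def improvement(self) -> float:
        """Cost decrease of the best split vs. no split at all."""
        if self.degenerate or self.objective.size == 0:
            return 0.0
        return float(self.no_split_cost - np.min(self.objective))


def sample_mean(x) -> float:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty vector")
    return float(np.mean(x))


def sample_variance(x) -> float:
    """Unbiased variance of one measurement vector (1/(M-1) denominator)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("variance needs at least 2 values")
    return float(np.var(x, ddof=1))


def normalize_series(sigma2) -> tuple[np.ndarray, bool]:
    """Min-max normalize a variance series to [0, 1].

    Returns ``(normalized, degenerate)``; a constant series maps to all
    zeros with the degenerate flag set.
    """
    s = np.asarray(sigma2, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 values to normalize")
    lo, hi = float(np.min(s)), float(np.max(s))
    if hi == lo:
        return np.zeros_like(s), True
    return (s - lo) / (hi - lo), False


def _segment_cost(v: np.ndarray) -> float:
    # population variance, floored before the log
    var = max(float(np.var(v)), VARIANCE_FLOOR)
    return len(v) * np.log(var)


def single_changepoint(V, timestamps=None) -> ChangepointResult:
    """Locate the single step change of a series by the log-variance cost.

    ``k`` is 1-based: the pre segment is V_1..V_{k-1} and the post segment
    V_k..V_n, each required to hold at least two points, so k ranges over
    [3, n-1].  Ties are broken toward the smallest k (earliest event).
    """
    V = np.asarray(V, dtype=float)
    n = V.size
    if n < 4:
        raise ValueError("changepoint detection needs at least 4 points")
    k_grid = np.arange(3, n)          # 1-based k in [3, n-1]
    J = np.array([
        _segment_cost(V[: k - 1]) + _segment_cost(V[k - 1:]) for k in k_grid
    ])
    k = int(k_grid[int(np.argmin(J))])
    no_split = _segment_cost(V)
    t = float(timestamps[k - 1]) if timestamps is not None else float(k)
    return ChangepointResult(
        k=k, time_s=t, objective=J, change_ratio=float("nan"),
        k_grid=k_grid, no_split_cost=no_split,
    )


def change_ratio(x, k: int) -> float:
    """Ratio of the post-segment mean (x_k..x_n) to the pre-segment mean."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if not 2 <= k <= n:
        raise ValueError(f"k={k} outside [2, {n}]")
    pre = float(np.mean(x[: k - 1]))
    if pre == 0.0:
        raise ValueError("pre-segment mean is zero")
    return float(np.mean(x[k - 1:])) / pre


def variance_pipeline(
    series: SampleSeries, *, ratio_on: str = "raw"
) -> tuple[VarianceSeries, ChangepointResult]:
    """Full variance analysis of one acquisition series.

    Computes the per-sample unbiased variance, normalizes it, detects the
    single changepoint on the normalized series and attaches the change
    ratio.  ``ratio_on`` selects whether R is evaluated on the raw variance
    series (default, scale-bearing) or on the normalized one.
    """
    sigma2 = np.array([sample_variance(s) for s in series.samples])
    normalized, degenerate = normalize_series(sigma2)
    vs = VarianceSeries(sigma2=sigma2, normalized=normalized,
                        timestamps=series.timestamps, degenerate=degenerate)
    if degenerate:
        cp = ChangepointResult(
            k=0, time_s=float("nan"), objective=np.array([]),
            change_ratio=1.0, degenerate=True,
        )
        return vs, cp
    cp = single_changepoint(normalized, timestamps=series.timestamps)
    target = sigma2 if ratio_on == "raw" else normalized
    cp.change_ratio = change_ratio(target, cp.k)
    return vs, cp
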