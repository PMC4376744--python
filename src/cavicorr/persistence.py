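"""Moving-window correlation traces and persistence statistics.

For long trajectories, couplings are not summarized by a single
whole-trajectory test: a window slides along the series and the MI
correlation is recomputed inside each window, giving a correlation-vs-time
trace per cavity pair.  The persistence statistic f_ij is the fraction of
window positions at which the pair's correlation exceeds a threshold
(defaults 0.25 and 0.5, the midpoints of the [0, 1] correlation range).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cavities import Cavity, are_neighbours
from .coupling import MIN_SERIES_LENGTH, mi_correlation
from .errors import ConsistencyError, ParameterError

__all__ = [
    "WindowTrace",
    "PersistenceRecord",
    "windowed_correlations",
    "persistence_fraction",
    "persistence_histogram",
    "neighbour_split",
    "window_size_sensitivity",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_WINDOW",
]

DEFAULT_WINDOW = 100  # snapshots (20 ns at 200 ps sampling)
DEFAULT_STRIDE = 1
DEFAULT_THRESHOLDS = (0.25, 0.5)


@dataclass(frozen=True)
class WindowTrace:
    """Windowed correlation values for one cavity pair."""

    pair: tuple[str, str]
    window: int
    stride: int
    values: np.ndarray
    starts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "starts", np.asarray(self.starts, dtype=int))


@dataclass(frozen=True)
class PersistenceRecord:
    """Fraction of window positions above a correlation threshold."""

    pair: tuple[str, str]
    threshold: float
    f: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise ParameterError("persistence fraction must lie in [0, 1]")


def windowed_correlations(
    x,
    y,
    window: int = DEFAULT_WINDOW,
    stride: int = DEFAULT_STRIDE,
    pair: tuple[str, str] = ("i", "j"),
    statistic: Callable[[np.ndarray, np.ndarray], float] = mi_correlation,
) -> WindowTrace:
    """Correlation of two series inside every window position.

    Positions start at 0, window, ... by ``stride``; the number of positions
    is floor((n - window) / stride) + 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("series must be 1-D and of equal length")
    n = x.size
    if window > n:
        raise ParameterError(f"window ({window}) exceeds series length ({n})")
    if window < MIN_SERIES_LENGTH:
        raise ParameterError(f"window must be >= {MIN_SERIES_LENGTH} snapshots")
    if stride < 1:
        raise ParameterError("stride must be >= 1")
    starts = np.arange(0, n - window + 1, stride)
    values = np.array(
        [statistic(x[s : s + window], y[s : s + window]) for s in starts]
    )
    return WindowTrace(tuple(pair), window, stride, values, starts)


def persistence_fraction(trace: WindowTrace, threshold: float) -> PersistenceRecord:
    """f = fraction of window positions with correlation strictly above
    ``threshold`` (thresholds are exceeded, not met)."""
    if not (0.0 < threshold < 1.0):
        raise ParameterError("threshold must lie in (0, 1)")
    if trace.values.size == 0:
        raise ParameterError("empty window trace")
    f = float(np.mean(trace.values > threshold))
    return PersistenceRecord(trace.pair, threshold, f)


def persistence_histogram(
    records: Sequence[PersistenceRecord], bins: int | Sequence[float] = 10
) -> pd.DataFrame:
    """Normalized frequency histogram of f values over [0, 1]; sums to 1."""
    if len(records) == 0:
        raise ParameterError("no persistence records")
    f = np.array([r.f for r in records])
    edges = (
        np.linspace(0.0, 1.0, bins + 1) if np.isscalar(bins) else np.asarray(bins)
    )
    counts, edges = np.histogram(f, bins=edges)
    freq = counts / counts.sum()
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "frequency": freq,
        }
    )


def neighbour_split(
    records: Sequence[PersistenceRecord], cavities: Mapping[str, Cavity]
) -> tuple[list[PersistenceRecord], list[PersistenceRecord]]:
    """Partition persistence records into (neighbour, non-neighbour) pairs."""
    neigh, non = [], []
    for rec in records:
        a, b = rec.pair
        if a not in cavities or b not in cavities:
            raise ConsistencyError(f"unknown cavity id in pair {rec.pair}")
        (neigh if are_neighbours(cavities[a], cavities[b]) else non).append(rec)
    return neigh, non


def window_size_sensitivity(
    x,
    y,
    sizes: Sequence[int] = (20, 30, 40, 50),
    stride: int = DEFAULT_STRIDE,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    pair: tuple[str, str] = ("i", "j"),
) -> pd.DataFrame:
    """Report f at each threshold across window sizes (descriptive harness;
    similarity across sizes is reported, not asserted)."""
    rows = []
    for size in sizes:
        trace = windowed_correlations(x, y, window=size, stride=stride, pair=pair)
        for thr in thresholds:
            rec = persistence_fraction(trace, thr)
            rows.append((size, thr, rec.f, len(trace.values)))
    return pd.DataFrame(rows, columns=["window", "threshold", "f", "n_positions"])
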