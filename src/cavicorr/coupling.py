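"""Cavity-pair coupling statistics.

The association measure is a normalized mutual-information correlation:
each crmsd series is discretized into B equal-frequency (rank) bins, the
plug-in mutual information I and the marginal entropies H(X), H(Y) are
computed from the joint histogram, and

    r = I / sqrt(H(X) * H(Y))          with r in [0, 1].

r is 0 for independent series and exactly 1 when one series is a strictly
monotone transform of the other (rank binning makes r invariant to any
strictly monotone rescaling).  Significance comes from a permutation null:
because rank binning maps every non-degenerate series of length n onto the
same multiset of bin labels, the null distribution of r depends only on
(n, B) and can be generated once and shared across all pairs of equal
length.  P-values use the add-one estimator and are adjusted per protein
and replica by the Benjamini–Hochberg step-up procedure.

A cavity pair is a *CSC* (cavity pair with significant correlation) when
its adjusted p-value is at or below alpha in both simulation replicas; with
a single trajectory the replica filter is skipped and the results flagged.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConsistencyError, DegeneracyError, ParameterError

__all__ = [
    "CouplingResult",
    "CSC",
    "NullDistribution",
    "n_bins_for",
    "rank_bins",
    "mi_correlation",
    "pearson_correlation",
    "abs_pearson",
    "permutation_pvalue",
    "null_distribution",
    "fdr_adjust",
    "analyze_pairs",
    "identify_cscs",
    "cavity_ca_correlation",
    "compare_correlation_distributions",
]

MIN_SERIES_LENGTH = 20
DEFAULT_N_PERM = 100_000
DEFAULT_ALPHA = 0.05


def n_bins_for(n: int) -> int:
    """Equal-frequency bin count B = max(2, floor(sqrt(n/5))); 4 at n = 100."""
    return max(2, int(np.sqrt(n / 5.0)))


def rank_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value to one of ``n_bins`` equal-frequency bins by rank.

    Ties are broken by original index (stable sort), so the assignment is
    deterministic and the label multiset depends only on (n, B).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    order = np.argsort(x, kind="stable")
    labels = np.empty(n, dtype=np.intp)
    labels[order] = (np.arange(n) * n_bins) // n
    return labels


def _mi_r_from_labels(bx: np.ndarray, by: np.ndarray, n_bins: int) -> float:
    """Normalized MI correlation from two label vectors (plug-in, nats)."""
    n = bx.size
    joint = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins).astype(float)
    joint /= n
    px = joint.reshape(n_bins, n_bins).sum(axis=1)
    py = joint.reshape(n_bins, n_bins).sum(axis=0)
    nz = joint > 0
    hx = -np.sum(px[px > 0] * np.log(px[px > 0]))
    hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
    if hx <= 0 or hy <= 0:
        warnings.warn("constant series: MI correlation defined as 0", stacklevel=3)
        return 0.0
    if np.array_equal(bx, by):
        return 1.0  # I = H(X) = H(Y) exactly; avoid round-off below 1
    outer = np.outer(px, py).ravel()
    mi = np.sum(joint[nz] * (np.log(joint[nz]) - np.log(outer[nz])))
    r = mi / np.sqrt(hx * hy)
    return float(min(max(r, 0.0), 1.0))


def mi_correlation(x, y, n_bins: int | None = None) -> float:
    """Mutual-information-based correlation of two equal-length series.

    Returns r in [0, 1]; r(x, x) = 1 for any non-constant x.  Series must
    have length >= 20.  A constant series has zero entropy and yields r = 0
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("series must be 1-D and of equal length")
    if x.size < MIN_SERIES_LENGTH:
        raise ParameterError(f"series length must be >= {MIN_SERIES_LENGTH}")
    B = n_bins_for(x.size) if n_bins is None else int(n_bins)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant series: MI correlation defined as 0", stacklevel=2)
        return 0.0
    return _mi_r_from_labels(rank_bins(x, B), rank_bins(y, B), B)


def pearson_correlation(x, y) -> float:
    """Product-moment correlation in [-1, 1]; zero variance is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ParameterError("series must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegeneracyError("Pearson correlation undefined for constant series")
    return float(stats.pearsonr(x, y).statistic)


def abs_pearson(x, y) -> float:
    """|Pearson r| — drop-in [0, 1] statistic for the permutation machinery."""
    return abs(pearson_correlation(x, y))


@dataclass(frozen=True)
class NullDistribution:
    """Empirical null of the MI correlation under independence.

    Built once per (series length, bin count): rank binning maps any
    non-degenerate series onto the same label multiset, so shuffling labels
    reproduces the per-pair permutation null exactly (up to Monte-Carlo
    error) for every pair of that length.
    """

    n: int
    n_bins: int
    values: np.ndarray  # sorted, ascending
    seed: int | None = None

    @property
    def n_perm(self) -> int:
        return len(self.values)

    def pvalue(self, r_observed: float) -> float:
        """Add-one permutation p-value: (1 + #{r_null >= r_obs}) / (1 + n_perm)."""
        n_ge = len(self.values) - np.searchsorted(
            self.values, r_observed - 1e-12, side="left"
        )
        return float((1 + n_ge) / (1 + len(self.values)))


def null_distribution(
    n: int,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator | None = None,
    n_bins: int | None = None,
) -> NullDistribution:
    """Simulate the null distribution of the MI correlation for length-n series."""
    if n_perm < 99:
        raise ParameterError("n_perm must be >= 99")
    B = n_bins_for(n) if n_bins is None else int(n_bins)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    base = (np.arange(n) * B) // n  # the fixed label multiset
    fixed = base.copy()
    values = np.empty(n_perm)
    for i in range(n_perm):
        values[i] = _mi_r_from_labels(fixed, rng.permutation(base), B)
    values.sort()
    return NullDistribution(n, B, values, seed if isinstance(seed, int) else None)


def permutation_pvalue(
    x,
    y,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator | None = None,
    statistic: Callable[[np.ndarray, np.ndarray], float] = mi_correlation,
    null: NullDistribution | None = None,
) -> float:
    """Permutation p-value of the observed association.

    The order of ``y`` is shuffled with ``x`` fixed; the p-value uses the
    add-one estimator (never exactly 0).  For the rank-binned MI statistic a
    precomputed shared :class:`NullDistribution` may be supplied instead of
    re-permuting per pair.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs = statistic(x, y)
    if null is not None:
        if null.n != x.size:
            raise ConsistencyError(
                f"null distribution is for n={null.n}, series have n={x.size}"
            )
        return null.pvalue(r_obs)
    if n_perm < 99:
        raise ParameterError("n_perm must be >= 99")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_ge = 0
    for _ in range(n_perm):
        if statistic(x, rng.permutation(y)) >= r_obs - 1e-12:
            n_ge += 1
    return (1 + n_ge) / (1 + n_perm)


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-aligned with input."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ParameterError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class CouplingResult:
    """Correlation of one cavity pair in one replica."""

    pair: tuple[str, str]
    r: float
    p: float
    p_adj: float
    replica_id: str = "r1"

    def __post_init__(self) -> None:
        a, b = self.pair
        object.__setattr__(self, "pair", tuple(sorted((a, b))))
        if not (-1e-12 <= self.r <= 1 + 1e-12):
            raise ParameterError(f"r={self.r} outside [0, 1]")
        if not (0 < self.p <= 1):
            raise ParameterError("p must lie in (0, 1]")
        if self.p_adj < self.p - 1e-12:
            raise ParameterError("adjusted p cannot be below raw p")


@dataclass(frozen=True)
class CSC:
    """A cavity pair with significant correlation (after all filters)."""

    pair: tuple[str, str]
    results: tuple[CouplingResult, ...]  # one per replica
    single_replica: bool = False
    neighbour: bool | None = None
    shared_pct: float | None = None
    distance: float | None = None
    ca_class: int | None = None  # 0, 1 or 2 member cavities Ca-correlated

    @property
    def mean_r(self) -> float:
        return float(np.mean([res.r for res in self.results]))


def analyze_pairs(
    series_by_id: Mapping[str, np.ndarray],
    replica_id: str = "r1",
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator | None = None,
    statistic: Callable[[np.ndarray, np.ndarray], float] = mi_correlation,
    null: NullDistribution | None = None,
) -> list[CouplingResult]:
    """Correlation, permutation p and BH-adjusted p for every cavity pair.

    For the MI statistic a shared null is built once (unless supplied);
    other statistics fall back to per-pair permutation.  The FDR family is
    all pairs of one protein in one replica.
    """
    ids = sorted(series_by_id)
    if len(ids) < 2:
        raise ParameterError("need at least two series")
    lengths = {len(series_by_id[i]) for i in ids}
    if len(lengths) != 1:
        raise ConsistencyError("all series must have equal length")
    (n,) = lengths
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if null is None and statistic is mi_correlation:
        null = null_distribution(n, n_perm, rng)
    pairs = list(itertools.combinations(ids, 2))
    rs, ps = [], []
    for a, b in pairs:
        x, y = np.asarray(series_by_id[a], float), np.asarray(series_by_id[b], float)
        rs.append(statistic(x, y))
        ps.append(
            permutation_pvalue(x, y, n_perm, rng, statistic=statistic, null=null)
        )
    p_adj = fdr_adjust(ps)
    return [
        CouplingResult(pair, r, p, pa, replica_id)
        for pair, r, p, pa in zip(pairs, rs, ps, p_adj)
    ]


def identify_cscs(
    replica1: Sequence[CouplingResult],
    replica2: Sequence[CouplingResult] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> list[CSC]:
    """Apply the significance and replica-conservation filters.

    A pair is a CSC iff its BH-adjusted p-value is <= alpha in *both*
    replicas.  In single-trajectory mode (``replica2 is None``) the replica
    filter is skipped and each CSC is flagged ``single_replica``.
    """
    by_pair1 = {res.pair: res for res in replica1}
    if replica2 is None:
        return [
            CSC(pair, (res,), single_replica=True)
            for pair, res in sorted(by_pair1.items())
            if res.p_adj <= alpha
        ]
    by_pair2 = {res.pair: res for res in replica2}
    if set(by_pair1) != set(by_pair2):
        raise ConsistencyError("replicas were not analysed over the same cavity pairs")
    return [
        CSC(pair, (by_pair1[pair], by_pair2[pair]))
        for pair in sorted(by_pair1)
        if by_pair1[pair].p_adj <= alpha and by_pair2[pair].p_adj <= alpha
    ]


def cavity_ca_correlation(
    cavity_values: np.ndarray,
    ca_values: np.ndarray,
    null: NullDistribution | None = None,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator | None = None,
) -> tuple[bool, float, float]:
    """Is a cavity's shape series significantly coupled to the Cα trace?

    Returns (significant, r, p).  Used to classify CSCs by how many member
    cavities move with the global backbone (class 0, 1 or 2).
    """
    r = mi_correlation(cavity_values, ca_values)
    p = permutation_pvalue(cavity_values, ca_values, n_perm, seed, null=null)
    return p <= alpha, r, p


def compare_correlation_distributions(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov comparison of two sets of correlations."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)
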