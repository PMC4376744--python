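"""End-to-end orchestration: series → couplings → attribution → reports.

The stages mirror how the analysis is run on real data: cavity crmsd
series are computed per replica, every cavity pair is tested with the
MI-based correlation and a permutation null, p-values are BH-adjusted per
replica, pairs significant in both replicas become CSCs, and each CSC is
annotated with neighbourhood, shared-atom percentage, centroid distance on
the reference structure, and how many member cavities track the Cα trace.
Runs are deterministic for a fixed seed and config.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cavities import (
    Cavity,
    are_neighbours,
    cavity_distance,
    shared_atom_percentage,
)
from .conservation import EquivalenceMap, conserved_cscs, conserved_report, map_equivalent_cavities
from .coupling import (
    CSC,
    CouplingResult,
    NullDistribution,
    abs_pearson,
    analyze_pairs,
    identify_cscs,
    mi_correlation,
    null_distribution,
    permutation_pvalue,
)
from .errors import ParameterError
from .persistence import (
    DEFAULT_THRESHOLDS,
    PersistenceRecord,
    neighbour_split,
    persistence_fraction,
    persistence_histogram,
    windowed_correlations,
)
from .shape import ca_trace_crmsd_series, cavity_crmsd_series
from .structure_io import Trajectory

__all__ = [
    "RunConfig",
    "load_config",
    "provenance_header",
    "compute_series",
    "run_csc",
    "run_persistence",
    "run_conservation",
    "CscRun",
]

logger = logging.getLogger("cavicorr")

_STATISTICS = {"mi": mi_correlation, "pearson": abs_pearson}


@dataclass(frozen=True)
class RunConfig:
    """Tunable analysis parameters (defaults follow the reference protocol)."""

    interval: float = 200.0  # ps between analysed snapshots
    alpha: float = 0.05  # FDR-adjusted significance cut-off
    n_perm: int = 100_000  # permutation samples for the null
    window: int = 100  # snapshots per moving window (20 ns at 200 ps)
    stride: int = 1  # snapshots between window positions
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    statistic: str = "mi"  # "mi" or "pearson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.statistic not in _STATISTICS:
            raise ParameterError(f"unknown statistic {self.statistic!r}")

    @property
    def statistic_fn(self):
        return _STATISTICS[self.statistic]


def load_config(path: str | Path) -> RunConfig:
    """Read a plain ``key = value`` config file; unknown keys are an error."""
    values: dict[str, object] = {}
    fields = {f: t for f, t in RunConfig.__annotations__.items()}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in fields:
            raise ParameterError(f"unknown config key {key!r}")
        if key == "thresholds":
            values[key] = tuple(float(v) for v in val.split(","))
        elif key == "statistic":
            values[key] = val
        elif key in {"n_perm", "window", "stride", "seed"}:
            values[key] = int(val)
        else:
            values[key] = float(val)
    return RunConfig(**values)


def provenance_header(config: RunConfig) -> str:
    """Comment block recording config hash, seed and version (no timestamps,
    so identical runs produce byte-identical outputs)."""
    blob = repr(sorted(asdict(config).items())).encode()
    digest = hashlib.sha256(blob).hexdigest()[:12]
    return (
        f"# cavicorr {__version__}\n"
        f"# config_sha256 {digest}\n"
        f"# seed {config.seed}\n"
    )


def compute_series(
    traj: Trajectory, cavs: Sequence[Cavity]
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-cavity crmsd series plus the Cα-trace series for one trajectory."""
    series = {c.cavity_id: cavity_crmsd_series(traj, c).values for c in cavs}
    ca = ca_trace_crmsd_series(traj).values
    return series, ca


@dataclass(frozen=True)
class CscRun:
    """Everything produced by one CSC analysis."""

    per_replica: tuple[tuple[CouplingResult, ...], ...]
    cscs: tuple[CSC, ...]
    table: pd.DataFrame  # one row per pair per replica, annotated
    config: RunConfig


def _ca_significant(
    series: Mapping[str, np.ndarray],
    ca: np.ndarray,
    null: NullDistribution,
    alpha: float,
) -> dict[str, bool]:
    out = {}
    for cid, values in series.items():
        p = permutation_pvalue(values, ca, null=null)
        out[cid] = p <= alpha
    return out


def run_csc(
    trajectories: Sequence[Trajectory],
    cavs: Sequence[Cavity],
    config: RunConfig = RunConfig(),
) -> CscRun:
    """The three-step coupling protocol over one or two replica trajectories.

    Steps: (1) MI correlation and permutation p-value for every cavity pair
    in every replica; (2) BH adjustment per replica, discard pairs with
    adjusted p above alpha; (3) keep only pairs significant in both
    replicas (skipped, and flagged, in single-trajectory mode).  CSCs are
    then annotated structurally.
    """
    if not 1 <= len(trajectories) <= 2:
        raise ParameterError("provide one or two replica trajectories")
    if len(cavs) < 2:
        raise ParameterError("need at least two cavities")
    rng = np.random.default_rng(config.seed)
    statistic = config.statistic_fn

    replica_results: list[list[CouplingResult]] = []
    ca_flags: list[dict[str, bool]] = []
    shared_null: NullDistribution | None = None
    for traj in trajectories:
        series, ca = compute_series(traj, cavs)
        n = len(ca)
        if shared_null is None and statistic is mi_correlation:
            shared_null = null_distribution(n, config.n_perm, rng)
        results = analyze_pairs(
            series,
            replica_id=traj.replica_id,
            n_perm=config.n_perm,
            seed=rng,
            statistic=statistic,
            null=shared_null,
        )
        n_sig = sum(res.p_adj <= config.alpha for res in results)
        logger.info(
            "replica %s: %d pairs tested, %d significant at adjusted p <= %g",
            traj.replica_id, len(results), n_sig, config.alpha,
        )
        replica_results.append(results)
        if statistic is mi_correlation:
            ca_flags.append(_ca_significant(series, ca, shared_null, config.alpha))
        else:
            ca_flags.append(
                {
                    cid: permutation_pvalue(
                        vals, ca, config.n_perm, rng, statistic=statistic
                    )
                    <= config.alpha
                    for cid, vals in series.items()
                }
            )

    if len(trajectories) == 2:
        cscs = identify_cscs(replica_results[0], replica_results[1], config.alpha)
    else:
        cscs = identify_cscs(replica_results[0], None, config.alpha)
    logger.info(
        "%d CSC(s) after the replica-conservation filter", len(cscs)
    )

    cav_by_id = {c.cavity_id: c for c in cavs}
    reference = trajectories[0].reference
    # a member cavity counts as Ca-correlated when significant in every replica
    ca_all = {
        cid: all(flags[cid] for flags in ca_flags) for cid in cav_by_id
    }
    annotated = []
    for csc in cscs:
        a, b = csc.pair
        annotated.append(
            CSC(
                csc.pair,
                csc.results,
                single_replica=csc.single_replica,
                neighbour=are_neighbours(cav_by_id[a], cav_by_id[b]),
                shared_pct=shared_atom_percentage(cav_by_id[a], cav_by_id[b]),
                distance=cavity_distance(cav_by_id[a], cav_by_id[b], reference),
                ca_class=int(ca_all[a]) + int(ca_all[b]),
            )
        )

    csc_pairs = {c.pair for c in annotated}
    rows = []
    for results in replica_results:
        for res in results:
            a, b = res.pair
            rows.append(
                (
                    res.replica_id, a, b, res.r, res.p, res.p_adj,
                    are_neighbours(cav_by_id[a], cav_by_id[b]),
                    shared_atom_percentage(cav_by_id[a], cav_by_id[b]),
                    cavity_distance(cav_by_id[a], cav_by_id[b], reference),
                    int(ca_all[a]) + int(ca_all[b]),
                    res.pair in csc_pairs,
                )
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "replica", "cavity_i", "cavity_j", "r", "p", "p_adj",
            "neighbour", "shared_pct", "distance_A", "ca_class", "is_csc",
        ],
    )
    return CscRun(
        tuple(tuple(r) for r in replica_results), tuple(annotated), table, config
    )


@dataclass(frozen=True)
class PersistenceRun:
    traces: pd.DataFrame
    records: tuple[PersistenceRecord, ...]
    histograms: dict[float, pd.DataFrame]
    split_histograms: dict[tuple[float, str], pd.DataFrame] = field(default_factory=dict)


def run_persistence(
    traj: Trajectory,
    cavs: Sequence[Cavity],
    config: RunConfig = RunConfig(),
) -> PersistenceRun:
    """Moving-window correlation traces, f values per threshold, histograms
    and the neighbour / non-neighbour split."""
    series, _ = compute_series(traj, cavs)
    ids = sorted(series)
    trace_rows = []
    records: list[PersistenceRecord] = []
    cav_by_id = {c.cavity_id: c for c in cavs}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            trace = windowed_correlations(
                series[a], series[b],
                window=config.window, stride=config.stride, pair=(a, b),
                statistic=config.statistic_fn,
            )
            for start, r in zip(trace.starts, trace.values):
                trace_rows.append((a, b, int(start), r))
            for thr in config.thresholds:
                records.append(persistence_fraction(trace, thr))
    traces = pd.DataFrame(
        trace_rows, columns=["cavity_i", "cavity_j", "window_start", "r"]
    )
    histograms = {}
    split_histograms = {}
    for thr in config.thresholds:
        recs = [r for r in records if r.threshold == thr]
        histograms[thr] = persistence_histogram(recs)
        neigh, non = neighbour_split(recs, cav_by_id)
        if neigh:
            split_histograms[(thr, "neighbour")] = persistence_histogram(neigh)
        if non:
            split_histograms[(thr, "non-neighbour")] = persistence_histogram(non)
    logger.info(
        "persistence: %d pairs, window %d, stride %d",
        len(ids) * (len(ids) - 1) // 2, config.window, config.stride,
    )
    return PersistenceRun(traces, tuple(records), histograms, split_histograms)


def run_conservation(
    cscs_a: Sequence[CSC],
    cscs_b: Sequence[CSC],
    cavs_a: Sequence[Cavity],
    cavs_b: Sequence[Cavity],
    emap: EquivalenceMap,
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Match cavities between two structures and report conserved CSCs."""
    cavity_map = map_equivalent_cavities(cavs_a, cavs_b, emap)
    logger.info("%d equivalent cavity pairs mapped", len(cavity_map))
    conserved = conserved_cscs(cscs_a, cscs_b, cavity_map)
    logger.info("%d conserved CSC(s)", len(conserved))
    return conserved_report(
        conserved,
        {c.cavity_id: c for c in cavs_a},
        {c.cavity_id: c for c in cavs_b},
        label_a, label_b,
    )
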