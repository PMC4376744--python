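"""Rigid superposition and the crmsd shape descriptor.

crmsd (coordinate root-mean-square deviation) is computed after optimal
least-squares superposition with the Kabsch algorithm:

    crmsd = sqrt( (1/N) * sum_j d_j^2 )

where N is the number of superposed atom pairs and d_j the post-fit distance
between atom j and its reference partner.  For a cavity the superposition
uses only that cavity's lining atoms (local fit); for the backbone the full
Cα trace is used.  Each trajectory snapshot is superposed onto the relaxed
reference conformation, giving one crmsd series per subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .cavities import Cavity
from .errors import DegeneracyError
from .structure_io import Trajectory

__all__ = [
    "CrmsdSeries",
    "kabsch_superpose",
    "crmsd",
    "crmsd_series",
    "cavity_crmsd_series",
    "ca_trace_crmsd_series",
    "write_series_tsv",
]

CA_TRACE_ID = "CA-trace"


@dataclass(frozen=True)
class CrmsdSeries:
    """Per-snapshot crmsd of one atom set against its reference conformation."""

    subject_id: str
    values: np.ndarray  # Å, one per snapshot
    n_atoms: int  # number of superposed atom pairs
    times: np.ndarray | None = None  # ps

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if self.n_atoms < 3:
            raise DegeneracyError("crmsd requires at least 3 superposed atoms")
        if (values < -1e-12).any():
            raise ValueError("crmsd values must be >= 0")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


def _as_points(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 3:
        raise DegeneracyError("need an (N, 3) array with N >= 3 points")
    return X


def kabsch_superpose(X, Y) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rigid transform mapping point set X onto Y.

    Returns ``(R, t)`` with ``det(R) = +1`` such that ``X @ R.T + t``
    minimizes the summed squared distance to Y over all rotations and
    translations (correspondence is positional).  Reflections are corrected
    by flipping the smallest singular direction.
    """
    X, Y = _as_points(X), _as_points(Y)
    if X.shape != Y.shape:
        raise DegeneracyError("point sets must have equal size")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    H = (X - xc).T @ (Y - yc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    return R, t


def crmsd(X, Y) -> float:
    """crmsd between two corresponded point sets after optimal superposition."""
    return float(crmsd_series(_as_points(X), _as_points(Y)[None, :, :])[0])


def crmsd_series(ref: np.ndarray, frames: np.ndarray) -> np.ndarray:
    """crmsd of every frame against ``ref``, via batched Kabsch.

    ``ref`` is (N, 3); ``frames`` is (M, N, 3).  Uses the trace identity
    rmsd² = (|Xc|² + |Yc|² − 2·Σσ̃) / N with the reflection-corrected
    singular values σ̃ of the cross-covariance, which avoids building the
    rotation matrices explicitly.
    """
    ref = _as_points(ref)
    frames = np.asarray(frames, dtype=float)
    n = ref.shape[0]
    ref_c = ref - ref.mean(axis=0)
    frames_c = frames - frames.mean(axis=1, keepdims=True)
    H = np.einsum("mni,nj->mij", frames_c, ref_c)  # (M, 3, 3)
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(U) * np.linalg.det(Vt)
    S_adj = S.copy()
    S_adj[:, -1] *= np.sign(det)  # reflection correction on smallest σ
    sq = (
        (ref_c**2).sum()
        + (frames_c**2).sum(axis=(1, 2))
        - 2.0 * S_adj.sum(axis=1)
    ) / n
    return np.sqrt(np.maximum(sq, 0.0))


def cavity_crmsd_series(traj: Trajectory, cav: Cavity) -> CrmsdSeries:
    """crmsd of one cavity per snapshot, superposing on its own lining atoms.

    The reference conformation of the same atoms is the fixed target; the
    fit is cavity-local, so only the cavity's shape change is measured, not
    its rigid displacement within the protein.
    """
    keys = sorted(cav.atoms)
    ref = traj.reference.coords_for(keys)
    frames = traj.coords_for(keys)
    values = crmsd_series(ref, frames)
    times = np.array([s.time for s in traj.snapshots])
    return CrmsdSeries(cav.cavity_id, values, len(keys), times)


def ca_trace_crmsd_series(traj: Trajectory) -> CrmsdSeries:
    """crmsd of the full Cα trace per snapshot (global backbone descriptor)."""
    keys = sorted(traj.reference.ca_keys())
    if len(keys) < 3:
        raise DegeneracyError("fewer than 3 Cα atoms in the reference structure")
    ref = traj.reference.coords_for(keys)
    frames = traj.coords_for(keys)
    values = crmsd_series(ref, frames)
    times = np.array([s.time for s in traj.snapshots])
    return CrmsdSeries(CA_TRACE_ID, values, len(keys), times)


def write_series_tsv(series: CrmsdSeries, path: str | Path) -> None:
    times = (
        series.times
        if series.times is not None
        else np.full(len(series), np.nan)
    )
    pd.DataFrame(
        {
            "snapshot_index": np.arange(1, len(series) + 1),
            "time_ps": times,
            "crmsd": series.values,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")
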