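"""Structures, trajectories and their file formats.

A :class:`Snapshot` is one conformation of a fixed atom set; a
:class:`Trajectory` is an ordered, uniformly sampled sequence of snapshots
of the same atoms, together with the relaxed reference conformation that
every shape computation is measured against.  Atom identity is carried by
:class:`AtomKey` (chain, residue number, insertion code, residue name, atom
name), never by file order.

Supported formats: single- and multi-model PDB (via biotite) and a plain
tab-separated coordinate table (columns ``frame, chain, resnum, resname,
atomname, x, y, z``; ``frame`` 0 is the reference conformation, frames
1..N are the snapshots in order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import AmbiguityError, ConsistencyError, FormatError, ParameterError

__all__ = [
    "AtomKey",
    "Snapshot",
    "Trajectory",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_trajectory_table",
    "write_trajectory_table",
    "subsample",
]

_WATER_RESNAMES = {"HOH", "WAT", "H2O", "DOD", "TIP3"}


class AtomKey(NamedTuple):
    """Identity of one atom within a structure (PDB author numbering)."""

    chain: str
    resnum: int
    inscode: str
    resname: str
    atomname: str


@dataclass(frozen=True)
class Snapshot:
    """One conformation: a fixed set of atoms with Cartesian coordinates (Å)."""

    atoms: tuple[AtomKey, ...]
    coords: np.ndarray  # (n_atoms, 3), Å
    time: float = 0.0  # ps
    _index: dict[AtomKey, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ConsistencyError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if self.time < 0:
            raise ParameterError("snapshot time must be >= 0 ps")
        index = {key: i for i, key in enumerate(self.atoms)}
        if len(index) != len(self.atoms):
            seen: set[AtomKey] = set()
            for key in self.atoms:
                if key in seen:
                    raise AmbiguityError(f"duplicate atom {key}")
                seen.add(key)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.atoms)

    def __getitem__(self, key: AtomKey) -> np.ndarray:
        return self.coords[self._index[key]]

    @property
    def atom_set(self) -> frozenset[AtomKey]:
        return frozenset(self.atoms)

    def coords_for(self, keys: Sequence[AtomKey]) -> np.ndarray:
        """Coordinates of ``keys`` in the given order, shape (len(keys), 3)."""
        try:
            idx = [self._index[k] for k in keys]
        except KeyError as exc:
            raise ConsistencyError(f"atom {exc.args[0]} absent from snapshot") from exc
        return self.coords[idx]

    def ca_keys(self) -> tuple[AtomKey, ...]:
        return tuple(k for k in self.atoms if k.atomname == "CA")

    def with_coords(self, coords: np.ndarray, time: float | None = None) -> "Snapshot":
        return Snapshot(self.atoms, coords, self.time if time is None else time)


@dataclass(frozen=True)
class Trajectory:
    """Reference conformation plus uniformly spaced snapshots of the same atoms."""

    reference: Snapshot
    snapshots: tuple[Snapshot, ...]
    interval: float  # ps between consecutive snapshots
    replica_id: str = "r1"

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ParameterError("sampling interval must be > 0 ps")
        object.__setattr__(self, "snapshots", tuple(self.snapshots))
        ref_set = self.reference.atom_set
        times = [s.time for s in self.snapshots]
        for i, snap in enumerate(self.snapshots):
            if snap.atom_set != ref_set:
                diff = ref_set ^ snap.atom_set
                raise ConsistencyError(
                    f"snapshot {i} atom set differs from reference "
                    f"({len(diff)} mismatching atoms, e.g. {next(iter(diff))})"
                )
        if times:
            expected = self.snapshots[0].time + self.interval * np.arange(len(times))
            if not np.allclose(times, expected, atol=1e-6):
                raise ConsistencyError("snapshot times are not uniformly spaced")

    @property
    def n_snapshots(self) -> int:
        return len(self.snapshots)

    @property
    def duration(self) -> float:
        """Simulated time covered by the snapshots (ps)."""
        return self.interval * self.n_snapshots

    def coords_for(self, keys: Sequence[AtomKey]) -> np.ndarray:
        """Per-snapshot coordinates of ``keys``: shape (n_snapshots, len(keys), 3)."""
        out = np.empty((self.n_snapshots, len(keys), 3))
        for i, snap in enumerate(self.snapshots):
            out[i] = snap.coords_for(keys)
        return out


# -- PDB ---------------------------------------------------------------------


def _atom_array_to_snapshot(array, time: float) -> Snapshot:
    keys = []
    for i in range(array.array_length()):
        keys.append(
            AtomKey(
                chain=str(array.chain_id[i]),
                resnum=int(array.res_id[i]),
                inscode=str(array.ins_code[i]).strip(),
                resname=str(array.res_name[i]),
                atomname=str(array.atom_name[i]),
            )
        )
    return Snapshot(tuple(keys), np.array(array.coord, dtype=float), time)


def _load_pdb_models(path: str | Path):
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(altloc="first", extra_fields=[])
    except Exception as exc:  # biotite raises several parse error types
        raise FormatError(f"could not parse PDB file {path}: {exc}") from exc
    # AtomArrayStack; filter to polymer ATOM records, drop waters
    mask = ~stack.hetero
    for water in _WATER_RESNAMES:
        mask &= stack.res_name != water
    stack = stack[..., mask]
    if stack.array_length() == 0:
        raise FormatError(f"no ATOM records retained from {path}")
    return stack


def read_structure(path: str | Path) -> Snapshot:
    """Read a single-model PDB file into a :class:`Snapshot`.

    Keeps one record per ATOM line (first altloc); HETATM and waters are
    excluded.  Duplicate atom identities raise :class:`AmbiguityError`.
    """
    stack = _load_pdb_models(path)
    return _atom_array_to_snapshot(stack[0], time=0.0)


def write_structure(snap: Snapshot, path: str | Path) -> None:
    """Write a snapshot as a single-model PDB file."""
    _write_pdb([snap], path)


def _write_pdb(snapshots: Sequence[Snapshot], path: str | Path) -> None:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    first = snapshots[0]
    n = len(first)
    template = struc.AtomArray(n)
    template.chain_id = np.array([k.chain for k in first.atoms], dtype="U4")
    template.res_id = np.array([k.resnum for k in first.atoms], dtype=int)
    template.ins_code = np.array([k.inscode for k in first.atoms], dtype="U1")
    template.res_name = np.array([k.resname for k in first.atoms], dtype="U5")
    template.atom_name = np.array([k.atomname for k in first.atoms], dtype="U6")
    template.element = np.array(
        [_element_of(k.atomname) for k in first.atoms], dtype="U2"
    )
    template.hetero = np.zeros(n, dtype=bool)
    stack = struc.stack([template] * len(snapshots))
    for m, snap in enumerate(snapshots):
        stack.coord[m] = snap.coords_for(first.atoms)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def _element_of(atomname: str) -> str:
    stripped = atomname.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "C"


# -- Trajectories ------------------------------------------------------------


def read_trajectory(
    path: str | Path,
    interval: float,
    reference: Snapshot | None = None,
    replica_id: str = "r1",
) -> Trajectory:
    """Read an ordered trajectory from a multi-model PDB or a coordinate table.

    Every model/frame becomes one snapshot, in file order, at times
    ``interval, 2*interval, ...``.  If ``reference`` is not given, the first
    model doubles as the reference conformation (for the TSV dialect the
    table's ``frame == 0`` block is the reference and is never counted as a
    snapshot).
    """
    path = Path(path)
    if path.suffix.lower() in {".tsv", ".txt", ".table"}:
        return read_trajectory_table(path, interval, replica_id=replica_id)
    stack = _load_pdb_models(path)
    n_models = stack.stack_depth()
    snaps = [
        _atom_array_to_snapshot(stack[m], time=(m + 1) * interval)
        for m in range(n_models)
    ]
    ref = reference if reference is not None else snaps[0].with_coords(
        snaps[0].coords, time=0.0
    )
    _check_frames_match(ref, snaps)
    return Trajectory(ref, tuple(snaps), interval, replica_id)


def _check_frames_match(reference: Snapshot, snaps: Iterable[Snapshot]) -> None:
    ref_set = reference.atom_set
    for i, snap in enumerate(snaps):
        if snap.atom_set != ref_set:
            diff = ref_set ^ snap.atom_set
            raise ConsistencyError(
                f"frame {i} atom set mismatch ({len(diff)} atoms differ)"
            )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (snapshots only; the reference
    conformation is written separately with :func:`write_structure`)."""
    _write_pdb(list(traj.snapshots), path)


_TABLE_COLUMNS = ["frame", "chain", "resnum", "resname", "atomname", "x", "y", "z"]


def write_trajectory_table(traj: Trajectory, path: str | Path) -> None:
    """Write reference (frame 0) and snapshots (frames 1..N) as a TSV table."""
    frames = [(0, traj.reference)] + [
        (i + 1, s) for i, s in enumerate(traj.snapshots)
    ]
    has_inscode = any(k.inscode for k in traj.reference.atoms)
    rows = []
    for frame, snap in frames:
        for key, xyz in zip(snap.atoms, snap.coords):
            row = [frame, key.chain, key.resnum, key.resname, key.atomname, *xyz]
            if has_inscode:
                row.insert(3, key.inscode)
            rows.append(tuple(row))
    columns = list(_TABLE_COLUMNS)
    if has_inscode:
        columns.insert(3, "inscode")
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_trajectory_table(
    path: str | Path, interval: float, replica_id: str = "r1"
) -> Trajectory:
    """Read the TSV coordinate-table dialect (see module docstring)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"could not read coordinate table {path}: {exc}") from exc
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"coordinate table missing columns {sorted(missing)}")
    if "inscode" not in df.columns:
        df["inscode"] = ""
    df["inscode"] = df["inscode"].fillna("").astype(str)

    def block_to_snapshot(block: pd.DataFrame, time: float) -> Snapshot:
        keys = [
            AtomKey(str(c), int(r), str(i), str(rn), str(an))
            for c, r, i, rn, an in zip(
                block["chain"], block["resnum"], block["inscode"],
                block["resname"], block["atomname"],
            )
        ]
        return Snapshot(tuple(keys), block[["x", "y", "z"]].to_numpy(float), time)

    frames = sorted(df["frame"].unique())
    if 0 not in frames:
        raise FormatError("coordinate table must contain frame 0 (the reference)")
    grouped = {f: g for f, g in df.groupby("frame", sort=True)}
    reference = block_to_snapshot(grouped[0], 0.0)
    snaps = [
        block_to_snapshot(grouped[f], i * interval)
        for i, f in enumerate([f for f in frames if f != 0], start=1)
    ]
    _check_frames_match(reference, snaps)
    return Trajectory(reference, tuple(snaps), interval, replica_id)


def subsample(traj: Trajectory, target_interval: float) -> Trajectory:
    """Thin a trajectory to a coarser sampling cadence.

    ``target_interval`` must be an integer multiple of the trajectory's
    interval; every k-th snapshot is kept (k = ratio), so a 20 ns run read at
    a fine cadence yields 100 snapshots at 200 ps.
    """
    ratio = target_interval / traj.interval
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-9:
        raise ParameterError(
            f"target interval {target_interval} ps is not an integer multiple "
            f"of the trajectory interval {traj.interval} ps"
        )
    if k == 1:
        return traj
    kept = traj.snapshots[k - 1 :: k]
    kept = tuple(
        s.with_coords(s.coords, time=(i + 1) * target_interval)
        for i, s in enumerate(kept)
    )
    return Trajectory(traj.reference, kept, target_interval, traj.replica_id)
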