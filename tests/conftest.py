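"""Shared fixtures: hand-written PDB text and small synthetic systems."""

from __future__ import annotations

import numpy as np
import pytest

from cavicorr.structure_io import AtomKey, Snapshot, Trajectory


def pdb_atom_line(
    serial: int,
    name4: str,
    resname: str,
    chain: str,
    resnum: int,
    x: float,
    y: float,
    z: float,
    altloc: str = " ",
    icode: str = " ",
    element: str = "C",
    record: str = "ATOM  ",
) -> str:
    """One fixed-column PDB coordinate line (name4 is the 4-char name field)."""
    return (
        f"{record}{serial:>5d} {name4:<4s}{altloc:1s}{resname:>3s} "
        f"{chain:1s}{resnum:>4d}{icode:1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


@pytest.fixture
def toy_pdb(tmp_path):
    """Three-residue toy protein (N, CA, C per residue) plus a water."""
    lines = []
    serial = 1
    for resnum in range(1, 4):
        for name4, element in ((" N  ", "N"), (" CA ", "C"), (" C  ", "C")):
            lines.append(
                pdb_atom_line(
                    serial, name4, "ALA", "A", resnum,
                    3.8 * resnum, float(serial % 3), 0.25 * serial, element=element,
                )
            )
            serial += 1
    lines.append(
        pdb_atom_line(serial, " O  ", "HOH", "A", 101, 20.0, 20.0, 20.0,
                      element="O", record="HETATM")
    )
    lines.append("END")
    path = tmp_path / "toy.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def make_snapshot(coords: np.ndarray, time: float = 0.0, atomname: str = "CA") -> Snapshot:
    """A snapshot of bare pseudo-atoms, one residue per atom."""
    keys = tuple(
        AtomKey("A", i + 1, "", "GLY", atomname) for i in range(len(coords))
    )
    return Snapshot(keys, np.asarray(coords, dtype=float), time)


def make_trajectory(
    frames: list[np.ndarray], interval: float = 200.0, reference: np.ndarray | None = None
) -> Trajectory:
    ref = make_snapshot(frames[0] if reference is None else reference)
    snaps = tuple(
        Snapshot(ref.atoms, np.asarray(f, float), (i + 1) * interval)
        for i, f in enumerate(frames)
    )
    return Trajectory(ref, snaps, interval)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
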