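"""Cavities as filtered lining-atom sets.

A cavity is represented by the set of atoms lining it on the reference
structure; cavities are defined once and tracked through the trajectory by
that fixed atom list.  Two filters are applied before any shape analysis:

* the *artefact filter* removes atoms whose names are assigned arbitrarily
  within chemically symmetric groups (e.g. Val CG1/CG2, Arg NH1/NH2), which
  would otherwise inflate rmsd-type descriptors;
* the *size filter* discards cavities with fewer than 30 lining atoms or
  fewer than 5 distinct residues.

A simplified gap-sphere detector is provided as optional plumbing for users
without an external cavity program; it makes no attempt to replicate
SURFNET's density-map contouring.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ParameterError
from .structure_io import AtomKey, Snapshot

__all__ = [
    "Cavity",
    "ARTEFACT_ATOMS",
    "ARTEFACT_ATOMS_AS_PRINTED",
    "VDW_RADII",
    "filter_lining_atoms",
    "filter_cavities",
    "are_neighbours",
    "shared_atom_percentage",
    "cavity_distance",
    "distance_profile",
    "detect_cavities_gapsphere",
    "all_pairs",
    "read_cavities_tsv",
    "write_cavities_tsv",
]

#: Symmetry-ambiguous atom names removed per residue type before rmsd work.
#: Asp and Glu carry their chemically intended symmetric pairs (OD1/OD2 and
#: OE1/OE2 under PDB naming).
ARTEFACT_ATOMS: Mapping[str, frozenset[str]] = {
    "VAL": frozenset({"CG1", "CG2"}),
    "LEU": frozenset({"CD1", "CD2"}),
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "ARG": frozenset({"NH1", "NH2"}),
    "PHE": frozenset({"CD1", "CD2", "CE1", "CE2"}),
    "TYR": frozenset({"CD1", "CD2", "CE1", "CE2"}),
}

#: Strict alternative that keeps the Asp/Glu names exactly as sometimes
#: printed (Asp O1/O2, Glu OD1/OD2) for reproducing legacy pipelines.
ARTEFACT_ATOMS_AS_PRINTED: Mapping[str, frozenset[str]] = {
    **ARTEFACT_ATOMS,
    "ASP": frozenset({"O1", "O2"}),
    "GLU": frozenset({"OD1", "OD2"}),
}

#: Van der Waals radii (Å) by element for the gap-sphere detector.
VDW_RADII: Mapping[str, float] = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
_DEFAULT_VDW = 1.7

MIN_LINING_ATOMS = 30
MIN_RESIDUES = 5


@dataclass(frozen=True)
class Cavity:
    """A cavity: stable identifier plus its (post-filter) lining atoms."""

    cavity_id: str
    atoms: frozenset[AtomKey]

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", frozenset(self.atoms))

    @property
    def residues(self) -> frozenset[tuple[str, int, str]]:
        return frozenset((a.chain, a.resnum, a.inscode) for a in self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def centroid(self, snap: Snapshot) -> np.ndarray:
        keys = sorted(self.atoms)
        return snap.coords_for(keys).mean(axis=0)


def filter_lining_atoms(
    atoms: Iterable[AtomKey],
    artefact_table: Mapping[str, frozenset[str]] = ARTEFACT_ATOMS,
) -> frozenset[AtomKey]:
    """Remove symmetry-ambiguous atoms; all other atoms are retained."""
    return frozenset(
        a
        for a in atoms
        if a.atomname not in artefact_table.get(a.resname.upper(), frozenset())
    )


def filter_cavities(
    cavities: Sequence[Cavity],
    min_atoms: int = MIN_LINING_ATOMS,
    min_residues: int = MIN_RESIDUES,
) -> list[Cavity]:
    """Retain cavities with >= ``min_atoms`` atoms AND >= ``min_residues``
    distinct residues; order preserved.  Thresholds are inclusive."""
    return [
        c
        for c in cavities
        if c.n_atoms >= min_atoms and len(c.residues) >= min_residues
    ]


def are_neighbours(a: Cavity, b: Cavity) -> bool:
    """Two cavities are neighbours iff they share at least one lining atom."""
    return not a.atoms.isdisjoint(b.atoms)


def shared_atom_percentage(a: Cavity, b: Cavity) -> float:
    """Shared atoms as a percentage of the mean cavity size of the pair.

    0 means no atom is shared; 100 means all are (identical cavities).
    """
    mean_size = (a.n_atoms + b.n_atoms) / 2.0
    if mean_size == 0:
        return 0.0
    return 100.0 * len(a.atoms & b.atoms) / mean_size


def cavity_distance(a: Cavity, b: Cavity, snap: Snapshot) -> float:
    """Euclidean distance (Å) between the two lining-atom centroids."""
    return float(np.linalg.norm(a.centroid(snap) - b.centroid(snap)))


def distance_profile(distances: Sequence[float], bin_width: float) -> pd.DataFrame:
    """Histogram of pair distances with a 1/d² volume-effect normalization.

    Returns columns ``bin_center``, ``count`` and ``normalized`` (count
    divided by the squared bin centre; NaN for a bin centred at zero).
    """
    if bin_width <= 0:
        raise ParameterError("bin width must be > 0")
    distances = np.asarray(list(distances), dtype=float)
    if distances.size == 0:
        return pd.DataFrame(columns=["bin_center", "count", "normalized"])
    if (distances < 0).any():
        raise ParameterError("distances must be >= 0")
    n_bins = int(np.floor(distances.max() / bin_width)) + 1
    edges = bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(distances, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(centers > 0, counts / centers**2, np.nan)
    return pd.DataFrame(
        {"bin_center": centers, "count": counts, "normalized": normalized}
    )


def all_pairs(cavities: Sequence[Cavity]) -> list[tuple[str, str]]:
    """All unordered cavity pairs, each in canonical (lexicographic) order."""
    ids = sorted(c.cavity_id for c in cavities)
    return list(itertools.combinations(ids, 2))


# -- Gap-sphere detection ----------------------------------------------------


def _vdw_radius(key: AtomKey) -> float:
    name = key.atomname.strip().lstrip("0123456789")
    element = name[:1].upper() if name else "C"
    return VDW_RADII.get(element, _DEFAULT_VDW)


def detect_cavities_gapsphere(
    snap: Snapshot,
    min_radius: float = 1.0,
    max_radius: float = 4.0,
    lining_margin: float = 0.5,
    apply_filters: bool = True,
    artefact_table: Mapping[str, frozenset[str]] = ARTEFACT_ATOMS,
) -> list[Cavity]:
    """Detect cavities by fitting gap spheres between atom pairs.

    Candidate spheres are seeded at the midpoint of every atom pair closer
    than ``2 * max_radius`` and shrunk until no atom penetrates (radius =
    min over atoms of distance-to-centre minus vdW radius, capped at
    ``max_radius``).  Spheres with radius >= ``min_radius`` survive;
    overlapping survivors are merged by single linkage, and each cluster
    becomes a cavity whose lining atoms lie within (sphere radius + vdW +
    ``lining_margin``) of any member sphere centre.  The artefact and size
    filters are then applied unless ``apply_filters`` is false.
    """
    if not (0 < min_radius < max_radius):
        raise ParameterError("radii must satisfy 0 < min < max")
    coords = snap.coords
    n = len(snap)
    if n == 0:
        return []
    vdw = np.array([_vdw_radius(k) for k in snap.atoms])

    # candidate centres at midpoints of nearby atom pairs
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    pairs = tree.query_pairs(2 * max_radius, output_type="ndarray")
    if pairs.size == 0:
        return []
    centres = (coords[pairs[:, 0]] + coords[pairs[:, 1]]) / 2.0

    kept_centres = []
    kept_radii = []
    for centre in centres:
        dist = np.linalg.norm(coords - centre, axis=1) - vdw
        radius = min(float(dist.min()), max_radius)
        if radius >= min_radius:
            kept_centres.append(centre)
            kept_radii.append(radius)
    if not kept_centres:
        return []
    kept_centres = np.array(kept_centres)
    kept_radii = np.array(kept_radii)

    # single-linkage clustering of overlapping spheres
    m = len(kept_centres)
    parent = list(range(m))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    sphere_tree = cKDTree(kept_centres)
    for i, j in sphere_tree.query_pairs(2 * kept_radii.max(), output_type="ndarray"):
        if np.linalg.norm(kept_centres[i] - kept_centres[j]) < (
            kept_radii[i] + kept_radii[j]
        ):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri

    clusters: dict[int, list[int]] = {}
    for i in range(m):
        clusters.setdefault(find(i), []).append(i)

    cavities = []
    for cid, members in enumerate(sorted(clusters.values(), key=lambda ms: ms[0])):
        lining: set[AtomKey] = set()
        for i in members:
            reach = kept_radii[i] + vdw + lining_margin
            dist = np.linalg.norm(coords - kept_centres[i], axis=1)
            for idx in np.nonzero(dist <= reach)[0]:
                lining.add(snap.atoms[idx])
        cavities.append(Cavity(f"gs{cid + 1}", frozenset(lining)))

    if apply_filters:
        cavities = [
            Cavity(c.cavity_id, filter_lining_atoms(c.atoms, artefact_table))
            for c in cavities
        ]
        cavities = filter_cavities(cavities)
    return cavities


# -- Cavity-definition TSV ---------------------------------------------------

_CAVITY_COLUMNS = ["cavity_id", "chain", "resnum", "inscode", "resname", "atomname"]


def write_cavities_tsv(cavities: Sequence[Cavity], path: str | Path) -> None:
    rows = []
    for cav in cavities:
        for a in sorted(cav.atoms):
            rows.append((cav.cavity_id, a.chain, a.resnum, a.inscode, a.resname, a.atomname))
    pd.DataFrame(rows, columns=_CAVITY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cavities_tsv(
    path: str | Path,
    apply_filters: bool = True,
    artefact_table: Mapping[str, frozenset[str]] = ARTEFACT_ATOMS,
    reference: Snapshot | None = None,
) -> list[Cavity]:
    """Read cavity definitions; the artefact and size filters are applied on
    load unless ``apply_filters`` is false.  If ``reference`` is given, every
    lining atom must exist in it."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    cavities = []
    for cavity_id, group in df.groupby("cavity_id", sort=False):
        atoms = frozenset(
            AtomKey(str(c), int(r), str(i), str(rn), str(an))
            for c, r, i, rn, an in zip(
                group["chain"], group["resnum"], group["inscode"],
                group["resname"], group["atomname"],
            )
        )
        if apply_filters:
            atoms = filter_lining_atoms(atoms, artefact_table)
        cavities.append(Cavity(str(cavity_id), atoms))
    if apply_filters:
        cavities = filter_cavities(cavities)
    if reference is not None:
        ref_set = reference.atom_set
        for cav in cavities:
            stray = cav.atoms - ref_set
            if stray:
                raise ConsistencyError(
                    f"cavity {cav.cavity_id} lists atoms absent from the "
                    f"reference structure, e.g. {next(iter(stray))}"
                )
    return cavities
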