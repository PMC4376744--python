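"""Equivalent cavities between orthologous structures and conserved CSCs.

Given an atom-equivalence map between two structures (from any external
structural aligner, or from the identity-based Cα-superposition mapper
provided here), cavities are matched one-to-one by maximum coincidence of
their mapped lining atoms.  A CSC in structure A is *conserved* when both
member cavities map onto cavities that form a CSC in structure B.  Cavity
residue sets can also be intersected with functional-site (FS) and
allosteric-site (AS) annotations to flag couplings that bridge the two.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cavities import Cavity, shared_atom_percentage
from .coupling import CSC
from .errors import AlignmentRequiredError, ConsistencyError, ParameterError
from .shape import crmsd
from .structure_io import AtomKey, Snapshot

__all__ = [
    "EquivalenceMap",
    "SiteAnnotation",
    "map_equivalent_cavities",
    "conserved_cscs",
    "ca_kabsch_map",
    "site_overlap",
    "read_equivalence_tsv",
    "write_equivalence_tsv",
    "read_annotations_tsv",
    "conserved_report",
]


@dataclass(frozen=True)
class EquivalenceMap:
    """One-to-one partial mapping between atoms of two structures."""

    pairs: Mapping[AtomKey, AtomKey]
    source: str = "external-alignment"

    def __post_init__(self) -> None:
        pairs = dict(self.pairs)
        if len(set(pairs.values())) != len(pairs):
            raise ConsistencyError("equivalence map is not one-to-one")
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def inverse(self) -> "EquivalenceMap":
        return EquivalenceMap({v: k for k, v in self.pairs.items()}, self.source)


@dataclass(frozen=True)
class SiteAnnotation:
    """Annotated residue set: functional site (FS) or allosteric site (AS)."""

    label: str  # "FS" or "AS"
    residues: frozenset[tuple[str, int]]  # (chain, resnum)

    def __post_init__(self) -> None:
        if self.label not in {"FS", "AS"}:
            raise ParameterError("site label must be 'FS' or 'AS'")
        if not self.residues:
            raise ParameterError("site annotation must be non-empty")
        object.__setattr__(self, "residues", frozenset(self.residues))


def _coincidence(cav_a: Cavity, cav_b: Cavity, emap: EquivalenceMap) -> int:
    return sum(1 for atom in cav_a.atoms if emap.pairs.get(atom) in cav_b.atoms)


def map_equivalent_cavities(
    cavities_a: Sequence[Cavity],
    cavities_b: Sequence[Cavity],
    emap: EquivalenceMap,
) -> list[tuple[str, str, int]]:
    """One-to-one cavity matching maximizing total atom coincidence.

    Coincidence of (A, B) is the number of A lining atoms whose mapped
    partner lines B.  The assignment maximizes the summed coincidence over
    all one-to-one matchings (Hungarian algorithm; exact, unlike a greedy
    descending-count pass, which can be trapped by a large entry that blocks
    two medium ones).  Pairs with zero coincidence are never matched.
    Output is sorted by descending coincidence, then lexicographic ids.
    """
    from scipy.optimize import linear_sum_assignment

    if not cavities_a or not cavities_b:
        return []
    cavities_a = sorted(cavities_a, key=lambda c: c.cavity_id)
    cavities_b = sorted(cavities_b, key=lambda c: c.cavity_id)
    matrix = np.array(
        [[_coincidence(ca, cb, emap) for cb in cavities_b] for ca in cavities_a]
    )
    rows, cols = linear_sum_assignment(matrix, maximize=True)
    matched = [
        (cavities_a[i].cavity_id, cavities_b[j].cavity_id, int(matrix[i, j]))
        for i, j in zip(rows, cols)
        if matrix[i, j] > 0
    ]
    matched.sort(key=lambda m: (-m[2], m[0], m[1]))
    return matched


def conserved_cscs(
    cscs_a: Sequence[CSC],
    cscs_b: Sequence[CSC],
    cavity_map: Sequence[tuple[str, str, int]] | Mapping[str, str],
) -> list[tuple[CSC, CSC]]:
    """CSCs of A whose mapped cavity pair is also a CSC in B.

    Both member cavities must be mapped; the mapped pair must appear among
    B's CSCs (pair order is canonical, so orientation is irrelevant).
    """
    if not isinstance(cavity_map, Mapping):
        cavity_map = {a: b for a, b, _ in cavity_map}
    b_by_pair = {csc.pair: csc for csc in cscs_b}
    out = []
    for csc in cscs_a:
        a1, a2 = csc.pair
        if a1 not in cavity_map or a2 not in cavity_map:
            continue
        mapped = tuple(sorted((cavity_map[a1], cavity_map[a2])))
        if mapped in b_by_pair:
            out.append((csc, b_by_pair[mapped]))
    return out


def ca_kabsch_map(
    structure_a: Snapshot,
    structure_b: Snapshot,
    rmsd_ceiling: float = 5.0,
) -> EquivalenceMap:
    """Identity-based atom map, validated by Cα superposition.

    Stand-in for an external structural alignment when the two structures
    share residue numbering: atoms with equal identity are paired, provided
    the Cα-trace crmsd after optimal superposition stays below
    ``rmsd_ceiling`` (else a proper aligner is required).
    """
    shared = sorted(structure_a.atom_set & structure_b.atom_set)
    ca_keys = [k for k in shared if k.atomname == "CA"]
    if len(ca_keys) < 3:
        raise AlignmentRequiredError("fewer than 3 shared Cα atoms")
    fit = crmsd(structure_a.coords_for(ca_keys), structure_b.coords_for(ca_keys))
    if fit > rmsd_ceiling:
        raise AlignmentRequiredError(
            f"Cα crmsd {fit:.2f} Å exceeds ceiling {rmsd_ceiling} Å; "
            "provide an external alignment map"
        )
    return EquivalenceMap({k: k for k in shared}, source="ca-kabsch")


def site_overlap(
    csc: CSC,
    cavities: Mapping[str, Cavity],
    annotations: Sequence[SiteAnnotation],
) -> bool:
    """True iff one member cavity touches FS residues and the other touches
    AS residues (either assignment); both sites in one cavity do not count."""
    if not annotations:
        raise ParameterError("annotations must be non-empty")
    fs = frozenset().union(*(a.residues for a in annotations if a.label == "FS"))
    as_ = frozenset().union(*(a.residues for a in annotations if a.label == "AS"))
    id1, id2 = csc.pair
    res1 = {(c, n) for c, n, _ in cavities[id1].residues}
    res2 = {(c, n) for c, n, _ in cavities[id2].residues}
    return bool((res1 & fs and res2 & as_) or (res2 & fs and res1 & as_))


# -- I/O ---------------------------------------------------------------------

_EMAP_COLUMNS = [
    "chain_a", "resnum_a", "inscode_a", "resname_a", "atomname_a",
    "chain_b", "resnum_b", "inscode_b", "resname_b", "atomname_b",
]


def write_equivalence_tsv(emap: EquivalenceMap, path: str | Path) -> None:
    rows = [(*a, *b) for a, b in sorted(emap.pairs.items())]
    pd.DataFrame(rows, columns=_EMAP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_equivalence_tsv(path: str | Path, source: str = "external-alignment") -> EquivalenceMap:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    pairs = {}
    for row in df.itertuples(index=False):
        a = AtomKey(str(row.chain_a), int(row.resnum_a), str(row.inscode_a),
                    str(row.resname_a), str(row.atomname_a))
        b = AtomKey(str(row.chain_b), int(row.resnum_b), str(row.inscode_b),
                    str(row.resname_b), str(row.atomname_b))
        pairs[a] = b
    return EquivalenceMap(pairs, source)


def read_annotations_tsv(path: str | Path) -> list[SiteAnnotation]:
    """Annotation TSV: columns label, chain, resnum; one row per residue."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for label, group in df.groupby("label", sort=True):
        residues = frozenset(
            (str(c), int(r)) for c, r in zip(group["chain"], group["resnum"])
        )
        out.append(SiteAnnotation(str(label), residues))
    return out


def conserved_report(
    conserved: Sequence[tuple[CSC, CSC]],
    cavities_a: Mapping[str, Cavity],
    cavities_b: Mapping[str, Cavity],
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Side-by-side table of conserved couplings: per structure the pair,
    its mean correlation and the shared-atom percentage within the pair."""
    rows = []
    for csc_a, csc_b in conserved:
        rows.append(
            (
                label_a,
                "-".join(csc_a.pair),
                round(csc_a.mean_r, 3),
                round(shared_atom_percentage(
                    cavities_a[csc_a.pair[0]], cavities_a[csc_a.pair[1]]), 1),
                label_b,
                "-".join(csc_b.pair),
                round(csc_b.mean_r, 3),
                round(shared_atom_percentage(
                    cavities_b[csc_b.pair[0]], cavities_b[csc_b.pair[1]]), 1),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "structure_a", "pair_a", "correlation_a", "shared_pct_a",
            "structure_b", "pair_b", "correlation_b", "shared_pct_b",
        ],
    )
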