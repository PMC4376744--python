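import numpy as np
import pytest

from cavicorr.cavities import (
    ARTEFACT_ATOMS_AS_PRINTED,
    Cavity,
    all_pairs,
    are_neighbours,
    cavity_distance,
    detect_cavities_gapsphere,
    distance_profile,
    filter_cavities,
    filter_lining_atoms,
    read_cavities_tsv,
    shared_atom_percentage,
    write_cavities_tsv,
)
from cavicorr.errors import ParameterError
from cavicorr.structure_io import AtomKey, Snapshot

from conftest import make_snapshot


def atom(resname, atomname, resnum=1, chain="A"):
    return AtomKey(chain, resnum, "", resname, atomname)


def make_cavity(cid, n_atoms, n_residues, chain="A", base=1):
    """A cavity with exactly n_atoms spread over n_residues residues."""
    atoms = set()
    for i in range(n_atoms):
        atoms.add(
            AtomKey(chain, base + i % n_residues, "", "CAV", f"P{i // n_residues + 1}")
        )
    return Cavity(cid, frozenset(atoms))


class TestArtefactFilter:
    @pytest.mark.parametrize(
        ("atoms", "kept"),
        [
            ({atom("VAL", "CG1", 12), atom("VAL", "CB", 12)}, {atom("VAL", "CB", 12)}),
            (set(), set()),
            (
                {atom("PHE", "CD1", 8), atom("PHE", "CZ", 8),
                 atom("ARG", "NH1", 9), atom("ARG", "NE", 9)},
                {atom("PHE", "CZ", 8), atom("ARG", "NE", 9)},
            ),
            # chemically intended symmetric pairs under PDB naming
            ({atom("ASP", "OD1"), atom("ASP", "CB")}, {atom("ASP", "CB")}),
            ({atom("GLU", "OE2"), atom("GLU", "CD")}, {atom("GLU", "CD")}),
            ({atom("TYR", "CE1"), atom("TYR", "OH")}, {atom("TYR", "OH")}),
            ({atom("LEU", "CD2"), atom("LEU", "CG")}, {atom("LEU", "CG")}),
        ],
    )
    def test_symmetric_atoms_removed_others_kept(self, atoms, kept):
        assert filter_lining_atoms(atoms) == frozenset(kept)

    def test_as_printed_table_differs_only_for_asp_glu(self):
        asp = {atom("ASP", "OD1"), atom("ASP", "O1")}
        assert filter_lining_atoms(asp) == {atom("ASP", "O1")}
        assert filter_lining_atoms(asp, ARTEFACT_ATOMS_AS_PRINTED) == {atom("ASP", "OD1")}


class TestSizeFilter:
    @pytest.mark.parametrize(
        ("n_atoms", "n_residues", "kept"),
        [(35, 6, True), (29, 10, False), (30, 5, True), (40, 4, False)],
    )
    def test_thresholds_are_inclusive(self, n_atoms, n_residues, kept):
        cav = make_cavity("c1", n_atoms, n_residues)
        assert cav.n_atoms == n_atoms and len(cav.residues) == n_residues
        assert (len(filter_cavities([cav])) == 1) is kept

    def test_filters_commute_with_joint_condition(self, rng):
        resnames = ["VAL", "LEU", "ASP", "GLY", "ALA"]
        names = ["CG1", "CD2", "OD1", "CA", "CB", "N"]
        cavities = []
        for cid in range(20):
            atoms = frozenset(
                AtomKey("A", int(rng.integers(1, 12)), "",
                        resnames[rng.integers(len(resnames))],
                        names[rng.integers(len(names))])
                for _ in range(rng.integers(5, 80))
            )
            cavities.append(Cavity(f"c{cid}", atoms))
        sequential = filter_cavities(
            [Cavity(c.cavity_id, filter_lining_atoms(c.atoms)) for c in cavities]
        )
        joint = [
            c for c in cavities
            if len(filter_lining_atoms(c.atoms)) >= 30
            and len(Cavity(c.cavity_id, filter_lining_atoms(c.atoms)).residues) >= 5
        ]
        assert [c.cavity_id for c in sequential] == [c.cavity_id for c in joint]


class TestNeighbourhood:
    def test_one_shared_atom_makes_neighbours(self):
        a = make_cavity("a", 30, 5)
        shared = next(iter(a.atoms))
        b = Cavity("b", frozenset({shared}) | make_cavity("b", 29, 5, base=50).atoms)
        assert are_neighbours(a, b)
        assert shared_atom_percentage(a, b) > 0

    def test_disjoint_and_identical(self):
        a = make_cavity("a", 30, 5, base=1)
        b = make_cavity("b", 30, 5, base=100)
        assert not are_neighbours(a, b)
        assert shared_atom_percentage(a, b) == 0.0
        assert are_neighbours(a, a)
        assert shared_atom_percentage(a, Cavity("a2", a.atoms)) == 100.0

    def test_shared_percentage_mean_size_normalization(self):
        # |a|=30, |b|=50, 20 shared -> 100*20/40 = 50
        common = {AtomKey("A", 1000 + i, "", "CAV", "P1") for i in range(20)}
        a = Cavity("a", frozenset(common) | make_cavity("x", 10, 5, base=1).atoms)
        b = Cavity("b", frozenset(common) | make_cavity("y", 30, 5, base=200).atoms)
        assert (a.n_atoms, b.n_atoms) == (30, 50)
        assert shared_atom_percentage(a, b) == pytest.approx(50.0)
        assert shared_atom_percentage(b, a) == pytest.approx(50.0)


class TestCavityDistance:
    def test_identical_cavities_distance_zero(self):
        coords = np.arange(9.0).reshape(3, 3)
        snap = make_snapshot(coords)
        cav = Cavity("c", frozenset(snap.atoms))
        assert cavity_distance(cav, cav, snap) == 0.0

    def test_single_atom_cavities(self):
        snap = make_snapshot(np.array([[0.0, 0, 0], [10.0, 0, 0]]))
        a = Cavity("a", frozenset({snap.atoms[0]}))
        b = Cavity("b", frozenset({snap.atoms[1]}))
        assert cavity_distance(a, b, snap) == pytest.approx(10.0)

    def test_matches_centroid_oracle(self, rng):
        coords = rng.uniform(0, 20, size=(6, 3))
        snap = make_snapshot(coords)
        a = Cavity("a", frozenset(snap.atoms[:3]))
        b = Cavity("b", frozenset(snap.atoms[3:]))
        # independent mean-and-norm computation
        ca = coords[[snap.atoms.index(k) for k in sorted(a.atoms)]].mean(axis=0)
        cb = coords[[snap.atoms.index(k) for k in sorted(b.atoms)]].mean(axis=0)
        expected = float(np.sqrt(((ca - cb) ** 2).sum()))
        assert cavity_distance(a, b, snap) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_rigid_motion(self, rng):
        coords = rng.uniform(0, 20, size=(6, 3))
        snap = make_snapshot(coords)
        a = Cavity("a", frozenset(snap.atoms[:3]))
        b = Cavity("b", frozenset(snap.atoms[3:]))
        theta = 1.1
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        moved = Snapshot(snap.atoms, coords @ R.T + np.array([5.0, -2.0, 7.0]))
        assert cavity_distance(a, b, moved) == pytest.approx(
            cavity_distance(a, b, snap), abs=1e-9
        )


class TestDistanceProfile:
    def test_inverse_square_normalization(self):
        df = distance_profile([2.0] * 8, bin_width=4.0)  # bin centre 2 A
        assert df.loc[0, "count"] == 8
        assert df.loc[0, "normalized"] == pytest.approx(8 / 4.0)

    def test_equalizing_counts(self):
        d = [5.0] * 25 + [10.0] * 100
        df = distance_profile(d, bin_width=5.0)  # centres 2.5, 7.5, 12.5
        counts = dict(zip(df["bin_center"], df["normalized"]))
        assert counts[7.5] == pytest.approx(25 / 7.5**2)
        assert counts[12.5] == pytest.approx(100 / 12.5**2)

    def test_empty_input(self):
        assert distance_profile([], 1.0).empty

    def test_zero_centre_bin_flagged(self):
        df = distance_profile([0.1], bin_width=1.0)
        assert np.isnan(df.loc[0, "normalized"]) or df.loc[0, "bin_center"] > 0


class TestGapSphereDetector:
    @staticmethod
    def hollow_cubic_shell():
        """5^3 lattice (2 A spacing) minus the interior: faces at +-4 A.

        The interior gap sphere at the origin reaches the nearest atoms
        (face centres at 4.0 A, carbon vdW 1.7) at radius 2.3 A.
        """
        pts = [
            (2.0 * i, 2.0 * j, 2.0 * k)
            for i in range(-2, 3)
            for j in range(-2, 3)
            for k in range(-2, 3)
            if max(abs(i), abs(j), abs(k)) == 2
        ]
        keys = tuple(AtomKey("A", n + 1, "", "GLY", "CA") for n in range(len(pts)))
        return Snapshot(keys, np.array(pts))

    def test_single_atom_yields_no_cavity(self):
        snap = make_snapshot(np.zeros((1, 3)))
        assert detect_cavities_gapsphere(snap) == []

    def test_interior_void_found_with_shell_lining(self):
        snap = self.hollow_cubic_shell()
        cavs = detect_cavities_gapsphere(snap, min_radius=1.0, max_radius=4.0)
        assert len(cavs) == 1
        assert cavs[0].atoms <= snap.atom_set
        # lining = atoms within 2.3 + 1.7 + 0.5 = 4.5 A of the centre:
        # 6 face centres (4.0 A) + 24 edge-adjacent atoms (sqrt(20) A)
        assert cavs[0].n_atoms == 30

    def test_min_radius_above_gap_finds_nothing(self):
        snap = self.hollow_cubic_shell()
        assert detect_cavities_gapsphere(snap, min_radius=3.0, max_radius=4.0) == []

    def test_invalid_radii(self):
        snap = self.hollow_cubic_shell()
        with pytest.raises(ParameterError):
            detect_cavities_gapsphere(snap, min_radius=3.0, max_radius=2.0)


class TestCavityTSV:
    def test_round_trip_preserves_lining(self, tmp_path):
        cavs = [make_cavity("c1", 35, 7), make_cavity("c2", 40, 8, base=100)]
        path = tmp_path / "cavities.tsv"
        write_cavities_tsv(cavs, path)
        back = read_cavities_tsv(path)
        assert [c.cavity_id for c in back] == ["c1", "c2"]
        assert back[0].atoms == cavs[0].atoms

    def test_filters_applied_on_load(self, tmp_path):
        small = make_cavity("tiny", 10, 5)
        path = tmp_path / "cavities.tsv"
        write_cavities_tsv([small], path)
        assert read_cavities_tsv(path) == []
        assert len(read_cavities_tsv(path, apply_filters=False)) == 1


def test_all_pairs_of_ten_cavities_is_45():
    cavs = [make_cavity(f"c{i:02d}", 30, 5, base=100 * i) for i in range(10)]
    assert len(all_pairs(cavs)) == 45
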