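"""Synthetic proteins and trajectories with planted coupling structure.

The generator emulates, at a statistical level, what a cavity-coupling
pipeline sees in an MD trajectory: each cavity is a spherical shell of
pseudo-atoms that "breathes" radially with an amplitude series

    s_c(t) = rho * z_pair(t) + sqrt(1 - rho^2) * eps_c(t)

for cavities in a planted coupled pair (shared latent z_pair), and
s_c(t) = eps_c(t) for independent cavities; the radial displacement is
amplitude * (baseline + s_c(t)), the baseline being the positive structural
drift from the reference around which real crmsd series fluctuate.  All
latent series are AR(1)
with lag-1 autocorrelation phi (crmsd series from MD are autocorrelated,
which is exactly what stresses a plain permutation null).  Per-atom
Gaussian jitter, an independent Cα-scaffold wobble, and a global rigid-body
wander (exercising crmsd invariance) are superimposed.  Planted couplings
can be restricted to a snapshot interval (regime switching), and designated
cavity pairs can share lining atoms (neighbours).  A ground-truth manifest
records what was planted.

No force field, solvent or energetics: the generator reproduces the
*statistical* structure the analysis must detect, not protein physics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .cavities import Cavity, are_neighbours
from .conservation import EquivalenceMap, write_equivalence_tsv
from .errors import ParameterError
from .structure_io import (
    AtomKey,
    Snapshot,
    Trajectory,
    write_trajectory_table,
)
from . import cavities as _cavmod

__all__ = [
    "PlantedCoupling",
    "GroundTruth",
    "ar1_series",
    "generate_protein",
    "generate_trajectory",
    "generate_series_set",
    "write_fixture_bundle",
    "SCENARIOS",
]

DEFAULT_N_CAVITIES = 10
DEFAULT_ATOMS_PER_CAVITY = 36
DEFAULT_RESIDUES_PER_CAVITY = 6
DEFAULT_SHELL_RADIUS = 4.0  # Å
DEFAULT_AMPLITUDE = 0.5  # Å, stationary sd of the breathing displacement
DEFAULT_BASELINE = 2.0  # baseline drift from the reference, in latent sd units
DEFAULT_SIGMA = 0.1  # Å, per-atom Gaussian jitter
DEFAULT_PHI = 0.5  # AR(1) lag-1 autocorrelation of latent series
DEFAULT_RHO = 0.95  # coupling strength of planted pairs
DEFAULT_INTERVAL_PS = 200.0


@dataclass(frozen=True)
class PlantedCoupling:
    """One planted cavity pair: coupling strength and active snapshot range."""

    pair: tuple[str, str]
    rho: float
    active: tuple[int, int] | None = None  # [start, end) snapshots; None = full

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair", tuple(sorted(self.pair)))
        if not (0.0 <= self.rho <= 1.0):
            raise ParameterError("coupling strength rho must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Manifest of what was planted into a synthetic trajectory."""

    planted: tuple[PlantedCoupling, ...]
    neighbour_pairs: tuple[tuple[str, str], ...]
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted": [
                    {
                        "pair": list(p.pair),
                        "rho": p.rho,
                        "active": list(p.active) if p.active else None,
                    }
                    for p in self.planted
                ],
                "neighbour_pairs": [list(p) for p in self.neighbour_pairs],
                "seed": self.seed,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(
            tuple(
                PlantedCoupling(
                    tuple(p["pair"]), p["rho"],
                    tuple(p["active"]) if p["active"] else None,
                )
                for p in obj["planted"]
            ),
            tuple(tuple(p) for p in obj["neighbour_pairs"]),
            int(obj["seed"]),
        )


def ar1_series(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Stationary AR(1) series with unit variance and lag-1 autocorrelation phi."""
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innov[t - 1]
    return x


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """n roughly uniform points on a sphere (deterministic)."""
    i = np.arange(n) + 0.5
    phi_ang = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return radius * np.column_stack(
        [np.cos(theta) * np.sin(phi_ang), np.sin(theta) * np.sin(phi_ang), np.cos(phi_ang)]
    )


def _cavity_id(k: int) -> str:
    return f"c{k + 1:02d}"


def generate_protein(
    n_cavities: int = DEFAULT_N_CAVITIES,
    atoms_per_cavity: int = DEFAULT_ATOMS_PER_CAVITY,
    residues_per_cavity: int = DEFAULT_RESIDUES_PER_CAVITY,
    shared_pairs: Sequence[tuple[int, int]] = (),
    n_shared_atoms: int = 12,
    n_ca: int = 20,
    shell_radius: float = DEFAULT_SHELL_RADIUS,
    seed: int = 0,
) -> tuple[Snapshot, list[Cavity]]:
    """Build a toy protein: cavity shells on a grid plus a Cα scaffold.

    Each cavity is a Fibonacci-sphere shell of ``atoms_per_cavity``
    pseudo-atoms grouped into ``residues_per_cavity`` residues (defaults
    pass the 30-atom / 5-residue cavity filters).  For every index pair in
    ``shared_pairs`` the second cavity is relocated to shell-radius·√2 from
    the first, so their shells intersect, and the ``n_shared_atoms`` atoms
    of the first shell nearest the intersection circle also line the second
    cavity: a shared wall whose motion contributes to both cavities' shape
    series (at the intersection circle the two radial directions are
    orthogonal, so the wall's displacement adds positively-correlated
    variance to both crmsds rather than cancelling).  Deterministic for a
    seed.
    """
    if atoms_per_cavity < _cavmod.MIN_LINING_ATOMS:
        raise ParameterError(f"atoms per cavity must be >= {_cavmod.MIN_LINING_ATOMS}")
    if residues_per_cavity < _cavmod.MIN_RESIDUES:
        raise ParameterError(f"residues per cavity must be >= {_cavmod.MIN_RESIDUES}")
    if n_shared_atoms > atoms_per_cavity:
        raise ParameterError("cannot share more atoms than a cavity has")
    for i, j in shared_pairs:
        if not (0 <= i < n_cavities and 0 <= j < n_cavities and i != j):
            raise ParameterError(f"invalid shared-atom pair ({i}, {j})")
    rng = np.random.default_rng(seed)

    # cavity centres on a coarse cubic grid, well separated
    spacing = 6.0 * shell_radius
    side = int(np.ceil(n_cavities ** (1 / 3)))
    centres = np.array(
        [
            spacing * np.array([k % side, (k // side) % side, k // (side * side)])
            for k in range(n_cavities)
        ],
        dtype=float,
    )
    centres += rng.normal(scale=0.5, size=centres.shape)  # break exact symmetry
    # neighbour pairs: move the second cavity so the shells intersect and a
    # shared wall exists (centre separation r*sqrt(2))
    for i, j in shared_pairs:
        axis = centres[j] - centres[i]
        axis /= np.linalg.norm(axis)
        centres[j] = centres[i] + shell_radius * np.sqrt(2.0) * axis

    keys: list[AtomKey] = []
    coords: list[np.ndarray] = []
    per_res = int(np.ceil(atoms_per_cavity / residues_per_cavity))
    cavity_atoms: list[list[AtomKey]] = []
    for k in range(n_cavities):
        shell = _fibonacci_sphere(atoms_per_cavity, shell_radius) + centres[k]
        atoms_k = []
        for a in range(atoms_per_cavity):
            key = AtomKey(
                chain="A",
                resnum=100 * (k + 1) + a // per_res,
                inscode="",
                resname="CAV",
                atomname=f"P{a % per_res + 1}",
            )
            keys.append(key)
            coords.append(shell[a])
            atoms_k.append(key)
        cavity_atoms.append(atoms_k)

    # Cα scaffold threading between the cavities
    t = np.linspace(0, 1, n_ca)
    lo, hi = centres.min(axis=0) - 2 * shell_radius, centres.max(axis=0) + 2 * shell_radius
    path = lo + (hi - lo) * t[:, None]
    path += 2.0 * np.column_stack(
        [np.sin(8 * np.pi * t), np.cos(8 * np.pi * t), np.zeros_like(t)]
    )
    for i in range(n_ca):
        keys.append(AtomKey("A", i + 1, "", "GLY", "CA"))
        coords.append(path[i])

    reference = Snapshot(tuple(keys), np.array(coords), time=0.0)

    lining = [set(atoms) for atoms in cavity_atoms]
    for i, j in shared_pairs:
        # wall atoms: donor-shell atoms nearest the shell-intersection circle
        donor = cavity_atoms[i]
        donor_xyz = np.array([reference[a] for a in donor])
        off_circle = np.abs(
            np.linalg.norm(donor_xyz - centres[j], axis=1) - shell_radius
        )
        for idx in np.argsort(off_circle, kind="stable")[:n_shared_atoms]:
            lining[j].add(donor[idx])
    cavs = [Cavity(_cavity_id(k), frozenset(lining[k])) for k in range(n_cavities)]
    return reference, cavs


def _rigid_wander(rng: np.random.Generator, coords: np.ndarray) -> np.ndarray:
    """Apply a random small rotation and translation to all atoms."""
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0, 0.3)  # rad
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-3.0, 3.0, size=3)
    centre = coords.mean(axis=0)
    return (coords - centre) @ R.T + centre + t


def _amplitude_series(
    cavs: Sequence[Cavity],
    planted: Sequence[PlantedCoupling],
    n_snapshots: int,
    phi: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-cavity breathing series s_c(t); coupled pairs share a latent."""
    in_pair: dict[str, PlantedCoupling] = {}
    for p in planted:
        for cid in p.pair:
            if cid in in_pair:
                raise ParameterError(f"cavity {cid} appears in two planted pairs")
            in_pair[cid] = p
    z: dict[tuple[str, str], np.ndarray] = {
        p.pair: ar1_series(rng, n_snapshots, phi) for p in planted
    }
    s: dict[str, np.ndarray] = {}
    for cav in cavs:
        eps = ar1_series(rng, n_snapshots, phi)
        cid = cav.cavity_id
        if cid in in_pair:
            p = in_pair[cid]
            coupled = p.rho * z[p.pair] + np.sqrt(1 - p.rho**2) * eps
            if p.active is None:
                s[cid] = coupled
            else:
                start, end = p.active
                out = eps.copy()
                out[start:end] = coupled[start:end]
                s[cid] = out
        else:
            s[cid] = eps
    return s


def generate_trajectory(
    reference: Snapshot,
    cavs: Sequence[Cavity],
    planted: Sequence[PlantedCoupling] = (),
    n_snapshots: int = 100,
    interval: float = DEFAULT_INTERVAL_PS,
    amplitude: float = DEFAULT_AMPLITUDE,
    baseline: float = DEFAULT_BASELINE,
    noise_sigma: float = DEFAULT_SIGMA,
    phi: float = DEFAULT_PHI,
    ca_amplitude: float = 0.3,
    n_replicas: int = 2,
    rigid_wander: bool = True,
    seed: int = 0,
) -> tuple[list[Trajectory], GroundTruth]:
    """Generate replica trajectories with the stated planted couplings.

    Every cavity's shell atoms move radially by
    ``amplitude * (baseline + s_c(t))`` from the cavity centroid.  The
    baseline models the structural drift away from the reference that real
    trajectories show (crmsd fluctuates about a positive level rather than
    returning to zero), keeping the cavity's crmsd monotone in its breathing
    amplitude.  Atoms lining two cavities receive both cavities'
    contributions, so shared-atom pairs co-fluctuate without any latent
    coupling; Cα atoms wobble independently; iid Gaussian jitter of sd
    ``noise_sigma`` and an optional global rigid wander are added.  Replicas
    share the planted structure but use independent noise streams.
    """
    if n_snapshots < 40:
        raise ParameterError("need at least 40 snapshots")
    for p in planted:
        if p.active is not None and not (
            0 <= p.active[0] < p.active[1] <= n_snapshots
        ):
            raise ParameterError(f"active interval {p.active} outside trajectory")
    known = {c.cavity_id for c in cavs}
    for p in planted:
        if not set(p.pair) <= known:
            raise ParameterError(f"planted pair {p.pair} references unknown cavities")

    ref_xyz = reference.coords
    atom_index = {key: i for i, key in enumerate(reference.atoms)}
    # radial unit vectors per (cavity, atom)
    contributions: list[tuple[str, np.ndarray, np.ndarray]] = []
    for cav in cavs:
        keys = sorted(cav.atoms)
        idx = np.array([atom_index[k] for k in keys])
        centre = ref_xyz[idx].mean(axis=0)
        u = ref_xyz[idx] - centre
        norms = np.linalg.norm(u, axis=1)
        u = u / np.where(norms > 1e-9, norms, 1.0)[:, None]
        contributions.append((cav.cavity_id, idx, u))
    ca_idx = np.array(
        [i for i, k in enumerate(reference.atoms) if k.atomname == "CA"], dtype=int
    )

    replicas = []
    children = np.random.SeedSequence(seed).spawn(n_replicas)
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        s = _amplitude_series(cavs, planted, n_snapshots, phi, rng)
        ca_dirs = rng.standard_normal((len(ca_idx), 3))
        ca_dirs /= np.linalg.norm(ca_dirs, axis=1, keepdims=True)
        ca_series = np.column_stack(
            [ar1_series(rng, n_snapshots, phi) for _ in range(len(ca_idx))]
        )
        snaps = []
        for t in range(n_snapshots):
            xyz = ref_xyz.copy()
            for cid, idx, u in contributions:
                xyz[idx] += amplitude * (baseline + s[cid][t]) * u
            if len(ca_idx):
                xyz[ca_idx] += ca_amplitude * ca_series[t][:, None] * ca_dirs
            xyz += rng.normal(scale=noise_sigma, size=xyz.shape)
            if rigid_wander:
                xyz = _rigid_wander(rng, xyz)
            snaps.append(Snapshot(reference.atoms, xyz, time=(t + 1) * interval))
        replicas.append(
            Trajectory(reference, tuple(snaps), interval, replica_id=f"r{rep + 1}")
        )

    neighbour_pairs = tuple(
        (a.cavity_id, b.cavity_id)
        for i, a in enumerate(cavs)
        for b in cavs[i + 1 :]
        if are_neighbours(a, b)
    )
    truth = GroundTruth(tuple(planted), neighbour_pairs, seed)
    return replicas, truth


def generate_series_set(
    n_cavities: int = DEFAULT_N_CAVITIES,
    planted: Sequence[PlantedCoupling] = (),
    n_snapshots: int = 100,
    amplitude: float = DEFAULT_AMPLITUDE,
    baseline: float = DEFAULT_BASELINE,
    sigma: float = DEFAULT_SIGMA,
    phi: float = DEFAULT_PHI,
    seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Cavity crmsd-like series directly at the statistical level.

    Skips 3-D geometry: each series is the magnitude of the breathing
    displacement about its baseline drift, combined with the jitter floor:
    sqrt((amplitude * (baseline + s_c))^2 + (sigma * g)^2).  Used for large
    significance/power simulations where building coordinates per snapshot
    would dominate the cost.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cavs = [Cavity(_cavity_id(k), frozenset()) for k in range(n_cavities)]
    # bypass Cavity size checks: only ids matter here
    s = _amplitude_series(cavs, planted, n_snapshots, phi, rng)
    out = {}
    for cid, series in s.items():
        g = rng.standard_normal(n_snapshots)
        out[cid] = np.sqrt((amplitude * (baseline + series)) ** 2 + (sigma * g) ** 2)
    return out


SCENARIOS = ("null", "coupled", "regime-switch", "neighbours", "ortholog-pair")


def write_fixture_bundle(
    out_dir: str | Path,
    scenario: str,
    seed: int = 0,
    n_snapshots: int = 100,
    rho: float = DEFAULT_RHO,
) -> dict[str, Path]:
    """Write a self-contained fixture bundle for one scenario.

    Emits trajectory coordinate tables (one per replica), the cavity
    definitions, and a ground-truth manifest; the ``ortholog-pair``
    scenario additionally writes a second (perturbed) structure with its
    own trajectories, cavities and an identity atom-equivalence map.
    Regenerating with the same seed reproduces the files byte for byte.
    """
    if scenario not in SCENARIOS:
        raise ParameterError(f"unknown scenario {scenario!r}; pick from {SCENARIOS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    shared_pairs = [(0, 1), (2, 3)] if scenario == "neighbours" else []
    reference, cavs = generate_protein(shared_pairs=shared_pairs, seed=seed)

    if scenario == "null" or scenario == "neighbours":
        planted: list[PlantedCoupling] = []
    elif scenario == "coupled":
        planted = [
            PlantedCoupling(("c01", "c02"), rho),
            PlantedCoupling(("c03", "c04"), rho),
            PlantedCoupling(("c05", "c06"), rho),
        ]
    elif scenario == "regime-switch":
        planted = [PlantedCoupling(("c01", "c02"), rho, (0, n_snapshots // 2))]
    else:  # ortholog-pair
        planted = [PlantedCoupling(("c01", "c02"), rho)]

    replicas, truth = generate_trajectory(
        reference, cavs, planted, n_snapshots=n_snapshots, seed=seed
    )
    for traj in replicas:
        path = out / f"traj_{traj.replica_id}.tsv"
        write_trajectory_table(traj, path)
        files[f"traj_{traj.replica_id}"] = path
    _cavmod.write_cavities_tsv(cavs, out / "cavities.tsv")
    files["cavities"] = out / "cavities.tsv"
    (out / "manifest.json").write_text(truth.to_json())
    files["manifest"] = out / "manifest.json"

    if scenario == "ortholog-pair":
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
        perturbed = Snapshot(
            reference.atoms,
            reference.coords + rng.normal(scale=0.2, size=reference.coords.shape),
            time=0.0,
        )
        replicas_b, _ = generate_trajectory(
            perturbed, cavs, planted, n_snapshots=n_snapshots, seed=seed + 1
        )
        for traj in replicas_b:
            path = out / f"ortholog_traj_{traj.replica_id}.tsv"
            write_trajectory_table(traj, path)
            files[f"ortholog_traj_{traj.replica_id}"] = path
        _cavmod.write_cavities_tsv(cavs, out / "ortholog_cavities.tsv")
        files["ortholog_cavities"] = out / "ortholog_cavities.tsv"
        emap = EquivalenceMap({k: k for k in reference.atoms}, source="ca-kabsch")
        write_equivalence_tsv(emap, out / "emap.tsv")
        files["emap"] = out / "emap.tsv"
    return files
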