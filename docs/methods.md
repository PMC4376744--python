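# Methods

## Scope and data model

`cavicorr` analyses couplings between protein cavities along an ordered set
of snapshots of a fixed atom set. Atom identity is carried by
(chain, residue number, insertion code, residue name, atom name) — never by
file order — and a trajectory consists of a relaxed reference conformation
plus uniformly spaced snapshots (the reference is stored separately and is
not counted among the analysed snapshots). Supported inputs are single- and
multi-model PDB (read with biotite; first altloc kept, HETATM and waters
dropped) and a plain TSV coordinate table. Trajectories sampled more finely
than the analysis cadence are thinned with `subsample` (default cadence
200 ps, i.e. 100 snapshots per 20 ns).

## Cavities

Cavities are defined once on the reference structure as lining-atom lists
and tracked by that fixed list; per-snapshot re-detection is deliberately
not performed, so the crmsd series of a cavity always refers to the same
atoms. Two filters precede all analysis:

* **artefact filter** — removes atoms whose names are arbitrary within
  chemically symmetric groups and would inflate rmsd-type descriptors:
  Val CG1/CG2, Leu CD1/CD2, Asp OD1/OD2, Glu OE1/OE2, Arg NH1/NH2,
  Phe CD1/CD2/CE1/CE2, Tyr CD1/CD2/CE1/CE2. Some legacy pipelines list the
  Asp/Glu pairs under other names (Asp O1/O2, Glu OD1/OD2);
  `ARTEFACT_ATOMS_AS_PRINTED` reproduces that variant, the default removes
  the chemically intended pairs under standard PDB naming.
* **size filter** — keeps cavities with ≥ 30 lining atoms *and* ≥ 5
  distinct residues (thresholds inclusive). The two filters commute.

Inter-cavity distance is the Euclidean distance between lining-atom
centroids, computed on the reference snapshot (the one conformation shared
by all pairs). Distance profiles divide per-bin pair counts by the squared
bin-centre distance to remove the volume effect.

The bundled gap-sphere detector is optional plumbing for users without an
external cavity program: candidate spheres seeded at atom-pair midpoints
are shrunk until no atom penetrates (van der Waals radii C 1.7, N 1.55,
O 1.52, S 1.8 Å; default otherwise 1.7), kept above a minimum radius
(default 1.0 Å, cap 4.0 Å), merged by single linkage, and converted to
lining-atom lists (atoms within sphere radius + vdW + 0.5 Å). It makes no
attempt to reproduce any particular production cavity program's contouring.

## Shape series

crmsd is computed after optimal proper superposition (Kabsch, reflection
corrected via the smallest singular value), implemented with the trace
identity rmsd² = (|Xc|² + |Yc|² − 2Σσ̃)/N so whole series are evaluated
with one batched SVD. For a cavity the superposition uses only that
cavity's lining atoms (cavity-local fit — rigid displacement of the cavity
within the protein does not register, only shape change); the global
descriptor uses all Cα atoms. Properties guaranteed by construction and
enforced by tests: symmetry to 1e-9 Å, invariance under proper rigid
transforms of either argument, and crmsd ≤ unsuperposed rmsd.

## Coupling statistic and significance

Each series is discretized into B = max(2, ⌊√(n/5)⌋) equal-frequency rank
bins (B = 4 at n = 100); ties are broken by original index with a stable
sort, so binning is deterministic. From the joint histogram the plug-in
mutual information I and marginal entropies H(X), H(Y) (nats) give

    r = I / sqrt(H(X) H(Y)) ∈ [0, 1],

exactly 1 for any strictly monotone transform pairing and 0 for
independence; a constant series has zero entropy and is defined to give
r = 0 with a warning. Rank binning makes r invariant to strictly monotone
transforms of either series, which has a useful computational consequence:
under the permutation null every non-degenerate series maps onto the same
multiset of bin labels, so the null distribution of r depends only on
(n, B). One empirical null (default 10⁵ shuffles, configurable; 10³ in the
fast simulations) is therefore generated per series length and shared by
all pairs; p-values use the add-one estimator p = (1 + #{r_null ≥ r_obs}) /
(1 + n_perm) and are never exactly zero. A per-pair shuffle path is kept
for non-rank statistics (|Pearson r| is available as a drop-in
alternative).

P-values are Benjamini–Hochberg adjusted (statsmodels) with the family
defined as all cavity pairs of one protein in one replica. A pair is a CSC
when its adjusted p ≤ α (default 0.05) in both replicas; in
single-trajectory mode the replica filter is skipped and results are
flagged. A member cavity counts as "Cα-correlated" (for the class-0/1/2
annotation) when its cavity–Cα permutation p ≤ α in every replica.

**Resolution interaction worth knowing:** with m candidate pairs the BH
step-up can only ever reject if min p ≤ α·k/m for some rank k, and the
add-one permutation floor is 1/(n_perm+1). With m = 45 and a single true
coupling, n_perm must be ≥ 900 for a discovery to be possible at α = 0.05;
the defaults (10⁵) are far above this, but scaled-down runs should respect
it.

## Persistence

Moving-window traces recompute r inside windows of `window` snapshots
(default 100 = 20 ns at 200 ps) advanced by `stride` (default 1; overlap
gives maximally smooth traces). The persistence statistic f is the fraction
of window positions with r strictly above a threshold (defaults 0.25 and
0.5 — the quarter and mid points of the correlation range); f is monotone
non-increasing in the threshold. Histograms of f over pairs, and
neighbour / non-neighbour splits, are descriptive outputs. A window-size
harness reports (not asserts) f across sizes {20, 30, 40, 50}.

## Conservation between structures

Atom-equivalence maps are consumed from a two-structure TSV so any external
aligner can feed the pipeline; when the structures share residue numbering,
`ca_kabsch_map` pairs identical atom identities after verifying the
Cα-superposition crmsd is below a ceiling (default 5 Å) and refuses
otherwise. Cavities are matched one-to-one by *maximum coincidence* of
mapped lining atoms. Coincidence maximization is solved exactly (Hungarian
assignment) rather than by a greedy descending-count pass: greedy can be
trapped by a single large entry that blocks two medium ones (e.g. the
matrix [[10, 9], [9, 1]]), and the exact optimum is both deterministic and
validated against exhaustive enumeration in the tests. Zero-coincidence
matches are never made. A CSC is conserved when both member cavities are
mapped and the mapped pair is a CSC in the other structure. Site overlap is
a plain set test: one member cavity's residues intersect the functional
site and the other's the allosteric site (either assignment; both sites
inside one cavity does not count).

## Synthetic data generator

The generator reproduces the *statistical* structure the analysis must
detect, not protein physics (no force field, solvent or energetics).

* **Geometry.** Cavities are Fibonacci-sphere shells of 36 pseudo-atoms
  (6 residues) of radius 4 Å on a coarse grid, plus a 20-atom Cα scaffold;
  all defaults pass the cavity filters, and 10 cavities yield the standard
  45 candidate pairs. Designated neighbour pairs are moved to shell-radius·√2
  separation and share the 12 shell atoms nearest the shell-intersection
  circle — a shared wall. At that circle the two radial directions are
  orthogonal, so the wall's squared displacement adds positively correlated
  variance to both cavities' crmsd (at the antipodal geometry the
  contributions cancel and no neighbour effect would exist).
* **Dynamics.** Each cavity's shell breathes radially by
  amplitude·(baseline + s_c(t)) with amplitude 0.5 Å and baseline 2 (in
  latent sd units). Planted coupled pairs share a latent:
  s_c = ρ·z_pair + √(1−ρ²)·ε_c (default ρ 0.95 for "strong" planting);
  independent cavities use s_c = ε_c; regime switching restricts ρ to a
  snapshot interval. All latents are AR(1) with lag-1 autocorrelation
  φ = 0.5 — MD shape series are autocorrelated, and this choice
  deliberately stresses the permutation null (below). The baseline models
  the structural drift real trajectories show: crmsd fluctuates about a
  positive plateau rather than returning to zero, which keeps the cavity's
  crmsd monotone in its breathing amplitude; planted pairs then reach
  r ≈ 0.4–0.6, the range real couplings occupy, whereas a zero-baseline
  (fold-around-zero) generator caps them near 0.25. Per-atom Gaussian
  jitter (σ = 0.1 Å), an independent Cα wobble (0.3 Å) and a global
  rigid-body wander (random rotation ≤ 0.3 rad plus translation, exercising
  crmsd invariance) are superimposed. Replicas share the planted structure
  and differ only in noise streams, emulating independent simulation
  replicas statistically.
* **Ground truth.** Every run emits a manifest (planted pairs with ρ and
  active interval, neighbour pairs, seed); fixture bundles for the
  scenarios `null`, `coupled`, `regime-switch`, `neighbours` and
  `ortholog-pair` are written as TSV/JSON and regenerate byte-identically
  from a seed. A statistical-level shortcut (`generate_series_set`)
  produces crmsd-like series directly for large simulations.

What passing tests on this generator do **not** show about real data: real
cavities deform anisotropically, exchange lining atoms, and sit in a
correlated elastic network, so effect sizes and the neighbour effect are
stylized; solvent-mediated couplings and multi-domain boundary effects are
entirely absent.

## Statistical limitations

The permutation null shuffles whole-series order, i.e. it assumes
exchangeability. For autocorrelated series (φ > 0) this null is
anticonservative: two independent AR(1) series co-occupy rank bins in runs,
inflating the observed MI relative to the shuffled null, so the realized
false-discovery proportion after BH exceeds its nominal level — the
acceptance script's false-discovery quantity, computed at φ = 0.5, reports
this honestly, and the test suite demonstrates nominal control when the
null is exchangeable (φ = 0). The replica-conservation filter is the
protocol's practical defence: a false positive must recur in two
independent noise realizations, which squares its probability, and the
null-scenario CSC rate is correspondingly near zero. A block-shuffle null
that preserves short-range autocorrelation is the natural extension and is
deliberately not implemented here, to keep the significance machinery
exactly as described above.

Other numerical choices: p-values are never 0 (add-one estimator);
r is clipped to [0, 1] against round-off and returns exactly 1 for
identical label vectors; degenerate inputs (constant series, < 3 atoms,
< 20 snapshots, empty traces) raise typed errors rather than propagating
NaNs; all simulations accept a single integer seed and are bit-reproducible
(fixture bundles, pipeline tables and provenance headers contain no
timestamps).

## Problem sizes in the shipped simulations

The test-suite and acceptance simulations use 10-cavity proteins,
100-snapshot replicas (500 for persistence scenarios), 10³ permutation
samples and 50–200 repetitions — sizes chosen so the full statistical
behaviour (null calibration, power at ρ = 0.95, regime detection) is
measurable while a complete run stays in the minutes range on one core.
The pipeline defaults (10⁵ permutations) match the protocol intended for
real trajectories.
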