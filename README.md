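# cavicorr

Cavity-coupling analysis for protein trajectories.

Protein cavities host functional sites, allosteric effector sites and the
interactions of a protein with its environment. During native-state
dynamics the shapes of different cavities can fluctuate in a coordinated
way, and such cavity–cavity couplings are candidate seeds for allosteric
regulation. `cavicorr` takes per-snapshot coordinates of a protein (from
molecular dynamics or an experimental ensemble) together with cavity
definitions, and identifies which cavity pairs are statistically coupled,
where those couplings come from structurally, and how they persist over
time — including a synthetic-trajectory generator so that the whole
pipeline is testable without running MD.

## Method

**Shape descriptor.** Each cavity is a fixed list of lining atoms defined
on the relaxed reference structure (symmetry-ambiguous atoms such as Val
CG1/CG2 or Arg NH1/NH2 are removed; cavities with < 30 atoms or < 5
residues are discarded). For every snapshot *t* the cavity's conformation
is superposed onto its reference conformation with the Kabsch algorithm
and its shape deviation recorded as

&nbsp;&nbsp;&nbsp;&nbsp;crmsd(t) = [ (1/N) Σ<sub>j</sub> d<sub>j</sub>² ]<sup>1/2</sup>,

where N is the number of superposed atom pairs and d<sub>j</sub> the
post-fit distance of atom *j* from its reference position. The same
descriptor over all Cα atoms gives the global backbone series.

**Coupling statistic.** For a cavity pair (C<sub>i</sub>, C<sub>j</sub>)
the association between their crmsd series is a normalized
mutual-information correlation: each series is discretized into B
equal-frequency rank bins (B = 4 at n = 100), and

&nbsp;&nbsp;&nbsp;&nbsp;r = I(X; Y) / √(H(X)·H(Y)) ∈ [0, 1],

which is 0 for independent series and exactly 1 when one series is a
strictly monotone transform of the other.

**Significance protocol.** (1) r and a permutation p-value (default 10⁵
random samples; the rank-binned null depends only on the series length, so
one empirical null is shared by all pairs) are computed for every pair in
every simulation replica. (2) P-values are Benjamini–Hochberg adjusted per
replica and pairs with adjusted p > 0.05 discarded. (3) A pair is a **CSC**
(cavity pair with significant correlation) only if it survives in *both*
replicas. CSCs are then annotated with neighbourhood (≥ 1 shared lining
atom), shared-atom percentage (normalized to mean cavity size), centroid
distance, and how many member cavities correlate with the Cα trace (class
0/1/2).

**Persistence.** For long trajectories a window (default 100 snapshots)
slides along the series and r is recomputed at each position; the fraction
f<sub>ij</sub> of window positions with r above a threshold (defaults 0.25
and 0.5) summarizes how persistently a pair is coupled, with
neighbour/non-neighbour splits and histograms.

**Conservation.** Given a second (e.g. orthologous) structure and an
atom-equivalence map from any structural aligner (or the bundled
Cα-superposition identity mapper), cavities are matched one-to-one by
maximum lining-atom coincidence, and CSCs whose mapped pair is also a CSC
in the second structure are reported as conserved. Cavity residue sets can
be intersected with functional-site / allosteric-site annotations.

## Worked example

```python
from cavicorr import generate_protein, generate_trajectory, PlantedCoupling
from cavicorr.pipeline import run_csc, RunConfig

ref, cavities = generate_protein(n_cavities=10, seed=42)
trajs, truth = generate_trajectory(
    ref, cavities,
    planted=[PlantedCoupling(("c01", "c02"), rho=0.95)],
    n_snapshots=100, seed=42,
)
run = run_csc(trajs, cavities, RunConfig(n_perm=1000, seed=42))
for csc in run.cscs:
    r1, r2 = csc.results
    print(f"CSC {csc.pair[0]}-{csc.pair[1]}: r = {r1.r:.2f}/{r2.r:.2f} "
          f"(adj. p = {r1.p_adj:.3f}/{r2.p_adj:.3f}), "
          f"neighbours = {csc.neighbour}, distance = {csc.distance:.1f} A, "
          f"Ca class = {csc.ca_class}")
```

prints

```
CSC c01-c02: r = 0.50/0.55 (adj. p = 0.045/0.022), neighbours = False, distance = 24.3 A, Ca class = 0
```

i.e. out of the 45 candidate pairs of this 10-cavity toy protein, exactly
the planted pair is recovered: its shape series correlate at r ≈ 0.5 in
both replicas, the coupling survives FDR adjustment and the
replica-conservation filter, the two cavities share no lining atom
(non-neighbours, centroids 24 Å apart) and neither tracks the global
backbone (class 0) — a long-range coupling not explained by atom sharing.

The same analyses are available from a shell via the `cavicorr` command
(subcommands `synth`, `cavities`, `series`, `csc`, `persistence`,
`conserve`), all reading and writing plain TSV/JSON.

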