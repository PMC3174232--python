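# Methods

`namsite` post-processes ensemble blind docking against nicotinic
acetylcholine receptor (nAChR) extracellular domains (ECDs) to locate a
negative-allosteric-modulator binding site, and carries the two
companion analyses such a study needs: geometric descriptors of agonist
binding and C-loop closure, and MM-PBSA-style binding-free-energy
aggregation with convergence auditing. This note records the models,
parameter choices and numerical conventions the package commits to, and
what the synthetic data does and does not establish.

## Consensus-site identification

**Within-conformation clustering.** Docking a ligand repeatedly to one
receptor conformation yields a cloud of poses. Poses are grouped by a
greedy leader pass over their heavy-atom centroids: visited
best-docking-energy-first (input order when energies are absent), a
pose joins the first cluster whose current centroid lies within the
tolerance (default 4 Å), else founds a new cluster. Two choices here
were genuinely open and are recorded in the output metadata:

- *Visiting order.* Energy-ordered greedy clustering is the convention
  of the standard docking engines whose output this stage consumes, so
  best-energy-first is the default; it also makes the pass fully
  deterministic without a seed.
- *Centroid update.* The cluster centroid is the running mean of its
  members, updated as poses join. The fixed-founder alternative
  under-merges elongated pose clouds; the running mean tracks them.

For focused docking the membership test is instead all-atom coordinate
RMSD (default tolerance 2 Å) against the cluster's *founder* pose — no
superposition, because docked poses already share the receptor frame,
and no running mean, because an RMSD between a pose and an averaged
rigid shape is ill-defined.

**Contact fingerprints.** Receptor conformations drift and rotate
between snapshots, so clusters from different conformations are
compared not in Cartesian space but by the set of receptor residues
any member pose touches: a residue is in the fingerprint when any of
its heavy atoms lies within the contact cutoff (default 5 Å) of any
ligand heavy atom. Hydrogens are excluded on both sides — their
positions in modelled structures are force-field artifacts. The
per-cluster residue list is the union over member poses by default
(an intersection mode exists for stricter cores). Residue identity is
`(chain, number, insertion code)` *without* the residue name, so
in-silico point mutants keep comparable fingerprints at the same site.

**Merging.** Two clusters belong to the same docking position when
their fingerprints share at least the merge threshold (default 65%) of
their residues. "Share" needs a denominator; the package defaults to
`|a ∩ b| / min(|a|, |b|)` because nested contact zones from
differently-sized clusters at one pocket should merge, and exposes
Jaccard as an alternative rather than deciding silently. Consensus
sites are the connected components of the pairwise-overlap graph —
single-linkage, the minimal closure of a pairwise rule. Clusters with
empty fingerprints (poses far from the receptor) carry no contact
information and become singleton sites.

**Site statistics.** Population fraction = site poses / all dockings
performed; recurrence = fraction of (ligand, conformation) pairs
contributing at least one top-k cluster to the site. Only the top-k
clusters per conformation (default k = 4) enter merging, mirroring how
such surveys are actually read.

## Geometric descriptors

**C-loop closure.** The flexible C loop on the principal face of the
agonist site closes over agonists and stays open around antagonists.
Closure is measured as the Cα–Cα distance between the loop-tip cysteine
(canonical α C191) and residue 58 on the complementary subunit's β2
strand. Canonical labels resolve to concrete residues through an
explicit numbering map; resolution fails loudly rather than guessing,
because cross-species numbering offsets are a classic silent error.

Classification uses closed intervals calibrated on AChBP crystal
structures: agonist 7.72–8.19 Å, partial agonist 9.75–12.30 Å,
antagonist/unbound 12.88–16.05 Å, peptidic antagonist 17.50–19.24 Å.
These ranges do not tile the line. A distance falling in a gap returns
`indeterminate(flanking states)` instead of being snapped to the
nearest range — nearest-neighbour assignment would fabricate a
confidence the calibration set does not support.

**Agonist anchoring.** Two distances quantify agonist stability: the
ligand's charged nitrogen to the Trp148 backbone carbonyl oxygen
(hydrogen bond), and to the centre of mass of the nine heavy atoms of
the Trp148 indole (cation-π). The indole centre is mass-weighted, not a
centroid, so the NE1 nitrogen pulls it slightly off the geometric
centre. Angle-dependent interaction criteria are out of scope: these
are stability *distances*, not interaction detectors.

**RMSD analyses.** Per-residue profiles superpose each frame globally
onto the reference via a Kabsch fit on backbone atoms (N, CA, C, O
where present), then report frame-averaged all-atom RMSD per residue;
a no-superposition flag covers the raw-coordinate reading, since
published traces rarely state their fitting convention. Whole-selection
traces accept an exclusion list (e.g. an unstable Cys loop) and fit on
the *included* selection only, so the excluded region influences
neither the alignment nor the deviation.

**Series statistics.** Sliding averages run over trailing windows
(output length n − w + 1) and return per-window SDs alongside the
means; summaries report mean with *population* SD formatted to two
decimals ("12.97 (1.49)"), optionally with the series minimum. At the
1500+ frame lengths these series have, sample vs population SD differs
in the third decimal and the population convention matches MD block
statistics.

## Binding-energy aggregation

Inputs are per-frame component series from an MM-PBSA-style
decomposition; no force-field, Poisson–Boltzmann or normal-mode term is
computed here. ΔG = mean(ΔH) − mean(TΔS) over all frames. The entropy
term is handled as a series that degrades gracefully to a single
repeated value, since entropy estimates are commonly computed far more
sparsely than enthalpies. Dispersion is reported as the SD of
sliding-window means (window 200 frames), the convention appropriate
to strongly autocorrelated MD data; raw-frame SD sits behind a flag.

Convergence is audited two ways: cumulative means at every checkpoint
(default every 100 frames), and the absolute change in cumulative mean
between two sampling depths (default frames 1400 → 1500). For
stationary noise that delta shrinks as O(1/n); for an equilibration
drift the cumulative mean approaches the asymptote monotonically. One
published component pair (ΔH −32.29, TΔS −17.37) is internally
inconsistent with its printed total at two decimals (−14.91); the
package always reports the recomputed value (−14.92) rather than
matching a rounding.

## Synthetic data: what it emulates and what it does not

The generators produce every input the pipeline consumes, with the
statistical structure the analysis assumes:

- **Receptor**: a deterministic ring of five chains (default 20
  residues each, ring radius 30 Å); each residue is a rigid group with
  a designated Cα, a backbone O displaced toward the pore, one
  sidechain pseudo-atom and one hydrogen. This preserves exactly what
  the pipeline reads — chain/residue identity, heavy-atom geometry,
  designated atoms — and nothing else.
- **Ensemble**: frame 0 is the input model; later frames add i.i.d.
  Gaussian jitter (default 0.3 Å) per coordinate. Real conformational
  drift is correlated and directional; jitter suffices to perturb
  fingerprints without destroying them.
- **Pose clouds**: 100 poses per conformation; each pose is a rigid
  5-atom ligand (4 heavy + 1 H), randomly oriented. With probability
  0.8 a pose's centroid is drawn from one of three planted sites
  (weights 0.5/0.3/0.2, isotropic 1 Å noise) at the inner wall of the
  ring, 3 Å inside the Cα radius so every site contacts residues;
  otherwise it is uniform in a spherical annulus spanning the pore
  lumen (0.25–0.70 of the ring radius), emulating the scattered decoy
  poses such surveys see on the inside of the doughnut-shaped domain.
  Planted poses draw energies from N(−7, 0.5) kcal/mol, decoys from
  N(−4, 0.5), so best-energy-first visiting and tie-breaking are both
  exercised at a realistic docking-score scale. True labels ride along
  on every pose for scoring.
- **Distance and energy series**: deterministic profile (constant,
  relaxation, or exponential equilibration drift) plus i.i.d. Gaussian
  noise.

All randomness flows from the scenario seed; identical scenario and
seed give byte-identical outputs.

What passing on this data shows: the bookkeeping, geometry and
statistics of the pipeline are correct — partitioning, fingerprint
construction, merging closure, recovery of planted structure at the
predicted binomial error. What it does not show: robustness to
correlated conformational change, anisotropic pose clouds, flexible
ligands, or the fingerprint drift of a genuinely breathing pocket.
Conclusions about real receptors still require real ensembles.

## Problem sizes and numerical conventions

The standard synthetic study is 26 conformations × 100 poses (2600
dockings) — large enough that the 3-standard-error recovery bands are
a few tenths of a percent wide, small enough that a 20-seed replication
of the full pipeline runs in seconds. Monte-Carlo checks of the
convergence delta use 2000–3000 replicates of length-1500 series.

Ties in top-k selection break by lower mean docking energy, then
earlier founding. Sorting of clusters and sites is by population
(descending) with deterministic secondary keys, so repeated runs are
byte-identical. PDB coordinates round-trip at the format's 3-decimal
precision; structure reading is strict (malformed records and
cross-MODEL topology changes are errors naming the offender, not
warnings). Altloc handling takes the highest-occupancy conformer.
PDBQT support is read-only and minimal: atom records and the energy
remark; torsion-tree records are ignored.

## Known limitations

- The consensus stage assumes a shared residue-identity space across
  conformations (one MD trajectory's topology); it does not align
  sequences across different constructs.
- Leader clustering is order-dependent by construction; the
  energy-ordered visiting rule pins the order down, but a different
  convention (e.g. size-ordered re-clustering) would shift cluster
  boundaries for marginal poses.
- `min`-denominator overlap can chain small nested fingerprints into a
  large site through single linkage; raising the threshold or choosing
  Jaccard tightens this at the cost of splitting drifting pockets.
- The state classification is only as good as its calibration
  intervals; values in the gaps are reported as indeterminate, and no
  probability is attached to any label.
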