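# Methods

## Problem and model

`zincsite` predicts which CHED residues (Cys, His, Glu, Asp — the residue
types that coordinate nearly all protein zinc) bind a *functional* zinc ion
in a 3D structure. The model is a binary random-forest classifier over
per-residue feature vectors; its contributions are (i) the labeling and
zinc-site taxonomy applied to structures, (ii) the heterogeneous feature
families extracted over a 9-residue sequence window, (iii) a two-step
feature-selection algorithm driven by random-forest importances and a
combined cross-validation score, and (iv) evaluation at a fixed-precision
operating point with ROC AUC and Davis–Goadrich recall–precision area at
residue and protein levels.

### Labeling and zinc taxonomy

A residue binds a zinc ion when the minimum distance over its non-hydrogen
atoms (backbone and side chain; the inclusive reading of "atoms of the
residue") to the ion is ≤ 3.0 Å, boundary inclusive. Each zinc ion is
classed by its number of coordinating residues: Zn1, Zn2, Zn3 (typically
catalytic), Zn4plus (≥ 4, typically structural; zincs with more than four
coordinating residues are binned here as structural rather than given their
own class). A zinc is reclassified *co-catalytic* when a second metal ion
(Mg, Mn, Fe, Co, Ni, Cu, Ca or Cd) lies within 5.0 Å and the zinc's 3.0 Å
coordination shell contains a bridging water oxygen, or one of its
coordinating residues also reaches into the second metal's shell. The
co-catalytic rule is a geometric operationalization — the literature
describes the concept but no algorithm — so both radii and the metal set
are configuration-exposed. Functional zinc = Zn3, Zn4plus or co-catalytic;
a CHED residue is a positive sample iff it coordinates at least one
functional zinc. Zn1/Zn2 ions are surface artifacts without biological
function and contribute no positives.

Parsing uses gemmi (first MODEL only; hydrogens discarded; alternate
locations resolved to the highest-occupancy conformer, ties keeping the
lexicographically first altloc code; non-standard residues map to `X` and
are never CHED).

### Feature families

All per-residue features are projected onto a sliding window of 9 residues
(V1..V9, V5 the centered residue); out-of-chain window slots are
zero-padded and masked.

- **Sequence** — PSI-BLAST PSSM log-odds over the window (9 × 20 = 180
  columns, named `PSSM_<n>_<aa>`); a conservation score per position,
  defined as Shannon information content R_i = log2(20) + Σ_j p_ij log2
  p_ij over the profile's weighted observed frequencies (the published
  description names the frequencies but the formula itself is ambiguous;
  information content is bounded, comparable across positions, and a plain
  negative-entropy variant is available by flag); chain composition
  (CHED percentage, per-type fractions of the chain's CHED set, Glu and
  CHED counts, His fraction, chain length). Frequencies are taken from the
  profile's percentage matrix ÷ 100, never re-derived from log-odds;
  all-zero percentage rows (a PSI-BLAST artifact at gapless columns) are
  kept as zeros and flagged, scoring 0 conservation.
- **Structure/exposure** — Shrake–Rupley SASA on a deterministic 960-point
  Fibonacci sphere lattice with vdW radii C 1.7, N 1.55, O 1.52, S 1.8 Å
  (1.8 Å default for unknown elements) and probe 1.4 Å; absolute polar
  side-chain accessibility (sum of per-atom SASA over side-chain N/O, the
  NACCESS-style all-polar row); a distance-only hydrogen-bond count
  (inter-residue N/O–N/O pairs within 3.5 Å — hydrogens are absent, so the
  full donor–acceptor angular criteria are not applicable); half-sphere
  exposures and coordination number in a 13 Å Cα sphere, the up/down split
  taken against the Cα→Cβ vector with a tetrahedrally reconstructed
  pseudo-Cβ for Gly; residue depth as mean distance of residue atoms (and
  of Cα alone) to the SASA lattice's accessible points, which serve as the
  molecular-surface proxy — this is why SASA is computed natively rather
  than delegated to a surface program that discards its lattice.
- **Network** — a Cα contact graph at 6.5 Å (inclusive) per chain, with
  per-node degree, clustering coefficient, closeness (Wasserman–Faust
  scaling so disconnected graphs stay finite), unnormalized betweenness,
  eccentricity, Harary status (sum of geodesics within the component) and
  ego-network density ("density" read as a node-level quantity; the
  chain-level graph density is also emitted). All seven metrics are
  windowed; which were windowed originally is unrecorded, so windowing all
  is the inclusive choice.
- **Pass-through** — externally computed columns (disorder, aggregation,
  B-factor, DSSP-style features) join on the sample key and are tagged
  `passthrough` in the matrix metadata.

### Dataset construction

One row per CHED residue, keyed `chain:seq_index`. Negatives are
subsampled uniformly to 6:1 against positives before selection and
training (benchmarks in this domain run ≈100:1 before subsampling;
prediction on the full background is supported at predict time). The
independent split cuts the shuffled positives into six near-equal parts,
one part becoming the independent test positives; negatives are drawn 6:1
independently for the two pools, and five CV folds partition the training
rows at random at residue level (chain-level grouping is available because
residue-level splitting can leak chain context between folds). Missing
values are imputed with medians computed on training rows only.

### Two-step feature selection

Step 1: the mean decrease in Gini impurity (MDGI) of each feature,
averaged over repeated independently-seeded forests, standardized to
Z-scores with the population standard deviation; the top 70 Z-scores form
the optimal feature candidates (ties at the boundary keep the
lexicographically smaller name).

Step 2: backward stepwise elimination on the combined score
AUC × recall × precision, with recall and precision read at the
fixed-precision-0.75 operating point on each held-out fold, fold scores
averaged, and the whole evaluation repeated over independently seeded
refits (100 in the full protocol). A feature is removed only when its
removal *strictly* increases the combined score; elimination stops when no
removal improves it. Two candidate orders are provided: `greedy`
(evaluate every remaining feature each round, remove the best improver —
the default) and `ranked` (a single pass in ascending-MDGI order, removing
each feature whose removal improves the score). Traces record every
round's candidate scores, the removal, and the surviving set; runs with
fewer than 100 repetitions are flagged `reduced_cost`.

**Desk-scale behaviour.** With the reduced protocol (5 repetitions,
100 trees) the combined-score estimate on a ~150-sample matrix has a
standard deviation (~0.03) far above the true effect of removing a single
redundant column (~0.002). Strict-improvement acceptance combined with
best-of-round selection then suffers a winner's curse: an accepted removal
inflates the current score and elimination halts after a few rounds. The
stable long elimination trajectories reported for this class of method
require the full 100-repetition protocol on benchmark-sized data (hours to
days of CPU). Tests therefore exercise the reduced `ranked` protocol and
the retention property (informative columns survive elimination); the
noise-discard rate achievable at full scale is not reproducible at desk
scale, and the corresponding acceptance check documents this by failing
under the reduced conditions.

### Classification and evaluation

The classifier is a random forest (500 trees by default, √p feature
subsampling, no class weighting) whose score is the fraction of trees
voting zinc-binding. The operating threshold is fixed-precision: among all
cut points achieving precision ≥ 0.75, the one maximizing recall (if none
achieves the target, the maximal-precision threshold is returned flagged).
By default the threshold is chosen on the evaluation set itself, mirroring
fixed-precision method comparisons; a train-derived threshold mode exists
for deployment-style assessment. ROC AUC uses the rank-based
(Mann–Whitney, average ranks on ties) estimator. The recall–precision
area uses Davis–Goadrich interpolation: between achievable (TP, FP) cut
points, intermediate integer TP counts receive proportional FP increments,
the curve is extended to recall 0 at the first interpolated precision, and
the area is the trapezoid over the polyline — under heavy imbalance this
avoids the optimism of linear PR interpolation. Protein-level evaluation
scores a chain by its maximum residue score; at a threshold, a zinc-binding
chain is a true positive when at least one of its true binding residues is
predicted positive, a false negative otherwise, and a non-binding chain
with any predicted positive is a false positive. Per-residue-type (C/H/E/D)
sub-reports partition the residue-level confusion counts.

## Synthetic data

The generator produces ground-truthed inputs so every stage is testable
offline: self-avoiding random-walk Cα traces (3.8 Å steps, ≥ 4.0 Å
non-consecutive clearance) with backbone plus minimal side-chain atoms;
planted sites placing one zinc near the centroid of 3–4 CHED residues and
re-posing their donor atoms 2.0–2.3 Å from the ion (distance-only
geometry — the labeling rule is distance-only, so angular realism is not
needed); decoy residues kept ≥ 3.2 Å from every zinc so ground truth is
exact by construction; PSI-BLAST-format profiles whose binding-site
columns put 0.9 of the probability mass on the true residue while
background columns are near-uniform Dirichlet draws; and pure-noise
feature columns for selection tests. Defaults: 8 chains of 40–60 residues,
one 4-residue site per chain, 30 % background CHED frequency.

What the fixtures do *not* emulate: realistic folds and packing densities
(exposure features are valid geometry but not protein-like distributions),
chains without any zinc (every default chain carries a site, so the toy
class imbalance is ≈4:1 rather than the benchmark's 100:1 — the 6:1
subsampler then keeps all negatives with a warning), evolutionary
correlation structure in profiles, apo/holo structural rearrangement.
Passing tests demonstrate the machinery is correct and that the pipeline
recovers planted signal; they do not certify real-data accuracy.

## Numerical choices

- Distance boundaries (labeling 3.0 Å, contacts 6.5 Å, H-bonds 3.5 Å) are
  inclusive; kd-tree queries add 1e-9 and re-check exactly.
- The SASA lattice is seedless and deterministic; per-atom areas are exact
  under rigid motion when the lattice is co-rotated, and total area agrees
  within lattice tolerance otherwise. The isolated-atom value is within
  2 % of the closed form 4π(r + 1.4)².
- Z-scores use the population SD; identical importances across all
  features raise an error rather than dividing by zero.
- 0/0 metric ratios are defined as 0 and flagged `degenerate`.
- All stochastic steps take explicit seeds; repeated-forest seeds are
  spawned from one `SeedSequence` and reused across candidate sets within
  a selection round so comparisons are paired.

## Problem sizes used in tests

Unit tests run on 2–3-chain fixtures and ≤ 150-sample matrices. The
acceptance suite uses: 100 random ≤ 8-node graphs for the metric oracle;
30-point score sets for ROC/PR oracles; 8-chain fixtures over 10 seeds for
the end-to-end cross-validated AUC; the reduced selection protocol
(5 repetitions, 100 trees, 5 folds, ranked order) over 5 seeds for the
planted-recovery check; and 20 seeds for the label-permutation null.

## Known limitations

- The hydrogen-bond count is distance-only and over-counts relative to
  angular criteria; it is a feature, not a structural annotation.
- Residue depth against the SASA point cloud is coarser than a triangulated
  molecular surface (adequate at feature granularity).
- Co-catalytic detection is an approximation; site classes other than the
  residue-count classes depend on its two radii.
- mmCIF input, biological-assembly expansion and symmetry mates are out of
  scope; structures are read as deposited, PDB format only.
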