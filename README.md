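# zincsite

Zinc is the most common transition metal in deposited protein structures,
with catalytic, structural and regulatory roles. `zincsite` predicts which
CHED residues (Cys, His, Glu, Asp — the residue types that coordinate
nearly all protein zinc) bind a *functional* zinc ion, for structural
bioinformaticians annotating structures of unknown function and for anyone
benchmarking metal-site predictors.

The method is an integrative random-forest framework:

1. **Labeling** — a residue binds zinc when any non-hydrogen atom lies
   within 3 Å of the ion; each ion is classed Znx by its number of
   coordinating residues, with a geometric rule for co-catalytic zinc
   (zinc acting with a second metal through a bridging water or side
   chain). Functional zinc = Zn3, Zn4+ or co-catalytic; residues
   coordinating one are the positive class.
2. **Features** — over a 9-residue window (V1..V9, V5 the center):
   PSI-BLAST PSSM log-odds (9 × 20 = 180 columns), conservation score
   R_i = log2 20 + Σ_j p_ij log2 p_ij, chain composition; Shrake–Rupley
   SASA, polar side-chain accessibility, H-bond counts, half-sphere
   exposures (HSEAU/HSEAD/HSEBU/HSEBD), coordination number, residue
   depth; and Cα contact-graph (6.5 Å) node metrics — degree, clustering,
   closeness, betweenness, eccentricity, status, ego density.
3. **Two-step feature selection** — mean-decrease-Gini importances
   standardized to Z-scores, z_i = (x_i − x̄)/σ, keep the top 70; then
   backward stepwise elimination driven by the cross-validated combined
   score AUC × REC × PRE at the fixed precision of 0.75, removing a
   feature only when the score strictly increases.
4. **Classification & evaluation** — a random forest scoring residues by
   vote fraction, thresholded at the fixed-precision operating point;
   REC/PRE/SPE/FPR, rank-based ROC AUC, and the area under the
   recall–precision curve with Davis–Goadrich interpolation, at residue
   and protein level (a protein counts as recovered when at least one of
   its true binding residues is predicted).

A seeded synthetic generator plants ground-truthed zinc sites in
random-walk backbones and writes matching PSSMs, so the whole pipeline is
testable without downloading structures.

## Worked example

```sh
zincsite simulate --out demo --seed 21 --n-chains 3
zincsite extract-features --structures demo/structures --pssms demo/pssms \
    --out demo/matrix.tsv
zincsite build-dataset --matrix demo/matrix.tsv --out demo/dataset --seed 21
zincsite train --matrix demo/dataset/benchmark.tsv --out demo/model.joblib \
    --trees 200 --seed 3
zincsite predict --model demo/model.joblib \
    --matrix demo/dataset/independent.tsv --out demo/preds.tsv
zincsite evaluate --preds demo/preds.tsv --out demo/reports
```

which prints, stage by stage:

```
wrote 3 structures, 12 planted binding residues -> demo
47 CHED samples x 352 features -> demo/matrix.tsv
only 35 negatives available for target 72; keeping all
training 33 rows, independent 14 rows -> demo/dataset
trained on 33 samples, 352 features -> demo/model.joblib
14 predictions -> demo/preds.tsv
residue REC 1.000 PRE 1.000 AUC 1.000 AURPC 1.000; protein REC 1.000 -> demo/reports
```

The fixture plants one 4-residue zinc site per chain (12 positive CHED
residues among 47); the toy chains carry fewer background CHED decoys than
6 per positive, so the subsampler keeps all 35 negatives with a warning.
A forest trained on the benchmark rows separates the planted sites in the
held-out split perfectly — the planted conservation contrast makes this an easy regime,
by design. `demo/reports/residue_report.tsv` holds the confusion counts,
REC/PRE/SPE/FPR, AUC and AURPC; the protein report aggregates chains by
their best-scoring residue.

The same steps run on real inputs: point `--structures` at PDB files and
`--pssms` at PSI-BLAST ASCII profiles named `<chain>.pssm`; externally
computed features (disorder, aggregation, B-factor) join via
`--passthrough table.tsv`.

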