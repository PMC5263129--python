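# scqpcr

Analysis toolkit for **single-cell RT-qPCR expression panels**: it converts
raw quantification-cycle (Cq) values into transcripts per cell, quantifies
how total transcript levels track cell-cycle phase and cell size, classifies
individual cells into cell states with random-forest ensembles, distills
minimal predictive gene signatures by recursive feature elimination (RFE),
discovers cell subpopulations by a PCA / Ward / self-organizing-map
consensus, and condenses the signature into a per-cell **cell-cycle index**
with an estimated G1→S crossover point.

It is aimed at groups profiling tens-to-hundreds of single cells over
~100-gene qPCR panels (e.g. BioMark-style dynamic arrays), where data are
reported as absolute molecules per cell without cross-cell normalization.
A synthetic-data generator with known ground truth (planted informative
genes, dropout, transcriptional-bursting skew, planted subpopulations)
makes every stage testable end to end.

## The model in brief

**Preprocessing.** A Cq value is anchored to absolute scale by the
convention Cq 25 = 1 molecule; values above the cap of 25 are replaced by
25, missing reactions are imputed at 0.5 molecules, and with 100% PCR
efficiency `molecules = 2^(25 − Cq)`. Totals per cell are plain row sums —
no reference-gene or library-size normalization.

**Classification.** For a pair of cell states (phases G1/S/G2M or sizes
small/large), a random forest of `n_trees` Gini-split trees is grown on
bootstrap samples of the cells × genes log2 matrix; out-of-bag (OOB)
predictions give a 2×2 confusion matrix, the OOB error, the balanced
accuracy (mean per-class recall), and a Fisher exact p on the confusion
matrix. An ensemble of `n_forests` independently seeded forests yields
mean ± SD for every statistic, and the per-split predictor count (mtry) is
selected as the smallest value minimizing a pilot ensemble's OOB error.
Genes must be detected in ≥50% of cells of at least one class to enter.

**RFE.** The least important gene (lowest mean decrease in Gini impurity)
is removed and the ensemble refit, down to one gene. The optimal signature
is the smallest gene set whose OOB error is within one ensemble SD of the
minimum; each signature gene carries a direction (+1 up toward the later
state, −1 down).

**Cell-cycle index.** For up-regulated genes *U* and down-regulated genes
*D* (G1 → S/G2M), each cell's index is

    index = ( Σ_{g∈U} log2 x_g − Σ_{g∈D} log2 x_g ) / (|U| + |D|)

G1 cells score low, G2/M cells high; sorting cells by index and fitting a
continuous two-segment (ramp-then-plateau) least-squares model estimates
the crossover point where proliferating cells enter the S/G2M plateau.

## Worked example

```python
from scqpcr.simulate import SimulationConfig, generate_dataset
from scqpcr.preprocess import cq_to_molecules, log2_matrix
from scqpcr.classify import train_forest_ensemble
from scqpcr.stats import total_transcripts, spearman_vs_factor, range_ratio

cfg = SimulationConfig(seed=1)          # 93 genes, 15 cells per phase x size group
cq, ann, truth = generate_dataset(cfg)
expr = cq_to_molecules(cq)              # Cq 25 = 1 molecule, missing -> 0.5
totals = total_transcripts(expr)
print("range ratio:", round(range_ratio(totals), 1))
rep = spearman_vs_factor(totals, ann, "phase")
print(f"Spearman rho (phase): {rep.rho:.2f} (p = {rep.p_value:.3g}, n = {rep.n_cells})")

log2 = log2_matrix(expr)
cells = ann.index[ann["phase"].isin(["G1", "G2M"])]
res = train_forest_ensemble(
    log2.loc[cells], ann.loc[cells, "phase"], class_order=("G1", "G2M"),
    n_forests=10, n_trees=200, mtry=9, seed=1,
)
print(res.summary())
```

prints

```
range ratio: 19.3
Spearman rho (phase): 0.15 (p = 0.151, n = 90)
Random-forest ensemble classification
=====================================================
Task:            G1 vs G2M
Genes:           93
Forests x trees: 10 x 200 (mtry=9)
-----------------------------------------------------
                     pred G1        pred G2M
true G1        28.90 ± 0.32     1.10 ± 0.32
true G2M        0.00 ± 0.00    30.00 ± 0.00
-----------------------------------------------------
OOB error:         0.0183 ± 0.0053
Balanced accuracy: 0.9817 ± 0.0053
Fisher exact p:    5.24e-16
=====================================================
```

The range ratio says the most transcript-rich of the 90 simulated cells
holds ~19× more total molecules than the poorest (heavy bursting skew);
the confusion matrix says on average 28.9 of 30 G1 cells and all 30 G2/M
cells are correctly recovered from their expression profile alone, with
ensemble SDs quantifying forest-to-forest variability.

A command-line interface mirrors the stages
(`scqpcr simulate | preprocess | stats | classify | rfe | subpop | index |
run-all`); `scqpcr run-all --config pipeline.yaml` executes the whole
workflow and writes provenance-stamped tables.

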