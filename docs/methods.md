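# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the known limitations of the package.

## Preprocessing model

Single-cell RT-qPCR reports one quantification cycle (Cq) per cell and
gene. The conversion to molecules per cell assumes:

- **anchor**: Cq 25 corresponds to one template molecule (instrument/panel
  calibration convention);
- **cap**: Cq values above 25 are replaced by 25, so every measured entry
  maps to ≥ 1 molecule;
- **imputation**: reactions with no detected amplification, and wells
  failing melting-curve QC, are set to 0.5 molecules — half the detection
  limit — and flagged as imputed in the detection mask;
- **efficiency**: with PCR efficiency E ∈ (0, 1],
  `molecules = (1 + E)^(anchor − min(Cq, cap))`; the default E = 1 makes
  one cycle exactly a factor of two.

All four constants are arguments of `cq_to_molecules` so their influence
can be probed; downstream results are insensitive to moderate changes
because every comparison is rank-based or within-panel. No cross-cell
normalization is applied anywhere: totals per cell are meaningful and are
analyzed as such.

"Detectable" means *measured* (non-missing, QC-pass). The detection filter
keeps a gene if it is measured in at least `min_fraction` (default 0.5) of
the cells of at least one class of the comparison at hand; imputed entries
never count toward detection.

Autoscaling (per-gene standardization to mean 0, sample SD 1, ddof = 1)
operates on log2 molecules. Multiplicative single-cell data are
approximately log-normal, so standardizing the log scale is the defensible
default; the caller can pass any matrix, so a linear-scale variant is a
one-line change. Zero-variance genes are dropped with a warning.

## Descriptive statistics

- Totals = row sums of the molecules matrix, imputed entries included
  (they represent the below-detection mass).
- Spearman correlations of totals against ordinal encodings: phase
  G1 = 1, S = 2, G2M = 3; size small = 1, large = 2; combined phase × size
  ordered small-G1 … large-G2M = 1 … 6 (size nested within phase). The
  combined ordering is a convention; it is configurable, and conclusions
  about "phase dominates size" are unaffected by the nesting order.
- The gene-pair census computes Spearman rho for all n(n−1)/2 unordered
  pairs; pairs involving a zero-variance gene are excluded from the
  positive-fraction numerator *and* denominator and reported separately.
- Mann-Whitney U tests are exact when the pooled sample is ≤ 25 and
  tie-free, otherwise the normal approximation with tie and continuity
  correction is used. Families of group comparisons are corrected by the
  Holm step-down procedure.

## Forest-ensemble classification

One task = one unordered pair of cell states, always two classes.
Forests use Gini-impurity splitting on bootstrap samples (scikit-learn
`RandomForestClassifier`); statistics come from out-of-bag predictions:
a cell is predicted by majority vote of the trees that did not see it.
Defaults are 1000 trees per forest and 100 forests per ensemble; all
reported statistics are ensemble mean ± SD. Cells never seen OOB (possible
only for very small forests) fall back to the majority training class.

mtry (predictors considered per split) is chosen by scanning a grid
(default 1 … n_genes) with a pilot sub-ensemble (default 10 forests per
candidate) and taking the *smallest* value attaining the minimal mean OOB
error; the full ensemble then runs at that mtry. The pilot/full split is
an explicit design choice — running the full 100-forest ensemble at every
mtry candidate would be two orders of magnitude slower for no accuracy
gain in the selection.

Fisher's exact test needs integer counts, so the single reported p-value
is computed on the ensemble-mean confusion matrix rounded to the nearest
integers; per-forest p-values are also retained
(`fisher_p_per_forest`) for callers who prefer aggregating p-values.

Class imbalance is left as-is (no resampling): the intended designs are
near-balanced (~15 vs ~15 cells), and balanced accuracy is the headline
metric precisely because it is insensitive to mild imbalance. Classes
below 5 cells are rejected — OOB estimation is meaningless there.

Seeding: a single master seed is expanded through `numpy.random
.SeedSequence` with a (stage, task, mtry, forest) key path, so any stage
can be re-run independently and reproduces bit-identically.

### Null-calibration caveat

On null data (two classes drawn from one distribution) the OOB error of
bagged trees is *pessimistically biased*: measured over 120 replicate
simulations (30 vs 30 cells, 20 noise genes, 10 forests × 200 trees) the
ensemble balanced accuracy has mean ≈ 0.47 and SD ≈ 0.08, and the
R randomForest implementation reproduces this. Consequently roughly
15–25% of null runs fall outside the band [0.4, 0.6]. This is a property
of the OOB estimator, not a defect of the pipeline; the Fisher-p null
calibration (p > 0.05 in > 90% of null runs) behaves as expected.

## Recursive feature elimination

Each cycle trains a full ensemble, records OOB error / balanced accuracy /
Fisher p / importances, and removes the gene with the lowest mean Gini
importance. Tie-breaks: larger importance SD is removed first, then the
lexicographically first gene id (documented, arbitrary). mtry is rescanned
every cycle by default; `rescan_stride` trades selection fidelity for
speed on large panels.

The **optimal signature** rule (default `oob_1sd`) takes the smallest gene
count whose mean OOB error is within one ensemble SD (at the minimizing
cycle) of the global minimum — the one-standard-error parsimony idea. Two
alternatives are provided (`oob_min`, `fisher_min`), and a consistency
flag records whether all three metrics (OOB min, balanced-accuracy max,
Fisher min) agree on the same cycle. Degenerate note: on perfectly
separable data with tiny ensembles the minimizing cycle can have SD = 0,
which collapses the tolerance and can select a larger signature; larger
ensembles or the `oob_min` rule avoid this.

Signature gene directions are signs of median log2 differences (later
class − earlier class), medians because the distributions are skewed;
zero median difference falls back to the mean, then to +1.

## Subpopulation discovery

The predictive (signature) genes define the feature space; the matrix is
autoscaled and clustered three ways: k-means on the 2-D PCA scores (the
automated stand-in for the manual gate an analyst would draw on a PCA
plot), Ward/Euclidean hierarchical clustering, and a 1-D Kohonen SOM.

The SOM is written in-package: `map_length` nodes (3–4) initialized
evenly spaced along PC1, sequential best-matching-unit training with a
rectangular neighborhood whose radius decays linearly from `neighbors`
(default 2) to 0 and a learning rate decaying linearly from 0.4 to 0 over
`iterations` (default 150) epochs. The original instrument-software decay
schedules are undocumented; linear decay with these endpoints is this
package's choice, and clustering results are insensitive to it on
well-separated data.

Each method designates its lowest-scoring cluster (by a per-cell score,
typically the mean autoscaled expression — low = low-transcription
candidate); cells placed in that cluster by ≥ 2 of the 3 methods form the
consensus subpopulation, with pairwise Jaccard agreement reported. In the
pipeline the gate operates within the target phase (default G1): the aim
is a sub-state of one phase, and clustering all cells at small k merely
rediscovers the phase partition.

The volcano procedure compares subpopulation members against the
remaining target-phase cells: per-gene log2 fold change as a difference
of group means of log2 molecules (means so a planted uniform shift is
recovered exactly; medians available), Mann-Whitney two-sided p, and a
Bonferroni family threshold α/n_tests (0.05/93 ≈ 0.00054 for a full
panel). Genes with |log2 FC| ≥ 1 ("at least two-fold") are colored green
(p below the family threshold), yellow (between the family threshold and
α), or red (above α); all others are "not-regulated". The total-transcript
contrast reports `100·(1 − mean(members)/mean(rest))` percent with a
Mann-Whitney p.

## Cell-cycle index and crossover

Index = (Σ log2 up-genes − Σ log2 down-genes) / (number of signature
genes), per cell, imputed values included. It is linear in log2
expression and negates under swapping the up/down sets (both are tested
invariants).

The crossover point — which interactive analyses typically annotate by eye
with guide lines — is operationalized as the knot of a continuous two-segment piecewise-linear
least-squares fit to the index values sorted ascending against rank:
basis (1, x, max(0, x − knot)), all candidate knots with ≥ 4 points per
segment scored by SSE. The reported crossover is the fitted index value
at the knot. A fit whose plateau slope is ≥ 50% of the rising slope is
flagged "no distinct crossover" (the pattern seen for uniformly
transitioning populations); a constant index yields a warning and no
estimate.

## Synthetic-data generator

The generator emulates the structure of sorted single-cell qPCR panels on
the log2-molecule scale:

    log2 m[c,g] = baseline_g + phase_g·step(c) + size_g·large(c)
                  + scale_c + ε[c,g]

- `baseline_g` uniform in `baseline_log2_mean ± baseline_log2_spread`
  (defaults 5 ± 2 log2 molecules — typical panel genes span ~1–100
  molecules);
- the first `n_informative_phase` genes carry ±`phase_fold_changes` log2
  per phase step (G1 = 0, S = 1, G2M = 2), alternating direction; the next
  `n_informative_size` genes respond to size analogously;
- `scale_c ~ N(0, cell_scale_sd)` is a global per-cell factor emulating
  transcriptional bursting; the default 0.8 log2 reproduces tens-fold
  max/min total-transcript ratios over ~90 cells. An optional
  `phase_scale_coupling` adds a per-step shift to the scale, reproducing
  the totals-vs-phase correlation of real panels;
- dropout: each entry is detected with logistic probability in log2
  molecules (slope 1, midpoint `detection_midpoint`, default 2 molecules —
  near the 1-molecule anchor); `None` disables dropout. The per-group
  detection rates of the real study are not published, so these defaults
  are the package's own and are not claimed to match any instrument;
- detected entries become `Cq = 25 − log2(m)` capped at 25 (high-Cq end
  only; negative Cq for very abundant transcripts is allowed); undetected
  entries are missing;
- an optional subpopulation spec shifts `round(fraction × n)` randomly
  chosen target-phase cells by a global log2 shift on all genes plus an
  extra marker shift on one gene (the marker shift stacks *on top of* the
  global shift, so a +1.5 marker on a −1 background nets +0.5 — an
  up-regulated outlier against a down-shifted profile).

Default group sizes are 15 cells per (phase × size) group, matching the
12–16-cell sorted groups of typical designs. Two canonical scenario
builders ship with the package: `null_config` (two same-distribution
classes, zero informative genes, no dropout — classifier calibration) and
`subpopulation_study_config` (93 genes, 12 phase genes at 1.5 log2/step,
a planted G1 subpopulation: 30% of G1 cells, −1 log2 global, +1.5 marker).
In the latter the residual cell-scale SD is 0.2 log2: the scenario models
the low-transcription state itself as the dominant within-phase scale
structure — the planted subpopulation is a distinct state, not a tail of
a continuum. The skewed-totals regime is the general defaults' job, not
this scenario's.

What the generator does **not** emulate: amplification curves,
preamplification bias, assay-specific efficiencies, gene-gene regulatory
correlation beyond the shared scale factor, cell-line differences, or
doublets. Passing tests therefore demonstrate that the pipeline recovers
planted structure under realistic noise, dropout and skew — not that any
particular biological dataset would yield the same gene lists.

## Problem sizes and runtime choices

The replicate studies in `scqpcr.evaluation` (shared by the test suite and
`scripts/acceptance.py`) use scaled-down ensembles — e.g. 10 forests × 200
trees for null calibration, 4 × 100 for RFE recovery with fixed
mtry = √p — because they estimate *calibration rates across replicate
simulations*, for which production-size ensembles only add Monte-Carlo
precision per replicate, not information. The acceptance script further
reduces replicate counts (30 null replicates, 15 RFE seeds, 10
subpopulation replicates) relative to the test suite (100/50/10).

## Known limitations

- OOB-based null balanced accuracy is pessimistically biased (see above).
- The `oob_1sd` rule degenerates when the best cycle has zero ensemble SD.
- The SOM uses a rectangular neighborhood and linear decay; other kernels
  (Gaussian) would change node trajectories but rarely final labels here.
- The crossover estimator assumes a single ramp-then-plateau shape; more
  complex index profiles (e.g. bimodal) yield a knot but the "distinct"
  flag and slopes must be inspected.
- Exact Mann-Whitney p-values are only used for tie-free pooled samples
  ≤ 25; with the 0.5-molecule imputation ties are common, where the
  corrected normal approximation is applied regardless of sample size.
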