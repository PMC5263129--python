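"""Replicated synthetic-data studies used to validate the whole pipeline.

Each routine generates data with known ground truth, runs the relevant
stages, and reports recovery/calibration statistics. Ensemble sizes default
to scaled-down values (fewer forests and trees than the 100 x 1000
production defaults) so that whole replicate suites remain tractable; the
statistics they estimate are calibration rates, not per-forest estimates,
and are insensitive to the ensemble size beyond added Monte-Carlo noise.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .classify import train_forest_ensemble
from .cycleindex import cell_cycle_index, crossover_point
from .preprocess import autoscale, cq_to_molecules, log2_matrix
from .rfe import optimal_signature, run_rfe
from .simulate import (
    GroupSpec,
    SimulationConfig,
    generate_dataset,
    null_config,
    subpopulation_study_config,
)
from .subpop import (
    consensus_subpopulation,
    pca_gate_clusters,
    som_clusters,
    ward_clusters,
)


def null_classification_calibration(
    n_reps: int = 100,
    n_forests: int = 10,
    n_trees: int = 200,
    mtry: int = 4,
    seed: int = 0,
) -> dict:
    """Classifier calibration under the null: two same-distribution classes.

    Returns the fraction of replicates whose ensemble balanced accuracy lies
    in [0.4, 0.6] and whose Fisher p exceeds 0.05.
    """
    in_band = 0
    fisher_ok = 0
    balaccs = []
    for r in range(n_reps):
        cq, ann, _ = generate_dataset(null_config(seed=child_seed(seed, "null-sim", r)))
        log2 = log2_matrix(cq_to_molecules(cq))
        res = train_forest_ensemble(
            log2, ann["phase"], class_order=("G1", "G2M"),
            n_forests=n_forests, n_trees=n_trees, mtry=mtry,
            seed=child_seed(seed, "null-fit", r),
        )
        balaccs.append(res.balanced_accuracy_mean)
        in_band += 0.4 <= res.balanced_accuracy_mean <= 0.6
        fisher_ok += res.fisher_p > 0.05
    return {
        "n_reps": n_reps,
        "balanced_accuracy_in_band_frac": in_band / n_reps,
        "fisher_p_above_alpha_frac": fisher_ok / n_reps,
        "balanced_accuracy_mean": float(np.mean(balaccs)),
    }


def _recovery_config(seed: int) -> SimulationConfig:
    # 3 informative genes at a 4-fold (2 log2) difference between G1 and
    # G2M (1 log2 per phase step), among 20 panel genes, 15 vs 15 cells
    return SimulationConfig(
        n_genes=20,
        n_informative_phase=3,
        phase_fold_changes=1.0,
        n_informative_size=0,
        groups=(GroupSpec("G1", "small", 15), GroupSpec("G2M", "small", 15)),
        seed=seed,
    )


def rfe_signature_recovery(
    n_seeds: int = 50,
    n_forests: int = 4,
    n_trees: int = 100,
    mtry: int = 4,
    seed: int = 0,
) -> dict:
    """Fraction of replicates whose optimal RFE signature contains at least
    two of the three planted genes."""
    hits = 0
    sizes = []
    for r in range(n_seeds):
        cq, ann, truth = generate_dataset(_recovery_config(child_seed(seed, "rfe-sim", r)))
        log2 = log2_matrix(cq_to_molecules(cq))
        trace = run_rfe(
            log2, ann["phase"], class_order=("G1", "G2M"),
            n_forests=n_forests, n_trees=n_trees, mtry=mtry,
            seed=child_seed(seed, "rfe-fit", r),
        )
        sig = optimal_signature(trace)
        sizes.append(sig.n_genes)
        hits += len(set(sig.genes) & set(truth.phase_genes)) >= 2
    return {
        "n_seeds": n_seeds,
        "recovery_frac": hits / n_seeds,
        "median_signature_size": float(np.median(sizes)),
    }


def subpopulation_recovery(n_reps: int = 10, seed: int = 0) -> dict:
    """Mean precision/recall of the PCA/Ward/SOM consensus against a planted
    low-transcription G1 subpopulation (30% of G1 cells, -1 log2 global
    shift, one up-regulated marker)."""
    precs, recs = [], []
    for r in range(n_reps):
        cq, ann, truth = generate_dataset(
            subpopulation_study_config(seed=child_seed(seed, "subpop-sim", r))
        )
        log2 = log2_matrix(cq_to_molecules(cq))
        g1 = ann.index[ann["phase"] == "G1"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scaled = autoscale(log2.loc[g1])
        score = scaled.mean(axis=1)
        results = [
            pca_gate_clusters(scaled, k=2, seed=child_seed(seed, "subpop-pca", r)),
            ward_clusters(scaled, k=2),
            som_clusters(scaled, map_length=3, seed=child_seed(seed, "subpop-som", r)),
        ]
        cons = consensus_subpopulation(results, score)
        truth_set = set(truth.subpop_members)
        tp = len(set(cons.members) & truth_set)
        precs.append(tp / len(cons.members) if cons.members else 0.0)
        recs.append(tp / len(truth_set))
    return {
        "n_reps": n_reps,
        "precision_mean": float(np.mean(precs)),
        "recall_mean": float(np.mean(recs)),
    }


def index_phase_ordering(seed: int = 0) -> dict:
    """Mean cell-cycle index per phase on data with planted directions."""
    cq, ann, truth = generate_dataset(subpopulation_study_config(seed=child_seed(seed, "idx")))
    log2 = log2_matrix(cq_to_molecules(cq))
    up = [g for g, d in truth.phase_genes.items() if d > 0]
    down = [g for g, d in truth.phase_genes.items() if d < 0]
    idx = cell_cycle_index(log2, up, down)
    means = idx.groupby(ann["phase"]).mean()
    return {
        "mean_index_G1": float(means["G1"]),
        "mean_index_S": float(means["S"]),
        "mean_index_G2M": float(means["G2M"]),
        "strictly_increasing": bool(means["G1"] < means["S"] < means["G2M"]),
    }


def crossover_recovery(
    knot: float = 2.0,
    n_ramp: int = 30,
    n_flat: int = 30,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> dict:
    """Changepoint recovery on a known ramp-then-plateau index sequence."""
    rng = np.random.default_rng(child_seed(seed, "knot"))
    y = np.r_[np.linspace(0.0, knot, n_ramp), np.full(n_flat, knot)]
    y = y + rng.normal(0, noise_sd, n_ramp + n_flat)
    fit = crossover_point(pd.Series(rng.permutation(y)))
    return {
        "true_knot": knot,
        "estimated_knot": float(fit.crossover),
        "abs_error": abs(float(fit.crossover) - knot),
        "distinct": bool(fit.distinct),
    }
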