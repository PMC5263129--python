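"""Recursive feature elimination over random-forest ensembles.

Starting from all N genes, each cycle trains a forest ensemble, records the
full classification statistics, and removes the gene with the lowest mean
Gini importance; iteration continues until one gene remains. Comparing
performance across cycles yields a minimal predictive gene signature: by
default the smallest gene set whose mean OOB error stays within one
ensemble SD of the global minimum (a parsimony rule in the spirit of the
one-standard-error rule for model selection). Signature genes carry a
direction (+1 up toward the later class, -1 down), estimated from median
log2 expression differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .classify import ForestEnsembleClassifier


@dataclass
class RFECycle:
    genes: tuple[str, ...]
    eliminated: str | None  # None in the final single-gene cycle
    mtry: int
    oob_error_mean: float
    oob_error_sd: float
    balanced_accuracy_mean: float
    balanced_accuracy_sd: float
    fisher_p: float
    importances_mean: pd.Series
    importances_sd: pd.Series


@dataclass
class RFETrace:
    """Full per-cycle record of one RFE run (cycle k holds N-k+1 genes)."""

    class_labels: tuple[str, str]
    cycles: list[RFECycle]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_genes": [len(c.genes) for c in self.cycles],
                "eliminated": [c.eliminated for c in self.cycles],
                "mtry": [c.mtry for c in self.cycles],
                "oob_error_mean": [c.oob_error_mean for c in self.cycles],
                "oob_error_sd": [c.oob_error_sd for c in self.cycles],
                "balanced_accuracy_mean": [c.balanced_accuracy_mean for c in self.cycles],
                "balanced_accuracy_sd": [c.balanced_accuracy_sd for c in self.cycles],
                "fisher_p": [c.fisher_p for c in self.cycles],
            }
        )


@dataclass
class GeneSignature:
    """Minimal ordered gene list for one task (most predictive first)."""

    task: tuple[str, str]
    genes: tuple[str, ...]
    directions: dict[str, int] | None
    n_genes: int
    oob_error_mean: float
    balanced_accuracy_mean: float
    fisher_p: float
    rule: str
    metrics_consistent: bool


def _pick_elimination(imp_mean: pd.Series, imp_sd: pd.Series) -> str:
    """Least important gene; ties -> larger importance SD, then gene id."""
    lo = imp_mean.min()
    tied = imp_mean.index[imp_mean == lo]
    if len(tied) == 1:
        return str(tied[0])
    hi_sd = imp_sd[tied].max()
    tied2 = [g for g in tied if imp_sd[g] == hi_sd]
    return sorted(tied2)[0]


def run_rfe(
    X: pd.DataFrame,
    y: Sequence,
    *,
    class_order: tuple[str, str] | None = None,
    n_forests: int = 100,
    n_trees: int = 1000,
    mtry: int | None = None,
    mtry_grid: Sequence[int] | None = None,
    pilot_forests: int = 10,
    rescan_stride: int = 1,
    seed: int = 0,
) -> RFETrace:
    """Iterate forest-ensemble training and least-important-gene removal.

    ``rescan_stride`` controls how often the mtry scan is repeated (1 = every
    cycle); between rescans the previous mtry is reused, clipped to the
    current gene count. A fixed ``mtry`` disables scanning entirely.
    """
    if X.shape[1] < 2:
        raise ValueError("RFE needs at least two genes")
    genes = list(X.columns)
    cycles: list[RFECycle] = []
    current_mtry: int | None = mtry
    k = 0
    while genes:
        if mtry is not None:
            use_mtry: int | None = min(mtry, len(genes))
            scan = False
        elif k % max(rescan_stride, 1) == 0 or current_mtry is None:
            use_mtry, scan = None, True
        else:
            use_mtry, scan = min(current_mtry, len(genes)), False
        model = ForestEnsembleClassifier(
            X[genes],
            y,
            class_order=class_order,
            n_forests=n_forests,
            n_trees=n_trees,
            mtry=use_mtry,
            mtry_grid=mtry_grid,
            pilot_forests=pilot_forests,
        )
        res = model.fit(seed=child_seed(seed, "rfe", k))
        current_mtry = res.mtry
        if len(genes) > 1:
            victim = _pick_elimination(res.importances_mean, res.importances_sd)
        else:
            victim = None
        cycles.append(
            RFECycle(
                genes=tuple(genes),
                eliminated=victim,
                mtry=res.mtry,
                oob_error_mean=res.oob_error_mean,
                oob_error_sd=res.oob_error_sd,
                balanced_accuracy_mean=res.balanced_accuracy_mean,
                balanced_accuracy_sd=res.balanced_accuracy_sd,
                fisher_p=res.fisher_p,
                importances_mean=res.importances_mean,
                importances_sd=res.importances_sd,
            )
        )
        if victim is None:
            break
        genes.remove(victim)
        k += 1
    return RFETrace(class_labels=model.class_labels, cycles=cycles)


def _consistency(trace: RFETrace, tol: float = 1e-12) -> bool:
    """Do OOB error, balanced accuracy and Fisher p agree on the best cycle?"""
    oob = np.array([c.oob_error_mean for c in trace.cycles])
    ba = np.array([c.balanced_accuracy_mean for c in trace.cycles])
    fp = np.array([c.fisher_p for c in trace.cycles])
    best_oob = set(np.flatnonzero(oob <= oob.min() + tol))
    best_ba = set(np.flatnonzero(ba >= ba.max() - tol))
    best_fp = set(np.flatnonzero(fp <= fp.min() + tol))
    return bool(best_oob & best_ba & best_fp)


def optimal_signature(
    trace: RFETrace,
    rule: str = "oob_1sd",
    X: pd.DataFrame | None = None,
    y: Sequence | None = None,
) -> GeneSignature:
    """Select the optimal signature size from an RFE trace.

    Rules: ``oob_1sd`` (default) — smallest gene count whose mean OOB error
    is within one ensemble SD (at the minimizing cycle) of the global
    minimum; ``oob_min`` — strict OOB minimum (smallest count on ties);
    ``fisher_min`` — strict Fisher-p minimum. If ``X`` and ``y`` are given,
    per-gene directions are attached.
    """
    oob = np.array([c.oob_error_mean for c in trace.cycles])
    sds = np.array([c.oob_error_sd for c in trace.cycles])
    fp = np.array([c.fisher_p for c in trace.cycles])
    if rule == "oob_1sd":
        i_min = int(np.argmin(oob))
        thr = oob[i_min] + sds[i_min]
        eligible = np.flatnonzero(oob <= thr)
    elif rule == "oob_min":
        eligible = np.flatnonzero(oob == oob.min())
    elif rule == "fisher_min":
        eligible = np.flatnonzero(fp == fp.min())
    else:
        raise ValueError(f"unknown signature rule {rule!r}")
    # later cycles have fewer genes; smallest gene count = largest cycle index
    chosen = trace.cycles[int(eligible.max())]
    imp = chosen.importances_mean
    ordered = tuple(sorted(chosen.genes, key=lambda g: (-imp[g], g)))
    directions = None
    if X is not None and y is not None:
        directions = signature_directions(X, y, ordered, class_order=trace.class_labels)
    return GeneSignature(
        task=trace.class_labels,
        genes=ordered,
        directions=directions,
        n_genes=len(ordered),
        oob_error_mean=chosen.oob_error_mean,
        balanced_accuracy_mean=chosen.balanced_accuracy_mean,
        fisher_p=chosen.fisher_p,
        rule=rule,
        metrics_consistent=_consistency(trace),
    )


def signature_directions(
    X: pd.DataFrame,
    y: Sequence,
    genes: Sequence[str],
    class_order: tuple[str, str],
) -> dict[str, int]:
    """Per-gene direction: sign of median log2 difference (later - earlier).

    Zero median difference falls back to the mean difference sign, then +1.
    """
    y = pd.Series(list(y), index=X.index)
    earlier, later = class_order
    missing = [g for g in genes if g not in X.columns]
    if missing:
        raise ValueError(f"signature genes absent from matrix: {missing}")
    out: dict[str, int] = {}
    for g in genes:
        a = X.loc[y == earlier, g].to_numpy(dtype=float)
        b = X.loc[y == later, g].to_numpy(dtype=float)
        d = np.median(b) - np.median(a)
        if d == 0:
            d = b.mean() - a.mean()
        out[g] = 1 if d >= 0 else -1
    return out
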