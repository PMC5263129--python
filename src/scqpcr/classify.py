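"""Pairwise random-forest ensemble classification of single cells.

Two cell states (e.g. G1 vs G2M, or small vs large) are compared at a time.
Each forest grows ``n_trees`` Gini-split trees on bootstrap samples; the
out-of-bag (OOB) predictions yield a 2x2 confusion matrix, the OOB error,
and the balanced accuracy. To expose model variance, an ensemble of
``n_forests`` independently seeded forests is grown and all statistics are
reported as ensemble mean +- SD. The number of candidate predictors per
split (mtry) is scanned over a grid using a pilot sub-ensemble and the
smallest mtry minimizing the mean OOB error is selected before the full
ensemble is run.

The model/results split follows the statsmodels convention:
``ForestEnsembleClassifier(X, y).fit(seed=...)`` returns a
``ForestEnsembleResult`` carrying estimates, spreads and ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier

from ._seeds import child_seed


def balanced_accuracy(confusion: np.ndarray) -> float:
    """Mean of per-class recalls from a 2x2 confusion matrix (rows = truth)."""
    c = np.asarray(confusion, dtype=float)
    if c.shape != (2, 2):
        raise ValueError("confusion matrix must be 2x2")
    row_sums = c.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError("confusion matrix has an empty true class")
    return float(np.mean(np.diag(c) / row_sums))


def fisher_exact_2x2(confusion: np.ndarray) -> float:
    """Two-sided Fisher exact p on an integer 2x2 confusion matrix."""
    c = np.asarray(confusion)
    if c.shape != (2, 2):
        raise ValueError("confusion matrix must be 2x2")
    if np.any(c < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    if not np.all(np.equal(np.mod(c, 1), 0)):
        raise ValueError("confusion matrix entries must be integers (round ensemble means first)")
    return float(sps.fisher_exact(c.astype(int), alternative="two-sided")[1])


@dataclass
class ForestEnsembleResult:
    """Ensemble-aggregated statistics for one two-class task."""

    class_labels: tuple[str, str]
    gene_ids: tuple[str, ...]
    n_forests: int
    n_trees: int
    mtry: int
    confusion_mean: np.ndarray  # rows = true class (labels order), cols = predicted
    confusion_sd: np.ndarray
    oob_error_mean: float
    oob_error_sd: float
    balanced_accuracy_mean: float
    balanced_accuracy_sd: float
    fisher_p: float
    importances_mean: pd.Series
    importances_sd: pd.Series
    mtry_scan: pd.DataFrame | None = None
    fisher_p_per_forest: np.ndarray | None = None

    def summary(self) -> str:
        a, b = self.class_labels
        cm, cs = self.confusion_mean, self.confusion_sd
        lines = [
            "Random-forest ensemble classification",
            "=" * 53,
            f"Task:            {a} vs {b}",
            f"Genes:           {len(self.gene_ids)}",
            f"Forests x trees: {self.n_forests} x {self.n_trees} (mtry={self.mtry})",
            "-" * 53,
            f"{'':12s}{'pred ' + a:>16s}{'pred ' + b:>16s}",
            f"{'true ' + a:12s}{cm[0,0]:>8.2f} ± {cs[0,0]:<5.2f}{cm[0,1]:>8.2f} ± {cs[0,1]:<5.2f}",
            f"{'true ' + b:12s}{cm[1,0]:>8.2f} ± {cs[1,0]:<5.2f}{cm[1,1]:>8.2f} ± {cs[1,1]:<5.2f}",
            "-" * 53,
            f"OOB error:         {self.oob_error_mean:.4f} ± {self.oob_error_sd:.4f}",
            f"Balanced accuracy: {self.balanced_accuracy_mean:.4f} ± {self.balanced_accuracy_sd:.4f}",
            f"Fisher exact p:    {self.fisher_p:.3g}",
            "=" * 53,
        ]
        return "\n".join(lines)


def _fit_one_forest(
    X: np.ndarray, y01: np.ndarray, n_trees: int, mtry: int, random_state: int
) -> tuple[np.ndarray, float, float, np.ndarray]:
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features=mtry,
        bootstrap=True,
        oob_score=True,
        random_state=random_state,
        n_jobs=1,
    )
    rf.fit(X, y01)
    proba = rf.oob_decision_function_
    never_oob = np.isnan(proba).any(axis=1)
    pred = np.zeros(len(y01), dtype=int)
    pred[~never_oob] = np.argmax(proba[~never_oob], axis=1)
    if never_oob.any():  # vanishingly rare for >= 50 trees; fall back to majority class
        pred[never_oob] = int(np.bincount(y01).argmax())
    confusion = np.zeros((2, 2), dtype=float)
    for t, p in zip(y01, pred):
        confusion[t, p] += 1
    oob_error = float(np.mean(pred != y01))
    balacc = balanced_accuracy(confusion)
    return confusion, oob_error, balacc, rf.feature_importances_


class ForestEnsembleClassifier:
    """Two-class random-forest ensemble model for cells x genes data.

    Parameters
    ----------
    X : DataFrame
        Cells x genes log2 expression (finite).
    y : Series or array
        Two-class labels aligned with ``X`` rows.
    class_order : optional pair
        (earlier, later) class labels, e.g. ("G1", "G2M"); defaults to the
        sorted unique labels. The confusion matrix rows follow this order.
    mtry : optional int
        Fix the predictor-subset size and skip the scan.
    mtry_grid : optional sequence
        Candidate mtry values; defaults to the full range 1..n_genes.
    pilot_forests : int
        Forests per mtry candidate during the scan.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: Sequence,
        class_order: tuple[str, str] | None = None,
        n_forests: int = 100,
        n_trees: int = 1000,
        mtry: int | None = None,
        mtry_grid: Sequence[int] | None = None,
        pilot_forests: int = 10,
    ) -> None:
        X = pd.DataFrame(X)
        if X.shape[1] == 0:
            raise ValueError("no genes left after filtering")
        if not np.isfinite(X.to_numpy(dtype=float)).all():
            raise ValueError("X must be finite")
        y = pd.Series(list(y), index=X.index)
        labels = sorted(y.unique()) if class_order is None else list(class_order)
        if len(labels) != 2 or set(y.unique()) != set(labels):
            raise ValueError(f"expected exactly two classes, got {sorted(y.unique())}")
        counts = y.value_counts()
        small = counts[counts < 5]
        if not small.empty:
            raise ValueError(
                f"class(es) {small.index.tolist()} have fewer than 5 cells; "
                "OOB estimation is unreliable below that"
            )
        self.X = X
        self.y = y
        self.class_labels = (str(labels[0]), str(labels[1]))
        self.y01 = (y == labels[1]).to_numpy().astype(int)
        self.n_forests = int(n_forests)
        self.n_trees = int(n_trees)
        self.mtry = mtry
        self.mtry_grid = mtry_grid
        self.pilot_forests = int(pilot_forests)

    def _scan_mtry(self, Xv: np.ndarray, seed: int) -> tuple[int, pd.DataFrame]:
        p = Xv.shape[1]
        grid = [m for m in (self.mtry_grid or range(1, p + 1)) if 1 <= m <= p]
        if not grid:
            raise ValueError("mtry grid is empty after clipping to the gene count")
        grid = sorted(set(grid))
        records = []
        for m in grid:
            errs = [
                _fit_one_forest(Xv, self.y01, self.n_trees, m,
                                child_seed(seed, "scan", m, f))[1]
                for f in range(self.pilot_forests)
            ]
            records.append((m, float(np.mean(errs))))
        scan = pd.DataFrame(records, columns=["mtry", "oob_error_mean"])
        best = scan["oob_error_mean"].min()
        # smallest mtry attaining the minimum (grid is ascending)
        chosen = int(scan.loc[scan["oob_error_mean"] == best, "mtry"].iloc[0])
        return chosen, scan

    def fit(self, seed: int = 0) -> ForestEnsembleResult:
        Xv = self.X.to_numpy(dtype=float)
        p = Xv.shape[1]
        scan_table = None
        if self.mtry is not None:
            mtry = int(min(self.mtry, p))
        else:
            mtry, scan_table = self._scan_mtry(Xv, seed)
        confusions, errors, balaccs, imps, fishers = [], [], [], [], []
        for f in range(self.n_forests):
            conf, err, ba, imp = _fit_one_forest(
                Xv, self.y01, self.n_trees, mtry, child_seed(seed, "ensemble", f)
            )
            confusions.append(conf)
            errors.append(err)
            balaccs.append(ba)
            imps.append(imp)
            fishers.append(fisher_exact_2x2(conf.astype(int)))
        confusions = np.stack(confusions)
        imps = np.stack(imps)
        conf_mean = confusions.mean(axis=0)
        fisher_p = fisher_exact_2x2(np.rint(conf_mean).astype(int))
        return ForestEnsembleResult(
            class_labels=self.class_labels,
            gene_ids=tuple(self.X.columns),
            n_forests=self.n_forests,
            n_trees=self.n_trees,
            mtry=mtry,
            confusion_mean=conf_mean,
            confusion_sd=confusions.std(axis=0, ddof=1) if self.n_forests > 1 else np.zeros((2, 2)),
            oob_error_mean=float(np.mean(errors)),
            oob_error_sd=float(np.std(errors, ddof=1)) if self.n_forests > 1 else 0.0,
            balanced_accuracy_mean=float(np.mean(balaccs)),
            balanced_accuracy_sd=float(np.std(balaccs, ddof=1)) if self.n_forests > 1 else 0.0,
            fisher_p=fisher_p,
            importances_mean=pd.Series(imps.mean(axis=0), index=self.X.columns),
            importances_sd=pd.Series(
                imps.std(axis=0, ddof=1) if self.n_forests > 1 else np.zeros(p),
                index=self.X.columns,
            ),
            mtry_scan=scan_table,
            fisher_p_per_forest=np.asarray(fishers),
        )


def train_forest_ensemble(
    X: pd.DataFrame,
    y: Sequence,
    *,
    class_order: tuple[str, str] | None = None,
    n_forests: int = 100,
    n_trees: int = 1000,
    mtry: int | None = None,
    mtry_grid: Sequence[int] | None = None,
    pilot_forests: int = 10,
    seed: int = 0,
) -> ForestEnsembleResult:
    """Functional wrapper: build the model and fit it in one call."""
    model = ForestEnsembleClassifier(
        X,
        y,
        class_order=class_order,
        n_forests=n_forests,
        n_trees=n_trees,
        mtry=mtry,
        mtry_grid=mtry_grid,
        pilot_forests=pilot_forests,
    )
    return model.fit(seed=seed)


def rank_importances(result: ForestEnsembleResult) -> list[str]:
    """Gene ids in descending mean Gini importance; ties broken by gene id."""
    s = result.importances_mean
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return list(order)
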