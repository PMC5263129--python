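"""Descriptive statistics on transcripts per cell.

Total transcript level per cell (the row sum over the whole gene panel),
Spearman rank correlations of totals against ordinal encodings of cell-cycle
phase and cell size, a census of pairwise gene-gene correlations, and
Mann-Whitney group comparisons with Holm-Bonferroni multiplicity control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

PHASE_CODE = {"G1": 1, "S": 2, "G2M": 3}
SIZE_CODE = {"small": 1, "large": 2}
# combined ordering: size nested within phase, small before large
COMBINED_CODE = {
    ("G1", "small"): 1,
    ("G1", "large"): 2,
    ("S", "small"): 3,
    ("S", "large"): 4,
    ("G2M", "small"): 5,
    ("G2M", "large"): 6,
}


@dataclass(frozen=True)
class CorrelationReport:
    encoding: str
    rho: float
    p_value: float
    n_cells: int


@dataclass
class PairwiseCorrelations:
    pairs: pd.DataFrame  # columns gene_a, gene_b, rho
    n_pairs: int  # all unordered pairs, defined or not
    n_undefined: int  # zero-variance pairs excluded from the census
    fraction_positive: float  # among defined pairs


def total_transcripts(expr) -> pd.Series:
    """Per-cell total molecules over all panel genes, imputed values included."""
    m = expr.molecules if hasattr(expr, "molecules") else expr
    totals = m.sum(axis=1)
    totals.name = "total_molecules"
    return totals


def encode_factor(
    ann: pd.DataFrame,
    encoding: str,
    combined_order: Mapping[tuple[str, str], int] | None = None,
) -> pd.Series:
    """Ordinal encoding of phase, size, or the combined phase x size factor."""
    if encoding == "phase":
        codes = ann["phase"].map(PHASE_CODE)
    elif encoding == "size":
        codes = ann["size"].map(SIZE_CODE)
    elif encoding == "phase_x_size":
        order = combined_order or COMBINED_CODE
        codes = pd.Series(
            [order[(p, s)] for p, s in zip(ann["phase"], ann["size"])], index=ann.index
        )
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    if codes.isna().any():
        bad = ann.index[codes.isna()].tolist()
        raise ValueError(f"encoding undefined for cells {bad}")
    return codes.astype(float)


def spearman_vs_factor(
    totals: pd.Series,
    ann: pd.DataFrame,
    encoding: str,
    combined_order: Mapping[tuple[str, str], int] | None = None,
) -> CorrelationReport:
    """Spearman rank correlation between totals and an ordinal factor encoding."""
    codes = encode_factor(ann.loc[totals.index], encoding, combined_order)
    if len(totals) < 3:
        raise ValueError("need at least three cells for a rank correlation")
    if codes.nunique() < 2:
        raise ValueError(f"encoding {encoding!r} is constant over these cells")
    rho, p = sps.spearmanr(totals.to_numpy(), codes.to_numpy())
    return CorrelationReport(encoding=encoding, rho=float(rho), p_value=float(p), n_cells=len(totals))


def pairwise_gene_correlations(matrix: pd.DataFrame) -> PairwiseCorrelations:
    """Spearman rho for every unordered gene pair, plus the positive fraction.

    Pairs involving a zero-variance gene have undefined rank correlation;
    they are excluded from both numerator and denominator of the positive
    fraction and counted separately.
    """
    n_cells, n_genes = matrix.shape
    if n_cells < 3 or n_genes < 2:
        raise ValueError("need at least three cells and two genes")
    with np.errstate(invalid="ignore"):
        rho_mat = sps.spearmanr(matrix.to_numpy(), axis=0).statistic
    if np.ndim(rho_mat) == 0:  # scipy collapses the 2-gene case to a scalar
        r = float(rho_mat)
        rho_mat = np.array([[1.0, r], [r, 1.0]])
    iu, ju = np.triu_indices(n_genes, k=1)
    rho = rho_mat[iu, ju]
    genes = matrix.columns.to_numpy()
    # zero-variance genes produce NaN correlations
    sd = matrix.to_numpy().std(axis=0)
    undef = (sd[iu] == 0) | (sd[ju] == 0)
    rho = np.where(undef, np.nan, rho)
    pairs = pd.DataFrame({"gene_a": genes[iu], "gene_b": genes[ju], "rho": rho})
    defined = pairs["rho"].notna()
    n_undef = int((~defined).sum())
    frac_pos = float((pairs.loc[defined, "rho"] > 0).mean()) if defined.any() else float("nan")
    return PairwiseCorrelations(
        pairs=pairs,
        n_pairs=len(pairs),
        n_undefined=n_undef,
        fraction_positive=frac_pos,
    )


def mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact for small tie-free samples, else
    normal approximation with tie and continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 25 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


def group_compare_mannwhitney(
    totals: pd.Series,
    groups: Mapping[str, Sequence[str]],
    comparisons: Sequence[tuple[str, str]],
    alpha: float = 0.05,
    correction: str = "holm_bonferroni",
) -> pd.DataFrame:
    """Pairwise Mann-Whitney tests with Holm step-down adjustment.

    ``groups`` maps group label -> cell ids; ``comparisons`` declares the
    family of group pairs tested together.
    """
    if correction not in ("holm_bonferroni",):
        raise ValueError(f"unknown correction {correction!r}")
    rows = []
    for a, b in comparisons:
        ids_a, ids_b = list(groups[a]), list(groups[b])
        if len(ids_a) < 2 or len(ids_b) < 2:
            raise ValueError(f"comparison ({a}, {b}): each group needs at least two cells")
        overlap = set(ids_a) & set(ids_b)
        if overlap:
            raise ValueError(f"comparison ({a}, {b}) has overlapping cells: {sorted(overlap)}")
        p = mannwhitney_p(totals.loc[ids_a].to_numpy(), totals.loc[ids_b].to_numpy())
        rows.append((a, b, len(ids_a), len(ids_b), p))
    table = pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "p_value"])
    reject, p_adj, _, _ = multipletests(table["p_value"], alpha=alpha, method="holm")
    table["p_adjusted"] = p_adj
    table["significant"] = reject
    return table


def range_ratio(totals: pd.Series) -> float:
    """Max/min ratio of per-cell totals (all positive by construction)."""
    vals = totals.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("totals must be strictly positive")
    return float(vals.max() / vals.min())
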