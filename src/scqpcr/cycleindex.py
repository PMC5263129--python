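"""Per-cell cell-cycle index and crossover-point estimation.

The index condenses a directed gene signature into one scalar per cell:
the sum of log2 expression over genes up-regulated from G1 toward S/G2M,
minus the sum over down-regulated genes, divided by the total number of
signature genes. G1 cells score low, G2/M cells high. Ordering cells by
index typically shows a rising G1 trend that enters a plateau around the
G1->S transition; the crossover point is operationalized here as the knot
of a continuous two-segment piecewise-linear least-squares fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


def cell_cycle_index(
    log2_expr: pd.DataFrame,
    up_genes: Sequence[str],
    down_genes: Sequence[str],
) -> pd.Series:
    """Index = (sum log2 up - sum log2 down) / (n_up + n_down), per cell.

    Imputed below-detection values (log2 = -1 under defaults) are included,
    matching the per-cell molecule accounting of the rest of the pipeline.
    """
    up, down = list(up_genes), list(down_genes)
    overlap = set(up) & set(down)
    if overlap:
        raise ValueError(f"genes in both up and down sets: {sorted(overlap)}")
    if not up and not down:
        raise ValueError("signature is empty")
    missing = [g for g in up + down if g not in log2_expr.columns]
    if missing:
        raise ValueError(f"signature genes absent from matrix: {missing}")
    n = len(up) + len(down)
    up_sum = log2_expr[up].sum(axis=1) if up else 0.0
    down_sum = log2_expr[down].sum(axis=1) if down else 0.0
    index = (up_sum - down_sum) / n
    index.name = "cell_cycle_index"
    return index


@dataclass
class CrossoverFit:
    """Two-segment piecewise-linear fit of the sorted index sequence."""

    crossover: float | None  # index value at the fitted knot
    knot_rank: int | None  # 0-based position of the knot in the sorted sequence
    rising_slope: float | None
    plateau_slope: float | None
    sse: float | None
    distinct: bool  # True when the plateau is clearly flatter than the rise
    message: str = ""


def crossover_point(
    index: pd.Series | Sequence[float],
    phases: Sequence[str] | None = None,
    min_segment: int = 4,
) -> CrossoverFit:
    """Estimate the index value where the sorted index enters a plateau.

    Cells are ordered by index; for every candidate knot position with at
    least ``min_segment`` points per segment, a continuous two-piece linear
    model (basis 1, x, max(0, x - knot)) is fit by least squares, and the
    knot minimizing the SSE is returned together with both segment slopes.
    A fit where the plateau slope is at least half the rising slope is
    flagged as "no distinct crossover".
    """
    values = np.asarray(pd.Series(index).to_numpy(), dtype=float)
    n = len(values)
    if n < 10:
        raise ValueError("need at least 10 cells to estimate a crossover")
    if phases is not None:
        if len(phases) != n:
            raise ValueError("phases must align with the index values")
        if len(set(phases)) < 2:
            raise ValueError("cells must span at least two phases")
    y = np.sort(values)
    if np.ptp(y) == 0:
        warnings.warn("constant index: crossover undefined", stacklevel=2)
        return CrossoverFit(None, None, None, None, None, False, "constant index")
    x = np.arange(n, dtype=float)
    candidates = range(min_segment - 1, n - min_segment)
    if len(list(candidates)) == 0:
        warnings.warn("too few cells per candidate segment: no estimate", stacklevel=2)
        return CrossoverFit(None, None, None, None, None, False, "too few cells per segment")
    best = None
    for i in range(min_segment - 1, n - min_segment):
        hinge = np.maximum(0.0, x - x[i])
        A = np.column_stack([np.ones(n), x, hinge])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, i, coef)
    sse, i, coef = best
    b0, b1, b2 = coef
    rising = float(b1)
    plateau = float(b1 + b2)
    knot_value = float(b0 + b1 * x[i])
    distinct = rising > 0 and plateau < 0.5 * rising
    msg = "" if distinct else "no distinct crossover: plateau slope close to rising slope"
    return CrossoverFit(
        crossover=knot_value,
        knot_rank=int(i),
        rising_slope=rising,
        plateau_slope=plateau,
        sse=sse,
        distinct=distinct,
        message=msg,
    )
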