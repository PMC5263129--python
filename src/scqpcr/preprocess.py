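"""Cq-to-molecule preprocessing for single-cell RT-qPCR panels.

Single-cell qPCR data are reported as transcripts per cell without any
cross-cell normalization. The conversion anchors absolute scale by the
convention that a quantification cycle (Cq) of 25 corresponds to one
molecule; Cq values above the cap (25) are replaced by the cap, missing
reactions are imputed at 0.5 molecules, and 100% PCR efficiency is assumed
so one cycle equals a factor of two. All of these constants are exposed so
their (small) impact on downstream analysis can be probed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class CqTable:
    """Raw cells x genes quantification-cycle values.

    ``values`` holds Cq with NaN for missing (undetected) reactions.
    ``qc_fail`` optionally flags wells with aberrant melting curves; flagged
    entries are treated as missing during conversion.
    """

    values: pd.DataFrame
    qc_fail: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.qc_fail is not None:
            if not self.qc_fail.index.equals(self.values.index) or not self.qc_fail.columns.equals(
                self.values.columns
            ):
                raise ValueError("qc_fail must share the Cq table's cells and genes")

    @property
    def cells(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns


@dataclass
class ExpressionMatrix:
    """Molecules per cell and gene, with the detection mask.

    ``detected`` is True where a molecule count was measured and False where
    the imputation constant was substituted. No cross-cell normalization is
    ever applied; totals and comparisons operate on absolute molecule counts.
    """

    molecules: pd.DataFrame
    detected: pd.DataFrame
    anchor: float = 25.0
    cap: float = 25.0
    efficiency: float = 1.0
    impute: float = 0.5

    def __post_init__(self) -> None:
        if not self.detected.index.equals(self.molecules.index) or not self.detected.columns.equals(
            self.molecules.columns
        ):
            raise ValueError("detection mask must share the matrix's cells and genes")

    @property
    def cells(self) -> pd.Index:
        return self.molecules.index

    @property
    def genes(self) -> pd.Index:
        return self.molecules.columns


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check the closed phase/size vocabularies and unique cell ids."""
    phases = {"G1", "S", "G2M"}
    sizes = {"small", "large"}
    if ann.index.has_duplicates:
        dupes = ann.index[ann.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate cell ids in annotation: {dupes}")
    bad_phase = set(ann["phase"].unique()) - phases
    if bad_phase:
        raise ValueError(f"unknown phase labels {sorted(bad_phase)}; expected {sorted(phases)}")
    if "size" in ann.columns:
        bad_size = set(ann["size"].dropna().unique()) - sizes
        if bad_size:
            raise ValueError(f"unknown size labels {sorted(bad_size)}; expected {sorted(sizes)}")
    return ann


def cq_to_molecules(
    cq: CqTable,
    anchor: float = 25.0,
    cap: float = 25.0,
    efficiency: float = 1.0,
    impute: float = 0.5,
) -> ExpressionMatrix:
    """Convert Cq values to molecules per cell.

    Present entries become ``(1 + efficiency) ** (anchor - min(Cq, cap))``;
    missing or QC-failed entries become the imputation constant and are
    flagged as not detected. Non-finite (infinite) Cq values are an error.
    """
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("PCR efficiency must lie in (0, 1]")
    vals = cq.values.to_numpy(dtype=float)
    inf_mask = np.isinf(vals)
    if inf_mask.any():
        i, j = np.argwhere(inf_mask)[0]
        raise ValueError(
            f"non-finite Cq for cell {cq.cells[i]!r}, gene {cq.genes[j]!r}"
        )
    missing = np.isnan(vals)
    if cq.qc_fail is not None:
        missing |= cq.qc_fail.to_numpy(dtype=bool)
    capped = np.minimum(vals, cap)
    molecules = np.power(1.0 + efficiency, anchor - capped)
    molecules = np.where(missing, impute, molecules)
    return ExpressionMatrix(
        molecules=pd.DataFrame(molecules, index=cq.cells, columns=cq.genes),
        detected=pd.DataFrame(~missing, index=cq.cells, columns=cq.genes),
        anchor=anchor,
        cap=cap,
        efficiency=efficiency,
        impute=impute,
    )


def filter_genes_by_detection(
    expr: ExpressionMatrix,
    cell_classes: Mapping[str, Sequence[str]],
    min_fraction: float = 0.5,
) -> list[str]:
    """Keep genes detected in at least ``min_fraction`` of one class's cells.

    ``cell_classes`` maps class label -> cell ids; a gene is retained iff the
    fraction of measured (non-imputed) entries within at least one class
    reaches ``min_fraction``. Returns retained gene ids in input order.
    """
    for label, ids in cell_classes.items():
        if len(ids) == 0:
            raise ValueError(f"class {label!r} contains no cells")
        missing = set(ids) - set(expr.cells)
        if missing:
            raise ValueError(f"class {label!r} names unknown cells: {sorted(missing)}")
    kept = []
    for gene in expr.genes:
        for ids in cell_classes.values():
            frac = expr.detected.loc[list(ids), gene].mean()
            if frac >= min_fraction:
                kept.append(gene)
                break
    return kept


def log2_matrix(expr: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2 molecules; imputed 0.5-molecule entries map to -1."""
    m = expr.molecules if isinstance(expr, ExpressionMatrix) else expr
    vals = m.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("molecule counts must be strictly positive before log2")
    return pd.DataFrame(np.log2(vals), index=m.index, columns=m.columns)


def autoscale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene to mean 0 and sample SD 1 across cells.

    Zero-variance genes carry no multivariate information and are dropped
    with a warning. Requires at least two cells.
    """
    if matrix.shape[0] < 2:
        raise ValueError("autoscaling requires at least two cells")
    sd = matrix.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(
            f"dropping {len(constant)} zero-variance gene(s) during autoscaling: {constant}",
            stacklevel=2,
        )
    keep = sd[sd > 0].index
    centred = matrix[keep] - matrix[keep].mean(axis=0)
    return centred / sd[keep]
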