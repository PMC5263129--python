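"""Delimited-text readers and writers for matrices, annotations and truth.

Matrices are cells-as-rows, genes-as-columns with a header row of gene ids
and a first column of cell ids; the delimiter (comma or tab) is
auto-detected on read. Missing Cq values are encoded as empty fields or
``NA``. Lines starting with ``#`` (e.g. the config-hash provenance header)
are ignored on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .simulate import GroundTruth


def _sep_for(path: Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=None,
        engine="python",
        comment="#",
        index_col=0,
        na_values=["", "NA"],
    )
    df.index.name = "cell_id"
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep=_sep_for(path), index_label="cell_id", na_rep="NA")


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#", index_col="cell_id")
    return df


def write_annotation(ann: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        ann.to_csv(fh, sep=_sep_for(path), index_label="cell_id")


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep=_sep_for(path), index=False)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "phase_genes": truth.phase_genes,
        "size_genes": truth.size_genes,
        "subpop_members": truth.subpop_members,
        "true_log2": {
            "cells": truth.true_log2.index.tolist(),
            "genes": truth.true_log2.columns.tolist(),
            "values": truth.true_log2.to_numpy().tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    mat = payload["true_log2"]
    return GroundTruth(
        phase_genes={k: int(v) for k, v in payload["phase_genes"].items()},
        size_genes={k: int(v) for k, v in payload["size_genes"].items()},
        subpop_members=list(payload["subpop_members"]),
        true_log2=pd.DataFrame(
            mat["values"],
            index=pd.Index(mat["cells"], name="cell_id"),
            columns=mat["genes"],
        ),
    )


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
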