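"""End-to-end orchestration: preprocess -> stats -> classify -> RFE ->
subpopulation -> cell-cycle index.

``PipelineConfig`` is schema-validated (unknown keys rejected) and fully
serialized into the output directory for provenance; every output table
carries the config hash as a comment header. Reruns with the same config
and seed produce byte-identical numeric tables.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import io as scio
from ._seeds import child_seed
from .classify import train_forest_ensemble
from .cycleindex import cell_cycle_index, crossover_point
from .preprocess import (
    CqTable,
    autoscale,
    cq_to_molecules,
    filter_genes_by_detection,
    log2_matrix,
    validate_annotation,
)
from .rfe import optimal_signature, run_rfe, signature_directions
from .stats import (
    group_compare_mannwhitney,
    pairwise_gene_correlations,
    range_ratio,
    spearman_vs_factor,
    total_transcripts,
)
from .subpop import (
    consensus_subpopulation,
    pca_gate_clusters,
    som_clusters,
    subpop_transcript_contrast,
    volcano,
    ward_clusters,
)

log = logging.getLogger("scqpcr")

_PHASES = {"G1", "S", "G2M"}
_SIZES = {"small", "large"}


class PreprocessParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    anchor: float = 25.0
    cap: float = 25.0
    efficiency: float = 1.0
    impute: float = 0.5
    min_detection_fraction: float = 0.5


class EnsembleParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_forests: int = 100
    n_trees: int = 1000
    pilot_forests: int = 10
    mtry: Optional[int] = None
    mtry_grid: Optional[list[int]] = None


class RFEParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rule: Literal["oob_1sd", "oob_min", "fisher_min"] = "oob_1sd"
    rescan_stride: int = 1
    n_forests: int = 100
    n_trees: int = 1000
    pilot_forests: int = 10
    mtry: Optional[int] = None


class ClusterParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pca_components: int = 2
    ward_k: int = 2
    som_map_length: int = 3
    som_neighbors: int = 2
    som_learning_rate: float = 0.4
    som_iterations: int = 150
    min_agree: int = 2


class TaskSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["phase", "size"]
    classes: tuple[str, str]

    @field_validator("classes")
    @classmethod
    def _check_classes(cls, v, info):
        return v

    def validate_labels(self) -> None:
        vocab = _PHASES if self.kind == "phase" else _SIZES
        for c in self.classes:
            if c not in vocab:
                raise ValueError(f"task classes: undefined {self.kind} label {c!r}")


def _default_tasks() -> list[TaskSpec]:
    return [
        TaskSpec(kind="phase", classes=("G1", "S")),
        TaskSpec(kind="phase", classes=("S", "G2M")),
        TaskSpec(kind="phase", classes=("G1", "G2M")),
        TaskSpec(kind="size", classes=("small", "large")),
    ]


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cq_path: Optional[str] = None
    ann_path: Optional[str] = None
    out_dir: Optional[str] = None
    preprocessing: PreprocessParams = PreprocessParams()
    tasks: list[TaskSpec] = Field(default_factory=_default_tasks)
    ensemble: EnsembleParams = EnsembleParams()
    rfe: RFEParams = RFEParams()
    clustering: ClusterParams = ClusterParams()
    subpop_target_phase: str = "G1"
    subpop_within_phase: bool = True
    index_signature: Literal["rfe"] = "rfe"
    seed: int = 0

    @field_validator("subpop_target_phase")
    @classmethod
    def _check_phase(cls, v):
        if v not in _PHASES:
            raise ValueError(f"subpop_target_phase: undefined phase label {v!r}")
        return v

    def model_post_init(self, _ctx) -> None:
        for t in self.tasks:
            t.validate_labels()


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _task_cells(ann: pd.DataFrame, task: TaskSpec) -> tuple[pd.Index, pd.Series]:
    col = task.kind
    if "treatment" in ann.columns:
        treated = ann["treatment"].astype(bool)
    else:
        treated = pd.Series(False, index=ann.index)
    mask = ann[col].isin(task.classes) & ~treated
    cells = ann.index[mask]
    return cells, ann.loc[cells, col]


def run_pipeline(
    config: PipelineConfig,
    cq: CqTable | None = None,
    ann: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute all stages; returns a report dict and writes tables if an
    output directory is configured."""
    t_start = time.time()
    if cq is None:
        if config.cq_path is None:
            raise ValueError("stage preprocess: no Cq table given (cq_path unset)")
        cq = CqTable(values=scio.read_matrix(config.cq_path))
    if ann is None:
        if config.ann_path is None:
            raise ValueError("stage preprocess: no annotation given (ann_path unset)")
        ann = scio.read_annotation(config.ann_path)
    ann = validate_annotation(ann)
    chash = scio.config_hash(config.model_dump())
    report: dict = {"config_hash": chash}

    # ---- preprocess -----------------------------------------------------
    pp = config.preprocessing
    expr = cq_to_molecules(cq, anchor=pp.anchor, cap=pp.cap, efficiency=pp.efficiency,
                           impute=pp.impute)
    log2 = log2_matrix(expr)
    report["expr"] = expr
    log.info("preprocess done (%.1fs)", time.time() - t_start)

    # ---- descriptive stats ---------------------------------------------
    t0 = time.time()
    totals = total_transcripts(expr)
    corr_rows = []
    for enc in ("phase_x_size", "phase", "size"):
        try:
            rep = spearman_vs_factor(totals, ann, enc)
            corr_rows.append((enc, rep.rho, rep.p_value, rep.n_cells))
        except (ValueError, KeyError) as e:
            log.warning("stats: skipping encoding %s (%s)", enc, e)
    corr_table = pd.DataFrame(corr_rows, columns=["encoding", "rho", "p_value", "n_cells"])
    pw = pairwise_gene_correlations(log2)
    phase_groups = {p: ann.index[ann["phase"] == p].tolist() for p in sorted(ann["phase"].unique())}
    comparisons = [("G1", "S"), ("S", "G2M"), ("G1", "G2M")]
    comparisons = [(a, b) for a, b in comparisons if a in phase_groups and b in phase_groups]
    mw_table = group_compare_mannwhitney(totals, phase_groups, comparisons)
    report["totals"] = totals
    report["correlations"] = corr_table
    report["pairwise"] = {
        "n_pairs": pw.n_pairs,
        "n_undefined": pw.n_undefined,
        "fraction_positive": pw.fraction_positive,
    }
    report["group_tests"] = mw_table
    report["range_ratio"] = range_ratio(totals)
    log.info("stats done (%.1fs)", time.time() - t0)

    # ---- classification + RFE ------------------------------------------
    t0 = time.time()
    class_rows = []
    signatures = {}
    for ti, task in enumerate(config.tasks):
        cells, labels = _task_cells(ann, task)
        classes = {c: labels.index[labels == c].tolist() for c in task.classes}
        genes = filter_genes_by_detection(expr, classes, pp.min_detection_fraction)
        if len(genes) < 2:
            raise ValueError(f"stage classify: task {task.classes}: fewer than 2 genes survive "
                             "the detection filter")
        X = log2.loc[cells, genes]
        ens = config.ensemble
        res = train_forest_ensemble(
            X, labels, class_order=task.classes,
            n_forests=ens.n_forests, n_trees=ens.n_trees, mtry=ens.mtry,
            mtry_grid=ens.mtry_grid, pilot_forests=ens.pilot_forests,
            seed=child_seed(config.seed, "classify", ti),
        )
        class_rows.append({
            "task": f"{task.classes[0]}_vs_{task.classes[1]}",
            "n_genes": len(genes),
            "mtry": res.mtry,
            "oob_error_mean": res.oob_error_mean,
            "oob_error_sd": res.oob_error_sd,
            "balanced_accuracy_mean": res.balanced_accuracy_mean,
            "balanced_accuracy_sd": res.balanced_accuracy_sd,
            "fisher_p": res.fisher_p,
        })
        report[f"classify_{task.classes[0]}_vs_{task.classes[1]}"] = res

        if task.kind == "phase":
            rp = config.rfe
            trace = run_rfe(
                X, labels, class_order=task.classes,
                n_forests=rp.n_forests, n_trees=rp.n_trees, mtry=rp.mtry,
                pilot_forests=rp.pilot_forests, rescan_stride=rp.rescan_stride,
                seed=child_seed(config.seed, "rfe", ti),
            )
            sig = optimal_signature(trace, rule=rp.rule, X=X, y=labels)
            signatures[sig.task] = sig
            report[f"rfe_{task.classes[0]}_vs_{task.classes[1]}"] = trace
    report["classification"] = pd.DataFrame(class_rows)
    report["signatures"] = signatures
    log.info("classify+rfe done (%.1fs)", time.time() - t0)

    # ---- subpopulation ---------------------------------------------------
    t0 = time.time()
    union_genes = sorted({g for sig in signatures.values() for g in sig.genes})
    if not union_genes:
        raise ValueError("stage subpop: no signature genes available")
    target = config.subpop_target_phase
    target_cells = ann.index[ann["phase"] == target]
    cl = config.clustering
    # the manual PCA gate of interactive workflows is replaced by a
    # clustering consensus; by default it operates within the target phase,
    # where the low-transcription state is a distinct cluster rather than a
    # phase-level split
    gate_cells = target_cells if config.subpop_within_phase else ann.index
    scaled = autoscale(log2.loc[gate_cells, union_genes])
    score = scaled.mean(axis=1)
    results = [
        pca_gate_clusters(scaled, k=cl.ward_k, n_components=cl.pca_components,
                          seed=child_seed(config.seed, "subpop")),
        ward_clusters(scaled, k=cl.ward_k),
        som_clusters(scaled, map_length=cl.som_map_length, neighbors=cl.som_neighbors,
                     learning_rate=cl.som_learning_rate, iterations=cl.som_iterations,
                     seed=child_seed(config.seed, "subpop-som")),
    ]
    consensus = consensus_subpopulation(results, score, min_agree=cl.min_agree)
    members = [c for c in consensus.members if c in set(target_cells)]
    remainder = [c for c in target_cells if c not in set(members)]
    report["consensus"] = consensus
    report["subpop_members"] = members
    if len(members) >= 3 and len(remainder) >= 3:
        vtable, vthr = volcano(log2, members, remainder)
        contrast, contrast_p = subpop_transcript_contrast(totals, members, remainder)
        report["volcano"] = vtable
        report["volcano_threshold"] = vthr
        report["subpop_contrast_percent"] = contrast
        report["subpop_contrast_p"] = contrast_p
    else:
        log.warning("subpop: consensus too small for volcano (%d members)", len(members))
    log.info("subpop done (%.1fs)", time.time() - t0)

    # ---- cell-cycle index ------------------------------------------------
    t0 = time.time()
    # direction of each union-signature gene from G1 toward the later phases
    y2 = pd.Series(["G1" if p == "G1" else "S/G2M" for p in ann["phase"]], index=ann.index)
    dirs = signature_directions(log2, y2, union_genes, class_order=("G1", "S/G2M"))
    up = [g for g, d in dirs.items() if d > 0]
    down = [g for g, d in dirs.items() if d < 0]
    index = cell_cycle_index(log2, up, down)
    fit = crossover_point(index, phases=ann["phase"].tolist())
    index_table = pd.DataFrame({
        "cell_id": index.index,
        "index": index.to_numpy(),
        "phase": ann["phase"].to_numpy(),
        "subpop": [c in set(members) for c in index.index],
    })
    report["index"] = index_table
    report["index_directions"] = dirs
    report["crossover"] = fit
    log.info("index done (%.1fs)", time.time() - t0)

    # ---- write bundle ----------------------------------------------------
    out = out_dir or config.out_dir
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(
            yaml.safe_dump({"config_hash": chash, **config.model_dump()}, sort_keys=True)
        )
        scio.write_table(corr_table, out / "correlations.csv", chash)
        scio.write_table(
            totals.rename("total_molecules").reset_index(), out / "totals.csv", chash
        )
        scio.write_table(mw_table, out / "group_tests.csv", chash)
        scio.write_table(report["classification"], out / "classification.csv", chash)
        sig_rows = [
            {"task": f"{t[0]}_vs_{t[1]}", "rank": i + 1, "gene": g,
             "direction": (s.directions or {}).get(g)}
            for t, s in signatures.items()
            for i, g in enumerate(s.genes)
        ]
        scio.write_table(pd.DataFrame(sig_rows), out / "signatures.csv", chash)
        for t, s in signatures.items():
            tr = report[f"rfe_{t[0]}_vs_{t[1]}"]
            scio.write_table(tr.as_frame(), out / f"rfe_{t[0]}_vs_{t[1]}.csv", chash)
        if "volcano" in report:
            scio.write_table(report["volcano"], out / "volcano.csv", chash)
        scio.write_table(
            pd.DataFrame({"cell_id": sorted(members)}), out / "subpop_members.csv", chash
        )
        scio.write_table(index_table, out / "cell_cycle_index.csv", chash)
    log.info("pipeline done (%.1fs total)", time.time() - t_start)
    return report
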