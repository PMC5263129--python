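"""Subpopulation discovery and characterization.

A refined PCA restricted to RFE-selected predictive genes exposes cell
subpopulations that the full panel hides; the candidate subpopulation is
cross-validated with Ward/Euclidean hierarchical clustering and a 1-D
Kohonen self-organizing map, and the consensus (cells placed in the
designated low-expression cluster by at least two of the three methods)
replaces the manual gate one would draw on a PCA plot. The subpopulation is
then characterized by a volcano procedure (log2 fold change vs Mann-Whitney
p with a Bonferroni family threshold) and a total-transcript contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from ._seeds import child_seed
from .stats import mannwhitney_p


@dataclass
class PCAEmbedding:
    scores: pd.DataFrame  # cells x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # genes x components


@dataclass
class ClusteringResult:
    method: str  # "pca", "ward", or "som"
    labels: pd.Series  # per-cell integer cluster label
    params: dict


@dataclass
class ConsensusResult:
    members: list[str]
    per_method_members: dict[str, list[str]]
    jaccard: pd.DataFrame


def pca_embed(X: pd.DataFrame, n_components: int = 2) -> PCAEmbedding:
    """PCA of an autoscaled matrix; component signs fixed so the
    largest-magnitude loading of each component is positive."""
    if X.shape[1] < n_components:
        raise ValueError("fewer genes than requested components")
    if X.shape[0] < 3:
        raise ValueError("need at least three cells")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X.to_numpy(dtype=float))
    loadings = pca.components_.T.copy()  # genes x comps
    for j in range(n_components):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    return PCAEmbedding(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(loadings, index=X.columns, columns=comp_names),
    )


def pca_gate_clusters(X: pd.DataFrame, k: int = 2, n_components: int = 2, seed: int = 0) -> ClusteringResult:
    """Automated stand-in for the manual PCA gate: k-means on the PCA scores."""
    emb = pca_embed(X, n_components=min(n_components, X.shape[1]))
    km = KMeans(n_clusters=k, n_init=10, random_state=child_seed(seed, "pca-gate"))
    labels = km.fit_predict(emb.scores.to_numpy()) + 1
    return ClusteringResult(
        method="pca",
        labels=pd.Series(labels, index=X.index),
        params={"k": k, "n_components": n_components},
    )


def ward_clusters(X: pd.DataFrame, k: int) -> ClusteringResult:
    """Agglomerative clustering with Ward's criterion on Euclidean distances."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > X.shape[0]:
        raise ValueError("k cannot exceed the number of cells")
    Z = linkage(X.to_numpy(dtype=float), method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusteringResult(method="ward", labels=pd.Series(labels, index=X.index), params={"k": k})


def som_clusters(
    X: pd.DataFrame,
    map_length: int = 3,
    neighbors: int = 2,
    learning_rate: float = 0.4,
    iterations: int = 150,
    seed: int = 0,
) -> ClusteringResult:
    """1-D Kohonen self-organizing map used as a clusterer.

    ``map_length`` nodes (typically 3-4) are initialized evenly spaced along
    the first principal component and trained by sequential best-matching-
    unit updates: for each presented cell the winning node and its
    neighborhood (radius decaying linearly from ``neighbors`` to 0 over the
    ``iterations`` epochs, rectangular kernel) move toward the cell with a
    learning rate decaying linearly from ``learning_rate`` to 0. Cells are
    labeled by their final best-matching node. Deterministic per seed.
    """
    n_cells = X.shape[0]
    if n_cells < map_length:
        raise ValueError("need at least as many cells as map nodes")
    Xv = X.to_numpy(dtype=float)
    rng = np.random.default_rng(child_seed(seed, "som"))

    if np.allclose(Xv.std(axis=0), 0):
        warnings.warn("constant data: all cells assigned to one SOM node", stacklevel=2)
        return ClusteringResult(
            method="som",
            labels=pd.Series(np.ones(n_cells, dtype=int), index=X.index),
            params={"map_length": map_length, "degenerate": True},
        )

    # initialize node weights evenly spaced along PC1
    emb = pca_embed(X, n_components=1)
    pc1 = emb.scores["PC1"].to_numpy()
    direction = emb.loadings["PC1"].to_numpy()
    centre = Xv.mean(axis=0)
    if map_length == 1:
        positions = np.array([0.0])
    else:
        positions = np.linspace(pc1.min(), pc1.max(), map_length)
    weights = centre[None, :] + positions[:, None] * direction[None, :]

    for t in range(iterations):
        frac = 1.0 - t / iterations
        lr = learning_rate * frac
        radius = neighbors * frac
        for i in rng.permutation(n_cells):
            x = Xv[i]
            bmu = int(np.argmin(((weights - x) ** 2).sum(axis=1)))
            node_idx = np.arange(map_length)
            within = np.abs(node_idx - bmu) <= radius
            weights[within] += lr * (x - weights[within])

    labels = np.array(
        [int(np.argmin(((weights - Xv[i]) ** 2).sum(axis=1))) + 1 for i in range(n_cells)]
    )
    return ClusteringResult(
        method="som",
        labels=pd.Series(labels, index=X.index),
        params={
            "map_length": map_length,
            "neighbors": neighbors,
            "learning_rate": learning_rate,
            "iterations": iterations,
            "seed": seed,
        },
    )


def _lowest_cluster(result: ClusteringResult, score: pd.Series) -> list[str]:
    """Cells in the cluster with the lowest mean of the per-cell score."""
    labels = result.labels
    means = score.groupby(labels).mean()
    target = means.idxmin()
    return sorted(labels.index[labels == target].tolist())


def consensus_subpopulation(
    results: Sequence[ClusteringResult],
    score: pd.Series,
    min_agree: int = 2,
) -> ConsensusResult:
    """Cells placed in the low-score cluster by at least ``min_agree`` methods.

    ``score`` is a per-cell scalar used to designate the target cluster in
    each partition (e.g. mean autoscaled expression over the signature
    genes, so the lowest cluster is the low-transcription candidate).
    Reports per-method membership and pairwise Jaccard agreement.
    """
    if len(results) < 2:
        raise ValueError("consensus needs at least two clustering results")
    universe = set(results[0].labels.index)
    for r in results[1:]:
        if set(r.labels.index) != universe:
            raise ValueError("clustering results must share the same cells")
    per_method = {r.method: _lowest_cluster(r, score) for r in results}
    counts: dict[str, int] = {}
    for members in per_method.values():
        for c in members:
            counts[c] = counts.get(c, 0) + 1
    members = sorted(c for c, n in counts.items() if n >= min_agree)
    methods = list(per_method)
    jac = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    for i, a in enumerate(methods):
        for j, b in enumerate(methods):
            if i < j:
                sa, sb = set(per_method[a]), set(per_method[b])
                union = sa | sb
                jac.loc[a, b] = jac.loc[b, a] = len(sa & sb) / len(union) if union else 1.0
    if not members:
        warnings.warn("no overlapping cluster across methods: empty consensus", stacklevel=2)
    return ConsensusResult(members=members, per_method_members=per_method, jaccard=jac)


def volcano(
    log2_expr: pd.DataFrame,
    members: Sequence[str],
    remainder: Sequence[str],
    n_tests: int | None = None,
    alpha: float = 0.05,
    fold_change: str = "mean",
) -> tuple[pd.DataFrame, float]:
    """Volcano table comparing a subpopulation against the remainder.

    Per gene: log2 fold change (difference of group means of log2 molecules,
    or medians with ``fold_change="median"``) and two-sided Mann-Whitney p.
    Genes with at least two-fold regulation (|log2 FC| >= 1) are categorized
    by the Bonferroni-corrected family threshold ``alpha / n_tests``:
    ``green`` below the corrected threshold, ``yellow`` between it and
    ``alpha``, ``red`` above ``alpha``; everything else is ``not-regulated``.
    Returns the table and the corrected threshold.
    """
    members, remainder = list(members), list(remainder)
    if len(members) < 3 or len(remainder) < 3:
        raise ValueError("both groups need at least three cells")
    if set(members) & set(remainder):
        raise ValueError("subpopulation and remainder overlap")
    if n_tests is None:
        n_tests = log2_expr.shape[1]
    threshold = alpha / n_tests
    centre = np.mean if fold_change == "mean" else np.median
    rows = []
    for gene in log2_expr.columns:
        a = log2_expr.loc[members, gene].to_numpy(dtype=float)
        b = log2_expr.loc[remainder, gene].to_numpy(dtype=float)
        fc = float(centre(a) - centre(b))
        p = mannwhitney_p(a, b)
        if abs(fc) < 1.0:
            cat = "not-regulated"
        elif p < threshold:
            cat = "green"
        elif p < alpha:
            cat = "yellow"
        else:
            cat = "red"
        rows.append((gene, fc, p, cat))
    table = pd.DataFrame(rows, columns=["gene", "log2_fc", "p_value", "category"])
    return table, threshold


def subpop_transcript_contrast(
    totals: pd.Series,
    members: Sequence[str],
    remainder: Sequence[str],
) -> tuple[float, float]:
    """Percent total-transcript reduction in the subpopulation, with MW p.

    Returns ``100 * (1 - mean(members) / mean(remainder))`` (positive when
    the subpopulation is lower) and the two-sided Mann-Whitney p-value.
    """
    members, remainder = list(members), list(remainder)
    if not members or not remainder:
        raise ValueError("both groups must be non-empty")
    a = totals.loc[members].to_numpy(dtype=float)
    b = totals.loc[remainder].to_numpy(dtype=float)
    percent = 100.0 * (1.0 - a.mean() / b.mean())
    p = mannwhitney_p(a, b)
    return float(percent), float(p)
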