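"""Joint embedding, graph clustering, and cluster-level bookkeeping.

Cells from both species, remapped onto the composite ortholog namespace and
scaled together, are embedded by PCA, connected in a shared-nearest-neighbor
graph, and partitioned with Leiden modularity optimization. Two labelings
of the same cells (e.g. clustering on all native genes vs. on ortholog genes
only) are compared by cross-tabulation (the transition table), and a joint
clustering is summarized by how many cells sit in "composite" clusters that
contain cells of every species.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io_formats import write_tsv
from .preprocess import ExprMatrix

log = logging.getLogger(__name__)


@dataclass
class ClusterLabels:
    """Integer cluster ids per barcode, relabeled 0..K-1 by decreasing size."""

    barcodes: list[str]
    labels: np.ndarray
    resolution: float
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (len(self.barcodes),):
            raise ValueError("one label per barcode required")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.barcodes, name="cluster")

    def write_tsv(self, path: str | Path) -> None:
        write_tsv(
            pd.DataFrame({"barcode": self.barcodes, "cluster": self.labels}), path
        )


@dataclass
class TransitionMatrix:
    """Cross-tabulation of one cell set under two labelings."""

    source_classes: list[str]
    target_classes: list[str]
    counts: np.ndarray
    row_pct: np.ndarray
    all_pct: np.ndarray

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.source_classes, columns=self.target_classes)

    def row_pct_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.row_pct, index=self.source_classes, columns=self.target_classes)

    def stay_pct(self) -> float:
        """Percent of cells whose class name is identical under both labelings."""
        total = self.counts.sum()
        stay = sum(
            self.counts[i, self.target_classes.index(c)]
            for i, c in enumerate(self.source_classes)
            if c in self.target_classes
        )
        return 100.0 * stay / total

    def write_tsv(self, path: str | Path) -> None:
        df = self.counts_frame().reset_index(names="source")
        write_tsv(df, path)


@dataclass
class CompositionReport:
    """Per-cluster species breakdown and the composite-cell summary."""

    per_cluster: pd.DataFrame  # cluster, n_cells, per-species counts, composite, fraction
    pct_cells_in_composite: float

    def write_tsv(self, path: str | Path) -> None:
        write_tsv(self.per_cluster, path)


def concat_datasets(matrices: Sequence[ExprMatrix]) -> ExprMatrix:
    """Column-concatenate matrices sharing an identical gene axis."""
    if not matrices:
        raise ValueError("no matrices to concatenate")
    first = matrices[0]
    if len(matrices) == 1:
        return first
    for m in matrices[1:]:
        if m.gene_ids != first.gene_ids:
            raise ValueError("gene axes differ between datasets")
        if m.layer != first.layer:
            raise ValueError("layers differ between datasets")
    barcodes: list[str] = []
    for m in matrices:
        barcodes.extend(m.barcodes)
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("barcode collision across datasets; prefix with sample ids")
    import scipy.sparse as sp

    if any(sp.issparse(m.values) for m in matrices):
        values = sp.hstack([sp.csr_matrix(m.values) for m in matrices]).tocsr()
    else:
        values = np.hstack([m.dense() for m in matrices])
    meta = pd.concat([m.cell_meta for m in matrices])
    return ExprMatrix(
        values=values, gene_ids=list(first.gene_ids), barcodes=barcodes,
        cell_meta=meta, layer=first.layer,
    )


@dataclass
class PCAResult:
    embedding: np.ndarray  # cells x n_pcs
    explained_variance_ratio: np.ndarray
    components: np.ndarray  # n_pcs x genes


def run_pca(e: ExprMatrix, n_pcs: int) -> PCAResult:
    """Deterministic PCA of cells in gene space.

    Sign convention: each component is flipped so that its largest-magnitude
    gene loading is positive, making the embedding reproducible across runs
    and platforms.
    """
    if e.layer != "scaled":
        raise ValueError("run_pca expects the scaled layer")
    x = e.dense().T  # cells x genes
    if n_pcs > min(x.shape):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(cells, genes)={min(x.shape)}")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    emb = pca.fit_transform(x)
    comp = pca.components_
    flip = np.sign(comp[np.arange(n_pcs), np.abs(comp).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return PCAResult(
        embedding=emb * flip,
        explained_variance_ratio=pca.explained_variance_ratio_,
        components=comp * flip[:, None],
    )


def snn_jaccard(neighbors_i: set[int], neighbors_j: set[int]) -> float:
    """Shared-nearest-neighbor Jaccard overlap of two neighbor sets."""
    union = len(neighbors_i | neighbors_j)
    return len(neighbors_i & neighbors_j) / union if union else 0.0


def build_knn_graph(
    embedding: np.ndarray, k: int, barcodes: Sequence[str] | None = None
) -> ig.Graph:
    """Symmetrized kNN graph with shared-nearest-neighbor Jaccard weights.

    Neighbors are the k nearest by Euclidean distance (self excluded, ties
    broken by index order). An edge joins i and j when either is a neighbor
    of the other; its weight is the Jaccard overlap of their neighbor sets,
    and zero-weight edges are pruned.
    """
    emb = np.asarray(embedding, dtype=np.float64)
    n = emb.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    dist, idx = nn.kneighbors(emb)
    # deterministic tie-break: sort each row by (distance, index)
    for i in range(n):
        order = np.lexsort((idx[i], dist[i]))
        idx[i] = idx[i][order]
        dist[i] = dist[i][order]
    neigh = [set() for _ in range(n)]
    for i in range(n):
        row = [j for j in idx[i] if j != i][:k]
        neigh[i] = set(row)
    edges: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in neigh[i]:
            key = (i, j) if i < j else (j, i)
            if key in edges:
                continue
            w = snn_jaccard(neigh[key[0]], neigh[key[1]])
            if w > 0:
                edges[key] = w
    g = ig.Graph(n=n, edges=list(edges.keys()))
    g.es["weight"] = list(edges.values())
    if barcodes is not None:
        g.vs["name"] = list(barcodes)
    return g


def cluster_graph(graph: ig.Graph, resolution: float, seed: int) -> ClusterLabels:
    """Leiden modularity clustering (RB configuration objective).

    Deterministic given the seed; labels are renumbered by decreasing
    cluster size (ties broken by smallest original label).
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=graph.es["weight"] if graph.ecount() else None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.asarray(part.membership, dtype=np.int64)
    sizes = np.bincount(raw)
    order = np.lexsort((np.arange(sizes.size), -sizes))
    relabel = np.empty(sizes.size, dtype=np.int64)
    relabel[order] = np.arange(sizes.size)
    labels = relabel[raw]
    barcodes = list(graph.vs["name"]) if "name" in graph.vs.attributes() else [
        str(i) for i in range(graph.vcount())
    ]
    return ClusterLabels(barcodes=barcodes, labels=labels, resolution=resolution, seed=seed)


def transition_table(
    labels_a: Mapping[str, str] | pd.Series, labels_b: Mapping[str, str] | pd.Series
) -> TransitionMatrix:
    """Cross-tabulate the same cells under two labelings.

    Computed over the intersection of barcodes; ``row_pct`` rows sum to 100
    (percent of each source class) and ``all_pct`` sums to 100 overall.
    """
    sa = pd.Series(labels_a).astype(str)
    sb = pd.Series(labels_b).astype(str)
    shared = sa.index.intersection(sb.index)
    if len(shared) == 0:
        raise ValueError("no shared barcodes between the two labelings")
    tab = pd.crosstab(sa.loc[shared], sb.loc[shared])
    tab = tab.sort_index(axis=0).sort_index(axis=1)
    counts = tab.to_numpy()
    row_sums = counts.sum(axis=1, keepdims=True)
    return TransitionMatrix(
        source_classes=[str(c) for c in tab.index],
        target_classes=[str(c) for c in tab.columns],
        counts=counts,
        row_pct=100.0 * counts / row_sums,
        all_pct=100.0 * counts / counts.sum(),
    )


def composite_composition(
    labels: ClusterLabels,
    species: Mapping[str, str] | pd.Series,
    min_cells_per_species: int = 1,
) -> CompositionReport:
    """Flag clusters containing >= ``min_cells_per_species`` cells of every species.

    The summary percentage is the share of all cells that sit in such
    composite clusters.
    """
    sp_series = pd.Series(species).astype(str).loc[labels.barcodes]
    all_species = sorted(sp_series.unique())
    if len(all_species) < 2:
        warnings.warn("single-species dataset: no cluster can be composite")
    df = pd.DataFrame({"cluster": labels.labels, "species": sp_series.to_numpy()})
    tab = pd.crosstab(df["cluster"], df["species"]).reindex(
        columns=all_species, fill_value=0
    )
    composite = (tab >= min_cells_per_species).all(axis=1) & (len(all_species) >= 2)
    sizes = tab.sum(axis=1)
    report = tab.copy()
    report.columns = [f"n_{s}" for s in all_species]
    report.insert(0, "cluster", tab.index)
    report["n_cells"] = sizes.to_numpy()
    report["composite"] = composite.to_numpy()
    report["fraction_of_cells"] = sizes.to_numpy() / sizes.sum()
    pct = 100.0 * sizes[composite].sum() / sizes.sum()
    return CompositionReport(
        per_cluster=report.reset_index(drop=True), pct_cells_in_composite=float(pct)
    )
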