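"""End-to-end workflows chaining the processing stages.

These functions are the library form of the CLI subcommands: joint
integration of two species on the composite ortholog namespace, and the
all-genes vs ortholog-only transition analysis within one species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cluster import (
    ClusterLabels,
    CompositionReport,
    PCAResult,
    TransitionMatrix,
    build_knn_graph,
    cluster_graph,
    composite_composition,
    concat_datasets,
    run_pca,
    transition_table,
)
from .io_formats import CountMatrix
from .ortholog import CompositeNamespace, OrthologTable, build_composite_namespace, remap_counts
from .preprocess import (
    ExprMatrix,
    PipelineConfig,
    filter_cells,
    filter_genes,
    normalize_log,
    scale_regress,
    select_hvg,
)

log = logging.getLogger(__name__)


def concat_counts(bundles: Sequence[CountMatrix]) -> CountMatrix:
    """Column-concatenate count bundles sharing an identical gene axis."""
    first = bundles[0]
    if len(bundles) == 1:
        return first
    for m in bundles[1:]:
        if m.gene_ids != first.gene_ids:
            raise ValueError("gene axes differ between bundles")
    barcodes: list[str] = []
    for m in bundles:
        barcodes.extend(m.barcodes)
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("barcode collision across bundles")
    return CountMatrix(
        counts=sp.hstack([m.counts for m in bundles]).tocsr(),
        gene_ids=list(first.gene_ids),
        barcodes=barcodes,
        cell_meta=pd.concat([m.cell_meta for m in bundles]),
    )


@dataclass
class IntegrationResult:
    labels: ClusterLabels
    embedding: np.ndarray
    composition: CompositionReport
    normalized: ExprMatrix  # full composite gene axis, all retained cells
    hvg: list[str]
    counts: CountMatrix  # filtered counts on the composite axis
    namespace: CompositeNamespace


def _embed_and_cluster(
    counts: CountMatrix, config: PipelineConfig
) -> tuple[ExprMatrix, list[str], np.ndarray, ClusterLabels]:
    norm = normalize_log(counts, config.target_sum)
    hvg = select_hvg(norm, config.n_hvg)
    ncount = counts.cell_totals().astype(np.float64)
    scaled = scale_regress(norm, genes=hvg, covariates={"nCount": ncount})
    n_pcs = min(config.n_pcs, len(hvg), counts.n_cells)
    pca = run_pca(scaled, n_pcs)
    graph = build_knn_graph(pca.embedding, config.knn_k, barcodes=counts.barcodes)
    labels = cluster_graph(graph, config.resolution, config.seed)
    return norm, hvg, pca.embedding, labels


def integrate(
    bundles_a: Sequence[CountMatrix],
    bundles_b: Sequence[CountMatrix],
    ortho: OrthologTable,
    config: PipelineConfig | None = None,
) -> IntegrationResult:
    """Joint two-species pipeline on the composite namespace.

    Remap each species onto the composite gene axis, pool all cells, apply
    the standard QC/normalize/HVG/scale/PCA/kNN/Leiden chain, and summarize
    how many cells land in composite (both-species) clusters. Depth
    normalization runs on the remapped matrix, so one-to-many duplication
    is part of each cell's library size by construction.
    """
    config = config or PipelineConfig()
    ns = build_composite_namespace(ortho)
    remapped = [remap_counts(m, ns, "a") for m in bundles_a] + [
        remap_counts(m, ns, "b") for m in bundles_b
    ]
    counts = concat_counts(remapped)
    counts = filter_cells(counts, config.min_cell_counts)
    counts = filter_genes(counts, config.min_cells_per_gene)
    norm, hvg, embedding, labels = _embed_and_cluster(counts, config)
    composition = composite_composition(
        labels, counts.cell_meta["species"], config.min_cells_per_species
    )
    return IntegrationResult(
        labels=labels,
        embedding=embedding,
        composition=composition,
        normalized=norm,
        hvg=hvg,
        counts=counts,
        namespace=ns,
    )


def cluster_single(
    bundles: Sequence[CountMatrix],
    config: PipelineConfig | None = None,
    genes: Sequence[str] | None = None,
    skip_cell_filter: bool = False,
) -> tuple[ClusterLabels, ExprMatrix]:
    """Cluster one species' data, optionally restricted to a gene subset."""
    config = config or PipelineConfig()
    counts = concat_counts(list(bundles))
    if genes is not None:
        keep = set(genes)
        mask = np.array([g in keep for g in counts.gene_ids])
        if not mask.any():
            raise ValueError("gene restriction leaves no genes")
        counts = counts.subset_genes(mask)
    if not skip_cell_filter:
        counts = filter_cells(counts, config.min_cell_counts)
    counts = filter_genes(counts, config.min_cells_per_gene)
    norm, hvg, embedding, labels = _embed_and_cluster(counts, config)
    return labels, norm


@dataclass
class TransitionResult:
    labels_all: ClusterLabels
    labels_ortho: ClusterLabels
    transition: TransitionMatrix


def transition_analysis(
    bundles: Sequence[CountMatrix],
    ortho: OrthologTable,
    side: Literal["a", "b"],
    config: PipelineConfig | None = None,
    type_map_all: pd.Series | None = None,
    type_map_ortho: pd.Series | None = None,
) -> TransitionResult:
    """Cluster one species on all native genes vs ortholog genes only.

    The two labelings of the same cells are cross-tabulated; optional
    user-supplied cluster-to-type mapping tables lift the comparison from
    raw cluster ids to named cell types.
    """
    config = config or PipelineConfig()
    ortho_genes = sorted({p.gene_a if side == "a" else p.gene_b for p in ortho.pairs})
    labels_all, _ = cluster_single(bundles, config)
    # same cells in both runs: restrict to the all-genes QC survivors
    survivors = set(labels_all.barcodes)
    kept = [m.subset_cells(np.array([b in survivors for b in m.barcodes])) for m in bundles]
    labels_ortho, _ = cluster_single(kept, config, genes=ortho_genes, skip_cell_filter=True)
    sa = labels_all.as_series().astype(str)
    sb = labels_ortho.as_series().astype(str)
    if type_map_all is not None:
        sa = sa.map(type_map_all.astype(str))
    if type_map_ortho is not None:
        sb = sb.map(type_map_ortho.astype(str))
    return TransitionResult(
        labels_all=labels_all,
        labels_ortho=labels_ortho,
        transition=transition_table(sa, sb),
    )
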