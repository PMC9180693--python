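"""QC filtering, depth normalization, variable-gene selection, and scaling.

The sequence mirrors the standard droplet scRNA-seq recipe: drop shallow
cells (total counts < 200 by default) and rarely detected genes (< 5 cells),
rescale every cell to a common depth (10,000) and take log1p, rank genes by
mean-binned normalized dispersion to pick the top 2,000, then regress out
nuisance covariates (total counts, optionally mitochondrial fraction) per
gene and z-score with clipping at +/-10. When the matrix lives on the
composite ortholog namespace these steps run on the remapped matrix, so
one-to-many duplication is already reflected in each cell's total counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import CountMatrix

log = logging.getLogger(__name__)

SCALE_CLIP = 10.0  # bound on z-scored values, limits PCA leverage of outliers
N_DISPERSION_BINS = 20


class QCError(RuntimeError):
    """Quality filtering removed everything."""


@dataclass
class PipelineConfig:
    """Tunable constants of the whole pipeline with their field defaults."""

    min_cell_counts: int = 200
    min_cells_per_gene: int = 5
    target_sum: float = 10_000.0
    n_hvg: int = 2000
    n_pcs: int = 30
    knn_k: int = 20
    resolution: float = 0.5
    alpha: float = 0.05
    min_pct: float = 0.1
    min_cells_per_species: int = 1
    use_padj: bool = False
    logfc_base: Literal["e", "2"] = "e"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_pcs > self.n_hvg:
            raise ValueError("n_pcs must not exceed n_hvg")
        for name in ("min_cell_counts", "min_cells_per_gene", "n_hvg", "n_pcs", "knn_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a ``key = value`` config file (one pair per line, # comments)."""
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"bool": lambda v: v.lower() in ("1", "true", "yes")}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise ValueError(f"unknown config key: {key!r}")
            default = getattr(cls(), key)
            if isinstance(default, bool):
                kwargs[key] = casts["bool"](val)
            elif isinstance(default, int):
                kwargs[key] = int(val)
            elif isinstance(default, float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ExprMatrix:
    """Real-valued expression, genes x cells, normalized or scaled layer."""

    values: sp.csr_matrix | np.ndarray
    gene_ids: list[str]
    barcodes: list[str]
    cell_meta: pd.DataFrame
    layer: Literal["normalized", "scaled"]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError("values shape inconsistent with gene/barcode lists")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def dense(self) -> np.ndarray:
        return self.values.toarray() if sp.issparse(self.values) else np.asarray(self.values)

    def subset_genes(self, genes: Sequence[str]) -> "ExprMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in genes]
        return ExprMatrix(
            values=self.values[idx, :],
            gene_ids=list(genes),
            barcodes=list(self.barcodes),
            cell_meta=self.cell_meta,
            layer=self.layer,
        )

    def subset_cells(self, barcodes: Sequence[str]) -> "ExprMatrix":
        pos = {b: i for i, b in enumerate(self.barcodes)}
        idx = [pos[b] for b in barcodes]
        return ExprMatrix(
            values=self.values[:, idx],
            gene_ids=list(self.gene_ids),
            barcodes=list(barcodes),
            cell_meta=self.cell_meta.iloc[idx],
            layer=self.layer,
        )


def filter_cells(m: CountMatrix, min_counts: int) -> CountMatrix:
    """Keep cells with total counts >= ``min_counts`` (strict 'less than' drop)."""
    totals = m.cell_totals()
    keep = totals >= min_counts
    n_removed = int((~keep).sum())
    if not keep.any():
        raise QCError("no cells survive QC")
    if n_removed:
        log.info("filter_cells: removed %d of %d cells", n_removed, m.n_cells)
    return m.subset_cells(keep)


def filter_genes(m: CountMatrix, min_cells: int) -> CountMatrix:
    """Keep genes detected (count > 0) in at least ``min_cells`` cells."""
    keep = m.gene_detection() >= min_cells
    if not keep.any():
        warnings.warn("filter_genes removed every gene")
    return m.subset_genes(keep)


def normalize_log(m: CountMatrix, target_sum: float = 10_000.0) -> ExprMatrix:
    """Depth-normalize each cell to ``target_sum`` and apply log1p (natural log)."""
    totals = m.cell_totals()
    if (totals == 0).any():
        raise QCError("zero-total cell encountered; run filter_cells first")
    x = m.counts.astype(np.float64).tocsc()
    scale = target_sum / totals
    x = x.multiply(sp.csr_matrix(scale.reshape(1, -1))).tocsr()
    x.data = np.log1p(x.data)
    return ExprMatrix(
        values=x, gene_ids=list(m.gene_ids), barcodes=list(m.barcodes),
        cell_meta=m.cell_meta, layer="normalized",
    )


def _gene_mean_var(values) -> tuple[np.ndarray, np.ndarray]:
    if sp.issparse(values):
        n = values.shape[1]
        mean = np.asarray(values.mean(axis=1)).ravel()
        sq = np.asarray(values.multiply(values).mean(axis=1)).ravel()
        var = (sq - mean**2) * n / max(n - 1, 1)
    else:
        mean = values.mean(axis=1)
        var = values.var(axis=1, ddof=1) if values.shape[1] > 1 else np.zeros(values.shape[0])
    return mean, np.maximum(var, 0.0)


def select_hvg(e: ExprMatrix, n: int) -> list[str]:
    """Top-``n`` genes by mean-binned normalized dispersion.

    Dispersion is variance/mean of the normalized values; genes are placed
    in 20 equal-frequency mean bins and the dispersion is standardized
    within each bin (robustly, by median and MAD, so a bin containing many
    genuinely variable genes does not mask them), removing the trend of
    dispersion with expression level.
    """
    if e.layer != "normalized":
        raise ValueError("select_hvg expects the normalized layer")
    if n >= e.n_genes:
        return list(e.gene_ids)
    mean, var = _gene_mean_var(e.values)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    expressed = mean > 0
    bins = np.zeros(e.n_genes, dtype=int)
    if expressed.any():
        # few genes -> fewer bins, so standardization stays meaningful
        n_bins = min(N_DISPERSION_BINS, max(1, int(expressed.sum()) // 10))
        ranks = pd.Series(mean[expressed]).rank(method="first").to_numpy()
        bins[expressed] = 1 + np.minimum(
            (ranks - 1) * n_bins // max(len(ranks), 1), n_bins - 1
        ).astype(int)
    z = np.zeros(e.n_genes)
    for b in np.unique(bins[bins > 0]):
        sel = bins == b
        med = np.median(disp[sel])
        mad = 1.4826 * np.median(np.abs(disp[sel] - med))
        scale = mad if mad > 0 else disp[sel].std(ddof=0)
        if scale > 0:
            z[sel] = (disp[sel] - med) / scale
    order = np.lexsort((np.arange(e.n_genes), -z))  # ties -> first gene in file order
    return [e.gene_ids[i] for i in order[:n]]


def scale_regress(
    e: ExprMatrix,
    genes: Sequence[str] | None = None,
    covariates: Mapping[str, np.ndarray] | None = None,
) -> ExprMatrix:
    """OLS-residualize each gene on the covariates, then z-score and clip.

    With no covariates this is plain per-gene standardization. Genes with
    zero residual variance are set to all-zero rather than dropped, keeping
    shapes stable. Constant covariates are dropped with a warning.
    """
    if e.layer != "normalized":
        raise ValueError("scale_regress expects the normalized layer")
    sub = e.subset_genes(list(genes)) if genes is not None else e
    x = sub.dense().astype(np.float64)
    n_cells = x.shape[1]
    cols = [np.ones(n_cells)]
    if covariates:
        for name, vec in covariates.items():
            vec = np.asarray(vec, dtype=np.float64)
            if vec.shape != (n_cells,):
                raise ValueError(f"covariate {name!r} has wrong length")
            if np.ptp(vec) == 0:
                warnings.warn(f"dropping constant covariate {name!r}")
                continue
            cols.append(vec)
    design = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    resid = x - (design @ beta).T
    sd = resid.std(axis=1, ddof=0)
    zero = sd < 1e-12
    sd_safe = np.where(zero, 1.0, sd)
    scaled = (resid - resid.mean(axis=1, keepdims=True)) / sd_safe[:, None]
    scaled[zero, :] = 0.0
    np.clip(scaled, -SCALE_CLIP, SCALE_CLIP, out=scaled)
    return ExprMatrix(
        values=scaled, gene_ids=list(sub.gene_ids), barcodes=list(sub.barcodes),
        cell_meta=sub.cell_meta, layer="scaled",
    )


def mito_fraction(m: CountMatrix, mito_genes: Sequence[str]) -> np.ndarray:
    """Per-cell fraction of counts in a user-supplied mitochondrial gene list."""
    mito = set(mito_genes)
    idx = [i for i, g in enumerate(m.gene_ids) if g in mito]
    totals = m.cell_totals().astype(float)
    if not idx:
        return np.zeros(m.n_cells)
    mito_counts = np.asarray(m.counts[idx, :].sum(axis=0)).ravel()
    return np.divide(mito_counts, totals, out=np.zeros(m.n_cells), where=totals > 0)
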