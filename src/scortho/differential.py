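"""Per-cluster differential expression with a rank-sum test.

The test is the two-sided Wilcoxon rank-sum (Mann-Whitney) test computed
here from first principles: exact tail enumeration of the rank-sum
distribution when the smaller group has at most 8 cells and there are no
ties, and otherwise the normal approximation with tie-corrected variance
and a 0.5 continuity correction. Fold changes follow the Seurat-v3-era
convention, ln(mean(expm1(x1)) + 1) - ln(mean(expm1(x2)) + 1), computed on
depth-normalized log values; a ``logfc_base="2"`` switch divides by ln 2. Multiple testing is controlled per table with
Benjamini-Hochberg.

Genes are prefiltered by detection: only genes seen in at least ``min_pct``
of either group are tested (default 10%); oracle-style exhaustive testing
sets ``min_pct = 0``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata

from .cluster import ClusterLabels
from .io_formats import write_tsv
from .preprocess import ExprMatrix

log = logging.getLogger(__name__)

EXACT_MAX_N = 8  # exact enumeration when min(n1, n2) <= this and no ties


@dataclass
class DEGTable:
    """One differential-expression record per tested gene."""

    records: pd.DataFrame  # gene, logFC, pval, padj, pct_1, pct_2, direction[, cluster]
    n1: int
    n2: int
    params: dict = field(default_factory=dict)

    def significant(self, alpha: float, use_padj: bool = False) -> pd.DataFrame:
        col = "padj" if use_padj else "pval"
        return self.records[self.records[col] < alpha]

    def write_tsv(self, path: str | Path) -> None:
        write_tsv(self.records, path)


@lru_cache(maxsize=None)
def _ranksum_cdf(n1: int, n2: int) -> np.ndarray:
    """counts[s] = number of n1-subsets of ranks 1..n1+n2 with sum s."""
    n = n1 + n2
    max_sum = n1 * n + 1
    # dp[j][s]: subsets of size j with rank-sum s, ranks added one at a time
    dp = np.zeros((n1 + 1, max_sum), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in range(1, n + 1):
        for j in range(min(r, n1), 0, -1):
            dp[j, r:] += dp[j - 1, :-r] if r else dp[j - 1, :]
    return dp[n1]


def _exact_two_sided_p(w: float, n1: int, n2: int) -> float:
    counts = _ranksum_cdf(n1, n2)
    total = counts.sum()
    w = int(round(w))
    p_le = counts[: w + 1].sum() / total
    p_ge = counts[w:].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p-value for two samples (scalar convenience path)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    w = ranks[:n1].sum()
    tie_sum = _tie_term(combined)
    if min(n1, n2) <= EXACT_MAX_N and tie_sum == 0:
        return _exact_two_sided_p(w, n1, n2)
    return _normal_approx_p(w, n1, n2, tie_sum)


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    t = counts[counts > 1].astype(np.float64)
    return float((t**3 - t).sum())


def _normal_approx_p(w: float, n1: int, n2: int, tie_sum: float) -> float:
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_sum / (n * (n - 1)))
    if var <= 0:
        return 1.0
    diff = w - mu
    if diff == 0:
        return 1.0
    z = (abs(diff) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return min(1.0, 2.0 * float(norm.sf(z)))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _group_values(e: ExprMatrix, barcodes: Sequence[str]) -> np.ndarray:
    pos = {b: i for i, b in enumerate(e.barcodes)}
    idx = [pos[b] for b in barcodes]
    vals = e.values[:, idx]
    return vals.toarray() if sp.issparse(vals) else np.asarray(vals, dtype=np.float64)


def wilcoxon_de(
    e: ExprMatrix,
    cells_1: Sequence[str],
    cells_2: Sequence[str],
    min_pct: float = 0.1,
    logfc_base: Literal["e", "2"] = "e",
    cluster: object = None,
) -> DEGTable:
    """Rank-sum differential expression of group 1 vs group 2, per gene."""
    if e.layer != "normalized":
        raise ValueError("wilcoxon_de expects the normalized layer")
    cells_1, cells_2 = list(cells_1), list(cells_2)
    if set(cells_1) & set(cells_2):
        raise ValueError("groups must be disjoint")
    n1, n2 = len(cells_1), len(cells_2)
    if min(n1, n2) < 3:
        raise ValueError("each group needs at least 3 cells")
    x1 = _group_values(e, cells_1)
    x2 = _group_values(e, cells_2)
    pct_1 = (x1 > 0).mean(axis=1)
    pct_2 = (x2 > 0).mean(axis=1)
    tested = (pct_1 >= min_pct) | (pct_2 >= min_pct)
    if not tested.any():
        warnings.warn("no genes pass the detection prefilter")
    genes = [g for g, t in zip(e.gene_ids, tested) if t]
    x1, x2 = x1[tested], x2[tested]
    pct_1, pct_2 = pct_1[tested], pct_2[tested]

    mean1 = np.expm1(x1).mean(axis=1)
    mean2 = np.expm1(x2).mean(axis=1)
    logfc = np.log(mean1 + 1.0) - np.log(mean2 + 1.0)
    if logfc_base == "2":
        logfc = logfc / np.log(2.0)

    data = np.hstack([x1, x2])
    ranks = rankdata(data, axis=1)
    w = ranks[:, :n1].sum(axis=1)
    pvals = np.empty(len(genes))
    exact_ok = min(n1, n2) <= EXACT_MAX_N
    for i in range(len(genes)):
        tie_sum = _tie_term(data[i])
        if exact_ok and tie_sum == 0:
            pvals[i] = _exact_two_sided_p(w[i], n1, n2)
        else:
            pvals[i] = _normal_approx_p(w[i], n1, n2, tie_sum)
    padj = bh_adjust(pvals) if len(genes) else np.array([])
    df = pd.DataFrame(
        {
            "gene": genes,
            "logFC": logfc,
            "pval": pvals,
            "padj": padj,
            "pct_1": pct_1,
            "pct_2": pct_2,
            "direction": np.where(logfc > 0, "up", "down"),
        }
    )
    if cluster is not None:
        df.insert(0, "cluster", cluster)
    return DEGTable(
        records=df, n1=n1, n2=n2,
        params={"min_pct": min_pct, "logfc_base": logfc_base, "test": "wilcoxon"},
    )


def per_cluster_condition_de(
    e: ExprMatrix,
    labels: ClusterLabels,
    condition_field: str,
    case: str,
    control: str,
    min_pct: float = 0.1,
    logfc_base: Literal["e", "2"] = "e",
) -> tuple[dict[int, DEGTable], list[dict]]:
    """Case-vs-control rank-sum DE within every eligible cluster.

    Returns the per-cluster tables plus a report of skipped clusters
    (missing condition or fewer than 3 cells in an arm).
    """
    if condition_field not in e.cell_meta.columns:
        raise ValueError(f"metadata lacks field {condition_field!r}")
    cond = e.cell_meta[condition_field].astype(str)
    lab = labels.as_series().loc[e.barcodes]
    tables: dict[int, DEGTable] = {}
    skipped: list[dict] = []
    for cl in sorted(lab.unique()):
        in_cl = lab == cl
        case_cells = lab.index[in_cl & (cond == case)].tolist()
        ctrl_cells = lab.index[in_cl & (cond == control)].tolist()
        if len(case_cells) < 3 or len(ctrl_cells) < 3:
            skipped.append(
                {"cluster": int(cl), "n_case": len(case_cells), "n_control": len(ctrl_cells)}
            )
            continue
        tables[int(cl)] = wilcoxon_de(
            e, case_cells, ctrl_cells, min_pct=min_pct, logfc_base=logfc_base, cluster=int(cl)
        )
    if skipped:
        log.info("per_cluster_condition_de: skipped %d clusters", len(skipped))
    return tables, skipped


def find_markers_all(
    e: ExprMatrix,
    labels: ClusterLabels,
    only_pos: bool = True,
    min_pct: float = 0.1,
    logfc_base: Literal["e", "2"] = "e",
) -> dict[int, DEGTable]:
    """One-vs-rest marker detection for every cluster."""
    lab = labels.as_series().loc[e.barcodes]
    if lab.nunique() < 2:
        raise ValueError("marker detection needs at least 2 clusters")
    out: dict[int, DEGTable] = {}
    for cl in sorted(lab.unique()):
        members = lab.index[lab == cl].tolist()
        rest = lab.index[lab != cl].tolist()
        if len(members) < 3:
            warnings.warn(f"cluster {cl} has fewer than 3 cells; skipped")
            continue
        table = wilcoxon_de(
            e, members, rest, min_pct=min_pct, logfc_base=logfc_base, cluster=int(cl)
        )
        if only_pos:
            table.records = table.records[table.records["logFC"] > 0].reset_index(drop=True)
        out[int(cl)] = table
    return out
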