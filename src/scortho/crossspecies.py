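"""Cross-species DEG intersection, synergy labels, enrichment, marker overlap.

A gene (strictly: an ortholog pair) differentially expressed in matched
clusters of both species is *synergistic* when its log fold changes share a
sign and *non-synergistic* when the signs oppose — the former marks a
conserved response, the latter a species-specific one. Gene-set
over-representation uses the upper-tail hypergeometric test against a
user-supplied universe, and significant sets from per-species analyses are
categorized as common, species-specific, or inconsistent-within-species.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .differential import DEGTable, bh_adjust
from .io_formats import GeneSetCollection, write_tsv
from .ortholog import SEPARATOR, OrthologTable, map_gene_set

log = logging.getLogger(__name__)

Synergy = Literal["synergistic", "non_synergistic", "undefined"]


def classify_synergy(logfc_a: float, logfc_b: float) -> Synergy:
    """Direction concordance of one ortholog pair's fold changes."""
    sa, sb = np.sign(logfc_a), np.sign(logfc_b)
    if sa == 0 or sb == 0:
        return "undefined"
    return "synergistic" if sa == sb else "non_synergistic"


@dataclass
class SynergyTable:
    """Per-ortholog-pair intersection of two species' DEG tables."""

    records: pd.DataFrame
    # columns: gene_a, gene_b, composite_id, logfc_a, logfc_b, pval_a, pval_b, synergy
    n_common: int
    n_synergistic: int
    n_non_synergistic: int
    n_undefined: int
    n_unique_genes_a: int  # collapsed tally: distinct species-A genes involved

    def write_tsv(self, path: str | Path) -> None:
        write_tsv(self.records, path)


def intersect_degs(
    t_a: DEGTable,
    t_b: DEGTable,
    ortho: OrthologTable,
    alpha: float = 0.05,
    use_padj: bool = False,
) -> SynergyTable:
    """Ortholog pairs significant in both species' tables, with synergy labels.

    Intersection granularity is the pair, so a one-to-many gene can
    contribute several records; a collapsed count of distinct species-A
    genes is reported alongside.
    """
    sig_a = t_a.significant(alpha, use_padj).set_index("gene")
    sig_b = t_b.significant(alpha, use_padj).set_index("gene")
    rows = []
    for p in ortho.pairs:
        if p.gene_a in sig_a.index and p.gene_b in sig_b.index:
            ra, rb = sig_a.loc[p.gene_a], sig_b.loc[p.gene_b]
            rows.append(
                {
                    "gene_a": p.gene_a,
                    "gene_b": p.gene_b,
                    "composite_id": p.gene_a + SEPARATOR + p.gene_b,
                    "logfc_a": float(ra["logFC"]),
                    "logfc_b": float(rb["logFC"]),
                    "pval_a": float(ra["pval"]),
                    "pval_b": float(rb["pval"]),
                    "synergy": classify_synergy(float(ra["logFC"]), float(rb["logFC"])),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_a", "gene_b", "composite_id", "logfc_a", "logfc_b",
            "pval_a", "pval_b", "synergy",
        ],
    )
    counts = df["synergy"].value_counts() if len(df) else pd.Series(dtype=int)
    return SynergyTable(
        records=df,
        n_common=len(df),
        n_synergistic=int(counts.get("synergistic", 0)),
        n_non_synergistic=int(counts.get("non_synergistic", 0)),
        n_undefined=int(counts.get("undefined", 0)),
        n_unique_genes_a=df["gene_a"].nunique() if len(df) else 0,
    )


@dataclass
class EnrichmentRecord:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    pval: float
    padj: float


def hypergeom_enrich(
    query: Iterable[str], sets: GeneSetCollection, universe: Iterable[str]
) -> list[EnrichmentRecord]:
    """Upper-tail hypergeometric over-representation of each gene set.

    For a set with K members in the universe of size N and a query of size
    n drawn from it, p = P(X >= overlap) under the hypergeometric
    distribution; p-values are BH-adjusted across the sets.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ValueError("empty universe")
    uni_set = set(uni)
    q = list(dict.fromkeys(query))
    outside = [g for g in q if g not in uni_set]
    if outside:
        warnings.warn(f"dropping {len(outside)} query genes outside the universe")
        q = [g for g in q if g in uni_set]
    n_draws = len(q)
    q_set = set(q)
    names, pvals, rows = [], [], []
    for name, members in sets.sets.items():
        members_in = [g for g in dict.fromkeys(members) if g in uni_set]
        k = len(q_set.intersection(members_in))
        p = float(hypergeom.sf(k - 1, len(uni), len(members_in), n_draws))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        names.append(name)
        pvals.append(p)
        rows.append((name, k, len(members_in), n_draws, len(uni)))
    padj = bh_adjust(pvals) if pvals else np.array([])
    return [
        EnrichmentRecord(n, k, ks, qs, us, p, float(a))
        for (n, k, ks, qs, us), p, a in zip(rows, pvals, padj)
    ]


def enrichment_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.set_name, r.overlap, r.set_size, r.query_size, r.universe_size, r.pval, r.padj)
            for r in records
        ],
        columns=["set_name", "overlap", "set_size", "query_size", "universe_size", "pval", "padj"],
    )


Category = Literal["common", "species_a_only", "species_b_only", "other"]


@dataclass
class CategoryRecord:
    set_name: str
    category: Category
    flags: dict[str, bool] = field(default_factory=dict)


def compare_enrichment(
    primary_a: Iterable[str],
    primary_b: Iterable[str],
    auxiliary_a: Sequence[Iterable[str]] = (),
) -> list[CategoryRecord]:
    """Categorize significant set names across per-species analyses.

    Species A may contribute several analyses (e.g. two brain regions);
    a set significant in some but not all of them is *other*, significant
    in all of them it is *common* (if also hit in species B) or
    *species_a_only*; hits seen only in species B are *species_b_only*.
    """
    analyses_a = [set(primary_a)] + [set(x) for x in auxiliary_a]
    b_hits = set(primary_b)
    all_names = sorted(set().union(b_hits, *analyses_a))
    out = []
    for name in all_names:
        in_a = [name in s for s in analyses_a]
        flags = {f"analysis_a{i}": v for i, v in enumerate(in_a)}
        flags["analysis_b"] = name in b_hits
        if any(in_a) and not all(in_a):
            cat: Category = "other"
        elif all(in_a) and flags["analysis_b"]:
            cat = "common"
        elif all(in_a):
            cat = "species_a_only"
        else:
            cat = "species_b_only"
        out.append(CategoryRecord(set_name=name, category=cat, flags=flags))
    return out


def category_frame(records: Sequence[CategoryRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"set_name": r.set_name, "category": r.category}
        row.update(r.flags)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class MarkerOverlap:
    n_a: int
    n_b: int
    n_shared: int
    pct_of_a: float | None
    n_b_unmapped: int


def marker_overlap(
    markers_a: Iterable[str], markers_b: Iterable[str], ortho: OrthologTable
) -> MarkerOverlap:
    """Share of species-A markers also found among species-B markers.

    Species-B markers are first mapped onto species-A ids through the
    ortholog table; the headline number is 100 * |shared| / |markers_a|.
    """
    a = list(dict.fromkeys(markers_a))
    b = list(dict.fromkeys(markers_b))
    mapped = map_gene_set(b, ortho, "b_to_a")
    shared = set(a) & set(mapped.genes)
    pct = 100.0 * len(shared) / len(a) if a else None
    if not a:
        warnings.warn("no species-A markers; overlap percentage undefined")
    return MarkerOverlap(
        n_a=len(a), n_b=len(b), n_shared=len(shared), pct_of_a=pct,
        n_b_unmapped=mapped.n_unmapped,
    )
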