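"""Composite cross-species gene namespace.

Two species' matrices cannot share a gene axis directly, so each ortholog
pair (gene_a, gene_b) becomes one artificial composite id
``"<gene_a>|<gene_b>"``. A species-A gene with several species-B partners
(one-to-many) therefore appears in several composite ids, and remapping a
count matrix onto the namespace duplicates that gene's row — per-cell
library sizes grow accordingly, which is why downstream depth normalization
is always computed on the remapped matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import CountMatrix, FormatError, write_tsv

log = logging.getLogger(__name__)

SEPARATOR = "|"

Relation = Literal["one2one", "one2many", "many2one", "many2many"]


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    relation: Relation


@dataclass
class OrthologTable:
    """Unique (gene_a, gene_b) pairs with their relation class.

    The relation of a pair is a property of its connected ortholog group:
    within the group of genes linked by shared partners, ``one2many`` means
    only the A side fans out, ``many2one`` only the B side, ``many2many``
    both, and ``one2one`` neither.
    """

    pairs: list[OrthologPair]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "OrthologTable":
        pairs = list(dict.fromkeys(pairs))
        return cls(pairs=_classify(pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def partners(self, direction: Literal["a_to_b", "b_to_a"]) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for p in self.pairs:
            src, dst = (p.gene_a, p.gene_b) if direction == "a_to_b" else (p.gene_b, p.gene_a)
            out.setdefault(src, []).append(dst)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.gene_a, p.gene_b, p.relation) for p in self.pairs],
            columns=["gene_a", "gene_b", "relation"],
        )

    def write_tsv(self, path: str | Path) -> None:
        write_tsv(self.to_frame(), path)


def _classify(pairs: list[tuple[str, str]]) -> list[OrthologPair]:
    """Relation class per pair from multiplicities in the whole table."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    mult_a: dict[str, int] = {}
    mult_b: dict[str, int] = {}
    for a, b in pairs:
        ka, kb = "A:" + a, "B:" + b
        parent.setdefault(ka, ka)
        parent.setdefault(kb, kb)
        union(ka, kb)
        mult_a[a] = mult_a.get(a, 0) + 1
        mult_b[b] = mult_b.get(b, 0) + 1
    # group fans out on the A side if some A gene has >1 partner, on the
    # B side if some B gene has >1 partner
    fan_a: dict[str, bool] = {}
    fan_b: dict[str, bool] = {}
    for a, b in pairs:
        root = find("A:" + a)
        fan_a[root] = fan_a.get(root, False) or mult_a[a] > 1
        fan_b[root] = fan_b.get(root, False) or mult_b[b] > 1
    out = []
    for a, b in pairs:
        root = find("A:" + a)
        if fan_a[root] and fan_b[root]:
            rel: Relation = "many2many"
        elif fan_a[root]:
            rel = "one2many"
        elif fan_b[root]:
            rel = "many2one"
        else:
            rel = "one2one"
        out.append(OrthologPair(a, b, rel))
    return out


@dataclass
class CompositeNamespace:
    """Ordered composite gene ids plus per-species position indexes."""

    composite_ids: list[str]
    pairs: list[OrthologPair]
    a_index: dict[str, list[int]]
    b_index: dict[str, list[int]]

    def __len__(self) -> int:
        return len(self.composite_ids)

    def index(self, side: Literal["a", "b"]) -> dict[str, list[int]]:
        return self.a_index if side == "a" else self.b_index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c, p.gene_a, p.gene_b, p.relation) for c, p in zip(self.composite_ids, self.pairs)],
            columns=["composite_id", "gene_a", "gene_b", "relation"],
        )

    def write_tsv(self, path: str | Path) -> None:
        write_tsv(self.to_frame(), path)


def build_composite_namespace(t: OrthologTable) -> CompositeNamespace:
    """One composite id per ortholog pair, sorted by (gene_a, gene_b)."""
    if not t.pairs:
        raise ValueError("ortholog table is empty")
    for p in t.pairs:
        if SEPARATOR in p.gene_a or SEPARATOR in p.gene_b:
            raise FormatError(f"gene id contains reserved separator {SEPARATOR!r}: {p}")
    ordered = sorted(t.pairs, key=lambda p: (p.gene_a, p.gene_b))
    composite_ids = [p.gene_a + SEPARATOR + p.gene_b for p in ordered]
    a_index: dict[str, list[int]] = {}
    b_index: dict[str, list[int]] = {}
    for i, p in enumerate(ordered):
        a_index.setdefault(p.gene_a, []).append(i)
        b_index.setdefault(p.gene_b, []).append(i)
    n_m2m = sum(p.relation == "many2many" for p in ordered)
    if n_m2m:
        log.warning("namespace contains %d many2many pairs", n_m2m)
    return CompositeNamespace(composite_ids, ordered, a_index, b_index)


def remap_counts(m: CountMatrix, ns: CompositeNamespace, side: Literal["a", "b"]) -> CountMatrix:
    """Remap a per-species matrix onto the composite gene axis.

    Each composite row copies the counts of its source gene on the chosen
    side; source genes absent from the namespace are dropped, and composite
    rows whose source gene is absent from ``m`` are all-zero.
    """
    index = ns.index(side)
    gene_pos = {g: i for i, g in enumerate(m.gene_ids)}
    src = np.full(len(ns), -1, dtype=np.int64)
    for gene, positions in index.items():
        j = gene_pos.get(gene)
        if j is not None:
            for pos in positions:
                src[pos] = j
    present = src >= 0
    if not present.any():
        raise ValueError("no orthologs present in the count matrix")
    # selection matrix: out[i, :] = m.counts[src[i], :] where present
    rows = np.flatnonzero(present)
    sel = sp.csr_matrix(
        (np.ones(rows.size, dtype=np.int64), (rows, src[rows])),
        shape=(len(ns), m.n_genes),
    )
    out = sel @ m.counts
    dropped = m.n_genes - len(set(src[rows].tolist()))
    if dropped:
        log.info("remap_counts: %d source genes not in namespace (side %s)", dropped, side)
    return CountMatrix(
        counts=out.tocsr(),
        gene_ids=list(ns.composite_ids),
        barcodes=list(m.barcodes),
        cell_meta=m.cell_meta,
    )


class MappedGenes(NamedTuple):
    genes: list[str]
    n_unmapped: int


def map_gene_set(
    genes: Iterable[str], t: OrthologTable, direction: Literal["a_to_b", "b_to_a"]
) -> MappedGenes:
    """Union of ortholog partners of each input gene, sorted and deduplicated.

    Genes without a partner in the given direction are dropped; their count
    is reported in the result.
    """
    partners = t.partners(direction)
    out: set[str] = set()
    unmapped = 0
    for g in dict.fromkeys(genes):
        hits = partners.get(g)
        if hits is None:
            unmapped += 1
        else:
            out.update(hits)
    return MappedGenes(sorted(out), unmapped)
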