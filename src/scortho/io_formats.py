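"""Readers and writers for on-disk artifacts.

Count data travel as 10x-style bundles: a Matrix Market coordinate file
(``matrix.mtx``, genes x cells), one gene id per line (``genes.tsv``), one
barcode per line (``barcodes.tsv``), and an optional per-cell metadata
sidecar (``cell_meta.tsv``, tab-separated with a ``barcode`` column).
Ortholog relations come as a two-column TSV, gene sets as Broad-dialect GMT,
and every tabular result is written as TSV with a header row.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

log = logging.getLogger(__name__)

MATRIX_FILE = "matrix.mtx"
GENES_FILE = "genes.tsv"
BARCODES_FILE = "barcodes.tsv"
META_FILE = "cell_meta.tsv"
META_FIELDS = ("species", "condition", "sample")


class FormatError(ValueError):
    """An on-disk artifact violates its format contract."""


@dataclass
class CountMatrix:
    """Raw integer counts, genes x cells, with per-cell annotations.

    ``cell_meta`` is indexed by barcode and always carries the columns
    ``species``, ``condition`` and ``sample`` (``"unknown"`` when absent
    from the source bundle).
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    barcodes: list[str]
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.barcodes)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("gene ids are not unique")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("barcodes are not unique")
        if self.counts.nnz:
            data = self.counts.data
            if not np.issubdtype(data.dtype, np.integer):
                if not np.all(data == np.rint(data)):
                    raise FormatError("counts must be integral")
                self.counts = self.counts.astype(np.int64)
            if self.counts.data.size and self.counts.data.min() < 0:
                raise FormatError("counts must be non-negative")
        else:
            self.counts = self.counts.astype(np.int64)
        meta = self.cell_meta.copy()
        for col in META_FIELDS:
            if col not in meta.columns:
                meta[col] = "unknown"
        if list(meta.index) != list(self.barcodes):
            meta = meta.reindex(self.barcodes, fill_value="unknown")
            meta[list(META_FIELDS)] = meta[list(META_FIELDS)].fillna("unknown")
        self.cell_meta = meta[list(META_FIELDS)].astype(str)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def cell_totals(self) -> np.ndarray:
        """Per-cell total counts (the nCount of a 10x bundle)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def gene_detection(self) -> np.ndarray:
        """Number of cells with a nonzero count, per gene."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            counts=self.counts[:, keep],
            gene_ids=list(self.gene_ids),
            barcodes=[self.barcodes[i] for i in keep],
            cell_meta=self.cell_meta.iloc[keep],
        )

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            counts=self.counts[keep, :],
            gene_ids=[self.gene_ids[i] for i in keep],
            barcodes=list(self.barcodes),
            cell_meta=self.cell_meta,
        )


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional explicit universe."""

    sets: dict[str, list[str]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")


def _read_id_list(path: Path) -> list[str]:
    # 10x gene files may carry extra tab-separated columns (id, symbol, ...);
    # the first column is the identifier.
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[0])
    return out


def read_mtx_bundle(dir_path: str | Path) -> CountMatrix:
    """Read a 10x-style bundle directory into a :class:`CountMatrix`.

    Gene and barcode order is preserved from the list files. Metadata
    fields missing from the sidecar (or the sidecar itself) default to
    ``"unknown"``.
    """
    dir_path = Path(dir_path)
    try:
        mat = mmread(dir_path / MATRIX_FILE)
    except ValueError as exc:
        raise FormatError(f"bad Matrix Market file: {exc}") from exc
    genes = _read_id_list(dir_path / GENES_FILE)
    barcodes = _read_id_list(dir_path / BARCODES_FILE)
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix header says {mat.shape} but lists give "
            f"{len(genes)} genes x {len(barcodes)} cells"
        )
    meta_path = dir_path / META_FILE
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", dtype=str)
        if "barcode" not in meta.columns:
            raise FormatError("cell_meta.tsv lacks a 'barcode' column")
        meta = meta.set_index("barcode")
    else:
        meta = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    return CountMatrix(
        counts=sp.csr_matrix(mat), gene_ids=genes, barcodes=barcodes, cell_meta=meta
    )


def write_mtx_bundle(m: CountMatrix, dir_path: str | Path) -> None:
    """Write ``m`` as a bundle directory; round-trips exactly."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    mmwrite(str(dir_path / MATRIX_FILE), sp.coo_matrix(m.counts), field="integer")
    (dir_path / GENES_FILE).write_text("".join(g + "\n" for g in m.gene_ids))
    (dir_path / BARCODES_FILE).write_text("".join(b + "\n" for b in m.barcodes))
    meta = m.cell_meta.reset_index(names="barcode")
    meta.to_csv(dir_path / META_FILE, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"duplicate gene-set name {name!r}")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                raise FormatError(f"GMT line {lineno}: set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets=sets)


def read_ortholog_table(path: str | Path):
    """Read a two-column (gene_a, gene_b) TSV into an :class:`OrthologTable`.

    Exact duplicate rows are collapsed with a warning; relation classes
    are recomputed from multiplicities over the whole table.
    """
    from .ortholog import OrthologTable

    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        return OrthologTable(pairs=[])
    cols = list(df.columns)
    if "gene_a" not in cols or "gene_b" not in cols:
        # headerless two-column file
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, names=["gene_a", "gene_b"])
    n0 = len(df)
    df = df.drop_duplicates(subset=["gene_a", "gene_b"])
    if len(df) < n0:
        warnings.warn(f"collapsed {n0 - len(df)} duplicate ortholog rows")
    return OrthologTable.from_pairs(list(zip(df["gene_a"], df["gene_b"])))


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
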