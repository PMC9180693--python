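"""Paired-species experiment generator with full ground truth.

The generator emulates the structure of a two-species brain single-cell
comparison: a shared set of cell-type expression programs, an ortholog map
with one-to-one and one-to-many relations plus species-unique genes,
negative-binomial counts (mean mu, size r, variance mu + mu^2/r) with
log-normal library-size variation, per-gene species shifts (batch-like,
shared across cells), and per-type condition effects whose direction is
concordant across species for a chosen fraction of the planted pairs
("synergistic") and discordant for the rest.

Every draw flows from one ``numpy`` Generator seeded from ``SimParams.seed``,
so identical parameters give bit-identical bundles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import CountMatrix, write_tsv
from .ortholog import OrthologTable

log = logging.getLogger(__name__)

SPECIES_A = "speciesA"
SPECIES_B = "speciesB"
CASE = "case"
CONTROL = "control"


@dataclass
class SimParams:
    """Knobs of the paired-species generator.

    The defaults describe a desk-scale experiment: 4 shared cell types x
    2 conditions x 300 cells per species (2,400 cells/species), 1,400
    one-to-one plus 50 one-to-many ortholog pairs (1,500 pairs total) and
    200 species-unique genes per species. ``base_mean`` scales per-gene
    negative-binomial means (each gene's baseline is log-normal around it),
    ``dispersion`` is the NB size r, and the condition effect ``de_logfc``
    defaults to ln 2 (a two-fold change).
    """

    n_types: int = 4
    cells_per_type_per_species_per_condition: int = 300
    n_pairs_one2one: int = 1400
    n_pairs_one2many: int = 50
    n_unique_genes_per_species: int = 200
    base_mean: float = 0.5
    dispersion: float = 2.0
    libsize_sigma: float = 0.3
    marker_genes_per_type: int = 20
    marker_logfc: float = 1.5
    n_de_per_type: int = 50
    de_logfc: float = float(np.log(2.0))
    frac_synergistic: float = 0.6
    species_shift_sigma: float = 0.15
    type_program_sigma: float = 0.4
    baseline_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_synergistic <= 1.0):
            raise ValueError("frac_synergistic must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion (NB size) must be positive")
        for name in (
            "n_types", "cells_per_type_per_species_per_condition", "n_pairs_one2one",
            "n_pairs_one2many", "n_unique_genes_per_species", "marker_genes_per_type",
            "n_de_per_type",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Planted facts of one simulated experiment."""

    cell_truth: pd.DataFrame  # barcode, species, type, condition
    de_truth: pd.DataFrame  # type, gene_a, gene_b, logfc_a, logfc_b, synergistic
    marker_truth: pd.DataFrame  # type, gene_a, gene_b


@dataclass
class SimResult:
    bundle_a: CountMatrix
    bundle_b: CountMatrix
    ortholog: OrthologTable
    truth: GroundTruth
    genes_a: list[str]
    genes_b: list[str]
    # expected NB mean per gene per cell (before sampling), for diagnostics
    means: dict[str, np.ndarray] | None = None


def simulate_ortholog_map(p: SimParams) -> tuple[OrthologTable, list[str], list[str]]:
    """Deterministic ortholog map: one2one pairs, one2many fans, unique genes.

    Species-A ids are upper case and species-B ids lower case, mimicking
    human vs zebrafish symbol conventions; each one-to-many species-A gene
    maps to exactly two species-B genes.
    """
    pairs: list[tuple[str, str]] = []
    genes_a: list[str] = []
    genes_b: list[str] = []
    for i in range(p.n_pairs_one2one):
        a, b = f"GA{i:05d}", f"gb{i:05d}"
        pairs.append((a, b))
        genes_a.append(a)
        genes_b.append(b)
    for i in range(p.n_pairs_one2many):
        a = f"GM{i:05d}"
        genes_a.append(a)
        for rep in (1, 2):
            b = f"gm{i:05d}.{rep}"
            pairs.append((a, b))
            genes_b.append(b)
    genes_a += [f"UA{i:05d}" for i in range(p.n_unique_genes_per_species)]
    genes_b += [f"ub{i:05d}" for i in range(p.n_unique_genes_per_species)]
    return OrthologTable.from_pairs(pairs), genes_a, genes_b


def simulate_paired_experiment(p: SimParams, return_means: bool = False) -> SimResult:
    """Generate both species' count bundles plus the planted ground truth."""
    rng = np.random.default_rng(p.seed)
    ortho, genes_a, genes_b = simulate_ortholog_map(p)
    n_paired_a = p.n_pairs_one2one + p.n_pairs_one2many
    n_paired_b = p.n_pairs_one2one + 2 * p.n_pairs_one2many
    n_a = len(genes_a)
    n_b = len(genes_b)

    # program units: one per species-A paired gene, plus per-species uniques;
    # one-to-many partners inherit their pair's species-A program
    unit_of_b = np.empty(n_paired_b, dtype=np.int64)
    unit_of_b[: p.n_pairs_one2one] = np.arange(p.n_pairs_one2one)
    for i in range(p.n_pairs_one2many):
        unit_of_b[p.n_pairs_one2one + 2 * i] = p.n_pairs_one2one + i
        unit_of_b[p.n_pairs_one2one + 2 * i + 1] = p.n_pairs_one2one + i

    baseline_paired = p.base_mean * np.exp(
        rng.normal(0.0, p.baseline_sigma, n_paired_a)
    )
    baseline_uniq_a = p.base_mean * np.exp(
        rng.normal(0.0, p.baseline_sigma, p.n_unique_genes_per_species)
    )
    baseline_uniq_b = p.base_mean * np.exp(
        rng.normal(0.0, p.baseline_sigma, p.n_unique_genes_per_species)
    )

    theta_paired = rng.normal(0.0, p.type_program_sigma, (n_paired_a, p.n_types))
    theta_uniq_a = rng.normal(0.0, p.type_program_sigma, (p.n_unique_genes_per_species, p.n_types))
    theta_uniq_b = rng.normal(0.0, p.type_program_sigma, (p.n_unique_genes_per_species, p.n_types))

    # markers: disjoint across types, drawn from the paired units
    n_marker_total = p.marker_genes_per_type * p.n_types
    marker_units = rng.choice(n_paired_a, size=min(n_marker_total, n_paired_a), replace=False)
    marker_rows = []
    for t in range(p.n_types):
        for u in marker_units[t * p.marker_genes_per_type : (t + 1) * p.marker_genes_per_type]:
            theta_paired[u, t] += p.marker_logfc
            ga = genes_a[u]
            for gb_idx in np.flatnonzero(unit_of_b == u):
                marker_rows.append({"type": t, "gene_a": ga, "gene_b": genes_b[gb_idx]})
    marker_truth = pd.DataFrame(marker_rows, columns=["type", "gene_a", "gene_b"])

    # condition effects: planted on expressed one2one pairs, disjoint across
    # types, with per-species signs concordant for a frac_synergistic share
    delta_a = np.zeros((n_paired_a, p.n_types))
    delta_b = np.zeros((n_paired_a, p.n_types))
    de_rows = []
    if p.n_de_per_type > 0 and p.de_logfc != 0.0:
        eligible = np.flatnonzero(
            (np.arange(n_paired_a) < p.n_pairs_one2one)
            & (baseline_paired >= p.base_mean)
            & ~np.isin(np.arange(n_paired_a), marker_units)
        )
        need = p.n_de_per_type * p.n_types
        if need > eligible.size:
            raise ValueError(
                f"cannot plant {need} condition effects: only {eligible.size} "
                "expressed one-to-one pairs available"
            )
        de_units = rng.choice(eligible, size=need, replace=False)
        for t in range(p.n_types):
            for u in de_units[t * p.n_de_per_type : (t + 1) * p.n_de_per_type]:
                sign_a = 1.0 if rng.random() < 0.5 else -1.0
                concordant = rng.random() < p.frac_synergistic
                sign_b = sign_a if concordant else -sign_a
                delta_a[u, t] = sign_a * p.de_logfc
                delta_b[u, t] = sign_b * p.de_logfc
                de_rows.append(
                    {
                        "type": t,
                        "gene_a": genes_a[u],
                        "gene_b": genes_b[u],  # one2one: same index
                        "logfc_a": delta_a[u, t],
                        "logfc_b": delta_b[u, t],
                        "synergistic": bool(concordant),
                    }
                )
    de_truth = pd.DataFrame(
        de_rows, columns=["type", "gene_a", "gene_b", "logfc_a", "logfc_b", "synergistic"]
    )

    # batch-like species shift, per species-B gene, shared across its cells
    shift_b = np.exp(rng.normal(0.0, p.species_shift_sigma, n_b))

    n_grp = p.cells_per_type_per_species_per_condition
    cell_rows = []
    bundles = {}
    means_out: dict[str, np.ndarray] = {}
    for species in (SPECIES_A, SPECIES_B):
        if species == SPECIES_A:
            genes = genes_a
            base = np.concatenate([baseline_paired, baseline_uniq_a])
            theta = np.vstack([theta_paired, theta_uniq_a])
            delta = np.vstack([delta_a, np.zeros((p.n_unique_genes_per_species, p.n_types))])
            gene_shift = np.ones(n_a)
        else:
            genes = genes_b
            base = np.concatenate(
                [baseline_paired[unit_of_b], baseline_uniq_b]
            )
            theta = np.vstack([theta_paired[unit_of_b], theta_uniq_b])
            delta = np.vstack(
                [delta_b[unit_of_b], np.zeros((p.n_unique_genes_per_species, p.n_types))]
            )
            gene_shift = shift_b
        n_genes = len(genes)
        cols = []
        barcodes = []
        meta_rows = []
        for t in range(p.n_types):
            for condition in (CONTROL, CASE):
                lib = np.exp(rng.normal(0.0, p.libsize_sigma, n_grp))
                log_mu = np.log(base) + theta[:, t]
                if condition == CASE:
                    log_mu = log_mu + delta[:, t]
                mu = (np.exp(log_mu) * gene_shift)[:, None] * lib[None, :]
                r = p.dispersion
                counts = rng.negative_binomial(r, r / (r + mu))
                cols.append(counts)
                for i in range(n_grp):
                    bc = f"{species}:t{t}:{condition}:{i:04d}"
                    barcodes.append(bc)
                    meta_rows.append(
                        {
                            "barcode": bc,
                            "species": species,
                            "condition": condition,
                            "sample": f"{species}_{condition}",
                        }
                    )
                    cell_rows.append(
                        {"barcode": bc, "species": species, "type": t, "condition": condition}
                    )
                if return_means:
                    means_out.setdefault(species, []).append(mu)
        counts = sp.csr_matrix(np.hstack(cols))
        meta = pd.DataFrame(meta_rows).set_index("barcode")
        bundles[species] = CountMatrix(
            counts=counts, gene_ids=list(genes), barcodes=barcodes, cell_meta=meta
        )
        if return_means:
            means_out[species] = np.hstack(means_out[species])

    truth = GroundTruth(
        cell_truth=pd.DataFrame(cell_rows, columns=["barcode", "species", "type", "condition"]),
        de_truth=de_truth,
        marker_truth=marker_truth,
    )
    return SimResult(
        bundle_a=bundles[SPECIES_A],
        bundle_b=bundles[SPECIES_B],
        ortholog=ortho,
        truth=truth,
        genes_a=genes_a,
        genes_b=genes_b,
        means=means_out if return_means else None,
    )


def write_ground_truth(gt: GroundTruth, dir_path: str | Path) -> None:
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    write_tsv(gt.cell_truth, dir_path / "cell_truth.tsv")
    write_tsv(gt.de_truth, dir_path / "de_truth.tsv")
    write_tsv(gt.marker_truth, dir_path / "marker_truth.tsv")


def read_ground_truth(dir_path: str | Path) -> GroundTruth:
    dir_path = Path(dir_path)
    cell = pd.read_csv(dir_path / "cell_truth.tsv", sep="\t")
    de = pd.read_csv(dir_path / "de_truth.tsv", sep="\t")
    marker = pd.read_csv(dir_path / "marker_truth.tsv", sep="\t")
    return GroundTruth(cell_truth=cell, de_truth=de, marker_truth=marker)
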