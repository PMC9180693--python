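# scortho

Cross-species single-cell / single-nucleus transcriptomics comparison on an
ortholog-derived composite gene namespace.

## The problem

Comparing the cellular response to a disease across two species — say, a
zebrafish amyloid-toxicity model against human Alzheimer's disease brain
data — requires putting both species' expression matrices on one gene axis.
Orthology is not one-to-one: a human gene may have several zebrafish
co-orthologs, many genes have none, and gene identifiers differ. `scortho`
implements the composite-namespace approach: every ortholog pair
(gene_a, gene_b) becomes one artificial gene id `gene_a|gene_b`, so a
one-to-many gene contributes one matrix row per pair (its counts are
duplicated), species-unique genes drop out, and both species' cells share a
single matrix that can be clustered jointly.

On top of that namespace the package provides the downstream comparison
machinery:

- **Joint clustering** — depth normalization to 10,000 counts/cell with
  log1p, top-2000 variable genes by mean-binned normalized dispersion,
  per-gene scaling with total-count regression (clipped at ±10), 30-PC PCA,
  a shared-nearest-neighbor kNN graph (k = 20, Jaccard weights), and Leiden
  community detection at resolution 0.5.
- **Composite-cluster composition** — which clusters contain cells of every
  species, and what share of all cells they hold.
- **Transition analysis** — cross-tabulation of the same cells clustered on
  all native genes vs. on ortholog genes only, quantifying how much the
  ortholog restriction perturbs cell-type structure.
- **Differential expression** — a two-sided Wilcoxon rank-sum test written
  from first principles (exact tail enumeration for small groups without
  ties, tie-corrected normal approximation with continuity correction
  otherwise), fold changes `ln(mean(expm1(x₁)) + 1) − ln(mean(expm1(x₂)) + 1)`,
  and Benjamini–Hochberg FDR control, applied per cluster
  (condition vs. control) or one-vs-rest (markers).
- **Synergy classification** — an ortholog pair significant in both species
  is *synergistic* when `sign(logFC_a) = sign(logFC_b)` and
  *non-synergistic* when the signs oppose; conserved vs. species-specific
  responses fall out directly.
- **Gene-set over-representation** — upper-tail hypergeometric
  `P(X ≥ overlap)` against user-supplied GMT collections, with
  common / species-specific / inconsistent categorization across analyses,
  and cross-species marker-overlap statistics.
- **A synthetic paired-species generator** — negative-binomial counts with
  shared cell-type programs, a one-to-one/one-to-many ortholog map,
  library-size and species batch effects, and planted condition effects
  with a controlled concordant fraction, so every stage is testable with
  known ground truth and no downloads.

## Worked example

```python
from scortho import (SimParams, simulate_paired_experiment, integrate, PipelineConfig,
                     per_cluster_condition_de, intersect_degs, normalize_log,
                     filter_cells, filter_genes, ClusterLabels)

sim = simulate_paired_experiment(SimParams(seed=0))
res = integrate([sim.bundle_a], [sim.bundle_b], sim.ortholog, PipelineConfig(seed=0))
print(f"clusters: {res.labels.n_clusters}")
print(f"cells in composite clusters: {res.composition.pct_cells_in_composite:.1f}%")

def de_tables(bundle):
    m = filter_genes(filter_cells(bundle, 200), 5)
    norm = normalize_log(m)
    lab = res.labels.as_series().loc[norm.barcodes]
    labels = ClusterLabels(barcodes=list(norm.barcodes), labels=lab.to_numpy(),
                           resolution=0.5, seed=0)
    tables, _ = per_cluster_condition_de(norm, labels, "condition", "case", "control")
    return tables

ta, tb = de_tables(sim.bundle_a), de_tables(sim.bundle_b)
syn = intersect_degs(ta[0], tb[0], sim.ortholog, alpha=0.05)
print(f"cluster 0: {syn.n_common} shared DEG pairs "
      f"({syn.n_synergistic} synergistic, {syn.n_non_synergistic} non-synergistic)")
rec = syn.records.iloc[0]
print(f"example pair {rec.composite_id}: "
      f"logFC_a={rec.logfc_a:+.3f}, logFC_b={rec.logfc_b:+.3f} -> {rec.synergy}")
```

prints

```
clusters: 4
cells in composite clusters: 100.0%
cluster 0: 53 shared DEG pairs (30 synergistic, 23 non-synergistic)
example pair GA00046|gb00046: logFC_a=+0.625, logFC_b=-0.551 -> non_synergistic
```

The generator planted four shared cell types across both species; joint
clustering recovers exactly those four, every cluster holds cells of both
species (100% composite), and within cluster 0 the case-vs-control DEG
lists of the two species intersect in 53 ortholog pairs whose fold-change
directions split into concordant and discordant responses.

The same workflows are scriptable from a shell:

```sh
scortho simulate  --outdir run --seed 0
scortho integrate --bundle-a run/bundle_a --bundle-b run/bundle_b \
                  --ortholog-table run/orthologs.tsv --seed 0 --outdir run/joint
scortho de        --bundle run/bundle_a --clusters run/joint/clusters.tsv \
                  --case case --control control --outdir run/de_a
```

Every run writes a `manifest.json` (command, config snapshot, seed, paths)
sufficient to reproduce it.

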