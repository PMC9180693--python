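# Methods

## Composite ortholog namespace

The cross-species gene axis is built from a user-supplied table of ortholog
pairs (gene_a, gene_b). Each pair becomes exactly one composite id
`gene_a|gene_b` (the separator is reserved and validated against the input
ids), ordered deterministically by (gene_a, gene_b). Remapping a species'
count matrix onto the namespace copies each source gene's row into every
composite position it participates in, so a one-to-many gene is duplicated;
rows whose source gene is absent stay all-zero, and source genes outside
the namespace are dropped. Two consequences are deliberate:

- total counts satisfy a duplication law — output total = Σ over source
  genes (pair multiplicity × source counts) — which the tests check against
  brute-force bookkeeping;
- per-cell library sizes inflate under duplication, so depth normalization
  is always computed **after** remapping. All downstream totals (including
  the regression covariate) refer to the remapped matrix.

Relation classes (one2one / one2many / many2one / many2many) are assigned
per connected ortholog group: within the set of genes linked through shared
partners, fanning out on the A side only is one2many, on the B side only is
many2one, on both is many2many. A group-level definition keeps the label
consistent for every pair of a tangle such as {(A1,b1), (A2,b1), (A1,b2)},
which is many2many throughout. many2many pairs are accepted (one row per
pair, like all others) and flagged in the namespace TSV.

Gene ids are opaque, case-sensitive strings: human-style upper-case and
zebrafish-style lower-case symbols are never case-folded.

## Preprocessing

Defaults (all in `PipelineConfig`, overridable by a `key = value` config
file):

| parameter | default | meaning |
| --- | --- | --- |
| `min_cell_counts` | 200 | keep cells with total counts ≥ 200 (strict "fewer than 200 removed") |
| `min_cells_per_gene` | 5 | keep genes detected (count > 0) in ≥ 5 cells |
| `target_sum` | 10,000 | per-cell depth target before log1p |
| `n_hvg` | 2,000 | variable genes retained for embedding |
| `n_pcs` | 30 | principal components |
| `knn_k` | 20 | neighbors in the SNN graph |
| `resolution` | 0.5 | Leiden resolution |
| `alpha` | 0.05 | significance level for downstream intersections |
| `min_pct` | 0.1 | detection prefilter for DE (either group) |

Normalization is `ln(1 + count / cell_total × target_sum)` — natural log
with pseudocount 1, matching the convention of the Seurat lineage this
pipeline follows. Variable genes are ranked by normalized dispersion
(variance/mean of normalized values) standardized within 20 equal-frequency
mean bins. Standardization per bin is robust — median and MAD (scaled by
1.4826; falling back to the bin SD when the MAD is zero) — rather than mean
and SD: when a bin happens to contain many genuinely variable genes, moment
estimates absorb them into the bin's own scale and mask them, whereas the
median tracks the quiet majority. With fewer than ~200 expressed genes the
bin count shrinks (one bin per ~10 genes) so per-bin statistics stay
meaningful.

Scaling residualizes each gene on the covariates (ordinary least squares
with intercept; the per-cell total count by default, a user-supplied
mitochondrial-fraction covariate optionally — mito genes come from an
explicit id list, never a hard-coded prefix, since the two species name
them differently), then z-scores per gene and clips at ±10 to bound PCA
leverage. Genes with zero residual variance become all-zero rows instead of
being dropped, keeping shapes stable; constant covariates are dropped with
a warning.

## Joint embedding and clustering

Both species' remapped matrices are pooled and processed as one dataset:
normalize → HVG → scale (totals regressed across all cells jointly) → PCA →
SNN graph → Leiden. This replaces anchor-based batch integration with joint
scaling on the shared namespace; the contract it must satisfy — and which
the end-to-end tests enforce — is that with species-balanced shared cell
types and modest per-gene species shifts (≲ 0.25 log units), shared types
co-cluster (≥ 95% of cells in composite clusters). It is *not* expected to
absorb strong batch structure; a generator preset with larger species
shifts will degrade co-clustering, by design.

PCA uses a full deterministic SVD with a fixed sign convention (the
largest-magnitude loading of each component is positive). The kNN graph
uses Euclidean distance in PC space, k nearest excluding self, distance
ties broken by index order; an edge joins two cells when either is a
neighbor of the other and carries the Jaccard overlap of their neighbor
sets (zero-overlap edges are pruned). Leiden optimizes the
RB-configuration modularity at the given resolution, is deterministic given
its seed, and labels are renumbered by decreasing cluster size (ties by
smallest original label) so runs are comparable.

A cluster is *composite* when every species present in the data contributes
at least `min_cells_per_species` cells (default 1 — a cluster with a single
foreign cell already fails "only one species"); the headline statistic is
the percentage of all cells sitting in composite clusters.

The transition analysis clusters one species twice — all native genes vs.
genes appearing in the ortholog table — on the same cells (QC survivors of
the all-genes run) and cross-tabulates the two labelings. Row percentages
divide by the source-class size and the all-cells percentages by the total;
cluster-to-named-type lifting is taken from user-supplied mapping tables,
never inferred.

## Differential expression

The test is the two-sided Wilcoxon rank-sum on depth-normalized log values.
When the smaller group has ≤ 8 cells and the gene has no tied values the
tail probabilities come from exact enumeration of the rank-sum distribution
(a dynamic-programming count of subsets, two-sided p = min(1, 2·min(P(W ≤
w), P(W ≥ w)))); otherwise the normal approximation with the standard
tie-corrected variance and a 0.5 continuity correction. Fold change is
`ln(mean(expm1(x₁)) + 1) − ln(mean(expm1(x₂)) + 1)` — the Seurat-v3-era
convention; `logfc_base = "2"` switches the reported scale to log2. Genes
are tested only when detected in ≥ `min_pct` of either group; oracle-style
exhaustive runs set `min_pct = 0`. BH adjustment is applied within each
table.

Significance for cross-species intersection defaults to raw p < α — the
convention of the workflow this reproduces, whose reported per-gene
p-values in the 0.01–0.04 range are treated as calls — with `use_padj`
switching to adjusted p throughout. Both p and adjusted p are always
reported.

## Synergy, enrichment, overlap

DEG intersection is at ortholog-pair granularity: each pair whose two genes
are both significant yields one record, so one-to-many genes can contribute
several; a collapsed count of distinct species-A genes is reported
alongside, since gene-level and pair-level tallies differ exactly when
one-to-many pairs are involved. Labels: synergistic iff the fold-change
signs agree and neither is zero, non-synergistic iff they oppose, undefined
iff either is exactly zero; `n_common = n_syn + n_nonsyn + n_undef` by
construction and by test.

Enrichment is the upper-tail hypergeometric p = P(X ≥ overlap) with the
universe as population, the set (intersected with the universe) as
successes and the query as draws — over-representation only, BH-adjusted
across sets. Query genes outside the universe are dropped with a warning.
Pathway categorization across analyses uses set membership of significant
names: *common* requires a hit in every species-A analysis and in species
B, *other* marks names significant in some but not all same-species
analyses (e.g. one brain region but not the other), and the
species-specific categories require full agreement within the species.
Because only significant-name sets cross this interface, "not significant"
and "not tested" are indistinguishable here; callers who need the
distinction should restrict the analyses to a shared tested universe first.

Marker overlap maps species-B markers onto species-A ids through the
ortholog table (union over partners) and reports
100 × |shared| / |markers_A|.

## Synthetic data generator

Counts are negative binomial with mean μ and size r (variance μ + μ²/r; the
"dispersion" parameter is the size r, stated explicitly because the word is
overloaded). For a gene g in cell c of type t, condition d, species s:

μ = baseline_g · exp(θ_{g,t}) · exp(δ_{g,t,s}·[d = case]) · shift_{g,s} · lib_c

- baseline_g = `base_mean` · exp(N(0, `baseline_sigma`²)) — log-normal spread
  of expression levels;
- θ_{g,t} ~ N(0, `type_program_sigma`²) per ortholog pair, **shared across
  species** (one-to-many partners inherit their pair's species-A program) —
  this is what makes shared types co-cluster; species-unique genes get
  independent programs per species;
- marker genes add `marker_logfc` to θ for their type;
- condition effects δ = ±`de_logfc` are planted on expressed one-to-one
  pairs (baseline ≥ `base_mean`, markers excluded — a recovery benchmark on
  genes below the detection floor would measure nothing), disjoint across
  types; the species-B sign equals the species-A sign with probability
  `frac_synergistic`;
- shift_{g,s} = exp(N(0, `species_shift_sigma`²)) per species-B gene — a
  batch-like species effect shared by all cells;
- lib_c = exp(N(0, `libsize_sigma`²)) — library-size variation.

Defaults: 4 types × 2 conditions × 300 cells per species (2,400
cells/species, 4,800 jointly), 1,400 one2one + 50 one2many pairs (1,500
pairs), 200 unique genes/species, base_mean 0.5, r = 2, baseline_sigma 1.0,
type_program_sigma 0.4, marker_logfc 1.5 (20 markers/type), de_logfc = ln 2
(50 pairs/type), frac_synergistic 0.6, species_shift_sigma 0.15,
libsize_sigma 0.3. The species shift is sized within the joint-scaling
contract above. All draws flow from a single seeded generator; identical
parameters give bit-identical bundles. Setting `de_logfc = 0` plants
nothing and the experiment is a clean null.

What the generator does **not** emulate: ambient RNA and empty droplets,
doublets, per-sample donor variability beyond the single species shift,
realistic gene-name content, zero-inflation beyond the NB, or continuous /
transitional cell states. Passing tests therefore demonstrate correctness
of the machinery under the stated model, not robustness to every artifact
of real droplet data.

## Numerical and design notes

- Exact-path threshold for the rank-sum test: min(n₁, n₂) ≤ 8, no ties.
- BH is the textbook step-up: sort, multiply by m/rank, running minimum
  from the largest rank, cap at 1, return in input order.
- Hypergeometric tails come from `scipy.stats.hypergeom.sf(k − 1, …)`; the
  test suite checks them against explicit binomial-coefficient sums for
  every universe up to size 20.
- transition rows and totals are exact integer cross-tabulations;
  percentage rows sum to 100 to ≤ 1e-9.
- Cluster-size relabeling, PCA sign fixing, kNN tie order, and HVG
  tie-breaking (file order) exist solely to make identical inputs produce
  identical outputs everywhere.
- Degenerate inputs are errors, not silent passes: empty graphs, zero-total
  cells at normalization, groups under 3 cells, empty universes, empty
  barcode intersections.

## Problem sizes used by the tests and the acceptance script

Unit tests run on hand-sized matrices and a reduced generator preset (4
types × 80 cells/group, 310 pairs). The end-to-end checks use the default
preset (2,400 cells/species) over seeds 0–4; DE recovery uses 200 cells per
arm with ln 2 effects; the null calibration pools ≥ 2,000 tested genes per
seed. The acceptance script covers the same ground single-pass from a
user-supplied master seed, deriving one sub-seed per stage.

## Known limitations

- No anchor/CCA-style batch correction: strong species or batch shifts are
  out of contract.
- DE is two-group rank-sum only — no covariate adjustment, pseudobulk, or
  mixed models; cells are treated as exchangeable replicates.
- Enrichment is annotation-agnostic: the GMT supplies the sets, and no
  GO-graph structure (parent/child pruning) is used.
- The composite namespace requires the ortholog table up front; it never
  queries an annotation service at runtime.
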