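# Methods

## Scope and rationale

`plaquemap` re-implements, as a tested and reusable pipeline, the analysis
that assigns GWAS risk loci to cell populations of a single-cell
transcriptome: per-cluster differential expression, grouping of DEGs into
population-matched expression patterns, positional locus-to-gene candidate
prioritisation, permutation-based global and per-pattern enrichment, and a
cross-dataset marker-overlap test for matching cluster identities between
studies. The original patient data (carotid-endarterectomy plaques) and the
external GWAS summary statistics are not redistributable, so the package
treats the *procedure* as the artifact and validates it on synthetic data
with planted ground truth.

## Generative model of the synthetic data

Counts for gene *g* in cell *c* of population *p* are negative binomial,

    count ~ NB(mean = s_c · μ_g · f_{g,p},  Var = μ + φ·μ²)

with

- `μ_g ~ LogNormal(-1.2, 0.8)` — gene baseline means. These defaults give a
  median per-gene-per-cell mean of ≈0.3 and ≈800 counts per cell over 2000
  genes, a plausible scale for plate-based single-cell protocols, and keep
  all but the bottom ~1% of genes informative for rank-based testing.
- `s_c ~ LogNormal(0, 0.35)` — library-size factors (≈±70% 2σ range).
- `φ = 0.5` — dispersion, a typical single-cell overdispersion level.
- `f_{g,p}` — the planted marker fold: `marker_fold` (default 4) when *g* is
  a marker of *p*, else 1. Marker lists are disjoint across populations.
- Mixed cells: a configurable fraction of cells averages the mean vectors of
  two randomly drawn parent populations (50/50), modelling a low-identity
  cluster of apoptotic/doublet-like cells. They carry a dedicated `Mixed`
  label by default, or can be assigned to their first parent.

The default **plaque preset** has 3282 cells in 14 populations with the
composition of an advanced carotid plaque: four T-cell clusters totalling
52.4% of cells, a five-cluster myeloid block at 18.5% (three macrophage
clusters, dendritic cells, mast cells), a 10% mixed cluster, B cells, smooth
muscle cells and two endothelial clusters. Each pure population carries 20
planted markers at fold 4.

What the generator does **not** emulate: linkage-disequilibrium structure,
batch effects, UMI saturation, doublet kinetics, gene–gene correlation
beyond the population structure, and realistic annotation geometry (genes
are tiled uniformly). Passing tests therefore demonstrate correctness of the
algorithms and their statistical calibration under the stated model — not
performance on any particular real tissue.

## Differential expression

One-vs-rest two-sided Wilcoxon rank-sum per (gene, cluster) on CP10K log1p
values, using the tie-corrected normal approximation with continuity
correction (numerically identical to `scipy.stats.mannwhitneyu(method=
"asymptotic")`, verified in tests; the 6-vs-6 worked example agrees with the
exhaustive C(12,6) permutation distribution within 0.02). Genes expressed in
fewer than 3 cells are excluded from testing *and* from the universe. BH
runs once over the whole (gene, cluster) table — a single error budget for
the union DEG set that feeds the patterns. The log₂ fold change is computed
on expm1-scale cluster means with pseudocount 1e-9. Clusters with fewer
than 3 cells are skipped with a warning. The test is two-sided with a signed
fold change retained, so the DEG set contains both up- and down-regulated
genes; this is the configurable default since marker calling conventions
differ on the point.

## Expression patterns

The pattern step is the most inferential part of the pipeline: a
block-structured heatmap of DEGs by cluster is the target output, and the
simplest procedure consistent with it is k-means on row-z-scored per-cluster
mean profiles. Choices made for reproducibility:

- k-means++ initialisation, Lloyd iterations, `n_restarts` (default 50)
  independent starts from a seeded generator, keeping the lowest
  within-cluster sum of squares (the sklearn implementation stands behind
  this contract; on 8-point instances it attains the exhaustive-enumeration
  optimum in tests);
- patterns re-indexed by descending member count, ties by smallest original
  index, and centroids recomputed as the mean of member z-profiles;
- K defaults to 15 and is deliberately configurable — there is no canonical
  relation between the number of patterns and the number of populations (a
  pattern can span several populations, e.g. an SMC+EC matrix-gene
  programme, and one population can split);
- annotation threshold `z_annot = 1.0`: a pattern is labelled with every
  population whose centroid z-score reaches 1 (≈ one standard deviation
  above that gene set's mean expression level), with an argmax fallback so
  no pattern is ever unlabelled.

A zero-variance DEG profile (flat across clusters) is z-scored to the zero
vector with a warning rather than dropped, so the pattern partition always
covers the DEG set exactly.

## Locus clumping and gene mapping

Distance-based greedy clumping stands in for LD clumping (no reference
panel is bundled): filter to `p ≤ 5×10⁻⁸` and `MAF ≥ 0.01` (missing MAF
passes, with a warning — public summary tables often omit it), then per
chromosome repeatedly take the most significant unassigned variant as lead
and absorb all significant variants within 500 kb. Ties in p-value break by
position, then variant id, making the output invariant to input row order.
Gene mapping is positional: protein-coding genes whose body ±100 kb
intersects the locus span, deduplicated across loci by minimal distance.
GWAS positions are 1-based, annotations BED 0-based half-open; conversion
happens once, inside the mapping step.

## Enrichment statistics

"Permutation over random data" is operationalised as uniform resampling of
gene sets of matched size: from the expression universe for the global
overlap test, from the DEG set for the per-pattern accumulation tests. Both
universes are explicit and logged because the choice of null population is
the single most consequential free parameter of such tests. The estimator is
`p = (b+1)/(n+1)`, so p = 0 is impossible and the minimum attainable p is
`1/(n_perm+1)`. Tests are one-sided for enrichment; depletion is reported
descriptively via fold enrichment < 1. The exact hypergeometric upper tail
is always co-reported; for uniform nulls it is the n_perm→∞ limit of the
permutation p, which the tests verify against exhaustive and exact-integer
enumeration to 1e-12. One shared draw stream is reused across patterns —
cheap, reproducible, and statistically harmless since the per-pattern counts
of one draw are used marginally. Raw permutation p-values are the primary
output; BH-adjusted q-values are an explicitly flagged add-on.

## Cross-dataset cluster matching

Upper-tail hypergeometric overlap of top-N (default 100) marker lists over
the harmonised gene universe, BH-corrected jointly over all query×reference
pairs, significance at q < 0.05. Symbol harmonisation defaults to
case-folding (the usual human/mouse bridge); an orthology map file overrides
it, with many-to-many rows dropped and counted. Marker lists are restricted
to the shared universe *before* capping at N, so the cap compares like with
like across datasets.

## Determinism and seeding

Every stage seed derives from the master seed and the stage name
(SHA-256, reduced to 31 bits), so toggling one stage never perturbs
another's randomness. Two runs with the same config are byte-identical in
every TSV/JSON output except `timings.json`, which holds per-stage
wall-clock and is documented as volatile.

## Validation problem sizes

The statistical guarantees are measured at sizes chosen to balance
resolution against desk-scale runtimes, all fixed in the test suite:

- DEG recovery: 20 simulations of 5 populations × 50 cells, 1000 genes, 20
  markers each at fold 4, dispersion 0.5 — planted-marker sensitivity ≥0.90
  and gene-level empirical FDR ≤1.5× the nominal α.
- Per-pattern type-I error: 200 null datasets (no planted enrichment) with a
  2000-gene universe, 600 DEGs in 10 patterns of unequal sizes (120…20) and
  150 uniformly drawn candidates, n_perm = 2000. The candidate count is set
  high enough that per-pattern overlaps resolve the 0.05 level at all; the
  discreteness of overlap counts still makes the test conservative, so the
  measured rejection rate sits at the low end of the nominal band (≈0.03).
- Planted-pattern recovery: 100 runs, 30 candidates with 40% planted into
  one of 10 patterns of 60 — the planted pattern must attain the unique
  minimum permutation p in ≥95 runs.
- Oracle agreement: universe 200 / DEG 50 / candidates 20 at 20 000
  permutations across 10 seeds, within 3 Monte-Carlo standard errors of the
  hypergeometric tail.

## Known limitations

- Positional ±100 kb mapping is deliberately simpler than LD/eQTL/chromatin
  prioritisation; candidate sets on real data will differ from FUMA-style
  pipelines, which is why a precomputed gene list can bypass the mapping.
- The k-means pattern procedure is one reasonable realisation of
  "patterns that best match the populations"; soft or hierarchical
  alternatives are out of scope.
- Gene identity is by symbol (case-sensitive within a species); only the
  cross-dataset module harmonises namespaces.
- The permutation null draws genes uniformly; expression-, length- or
  GC-matched nulls are not implemented.
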