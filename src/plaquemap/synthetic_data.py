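"""Synthetic plaque-like single-cell fixtures with planted structure.

The count simulator emulates the statistical shape of a digested-plaque
scRNA-seq experiment: a handful of discrete cell populations of very
unequal sizes (T cells dominating at roughly half the cells, a myeloid
block near a fifth), population-specific marker genes elevated over a
shared negative-binomial background, log-normal library-size variation,
and an optional low-identity "mixed" population whose cells are 50/50
mixtures of two randomly chosen parent populations (the apoptotic
myeloid/T-cell cluster analog).

The GWAS fixture tiles the simulated genes along artificial chromosomes
and plants one genome-wide-significant variant inside each chosen gene
body, surrounded by null decoy variants, so that locus clumping plus
positional mapping has an exactly known right answer.

All generators are pure functions of (design, seed): the same design and
seed reproduce bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (
    ClusterAssignment,
    CountMatrix,
    GeneAnnotation,
    GwasTable,
    ValidationError,
)
import scipy.sparse as sp

GENOME_WIDE_SIG = 5e-8


@dataclass
class Population:
    label: str
    n_cells: int
    marker_genes: list  # gene indices into the simulated gene list
    marker_fold: float


@dataclass
class SimulationDesign:
    """Generative design for a plaque-like count matrix.

    Counts for gene g in cell c of population p are negative binomial with
    mean ``s_c · μ_g · f_{g,p}`` and variance ``μ + dispersion·μ²``, where
    s_c is a log-normal library-size factor, μ_g a log-normal gene
    baseline, and f the marker fold (1 for non-markers).  Mixed cells
    average the mean vectors of two distinct parent populations.
    """

    n_genes: int
    populations: list
    baseline_mean_logmu: float = -1.2
    baseline_mean_logsigma: float = 0.8
    dispersion: float = 0.5
    libsize_logsigma: float = 0.35
    mixed_fraction: float = 0.0
    mixed_label: str = "Mixed"
    mixed_assignment: str = "mixed"  # "mixed" or "parent"
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be ≥1")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be >0")
        if self.libsize_logsigma < 0:
            raise ValidationError("libsize_logsigma must be ≥0")
        if not (0 <= self.mixed_fraction < 1):
            raise ValidationError("mixed_fraction must lie in [0,1)")
        if self.mixed_assignment not in ("mixed", "parent"):
            raise ValidationError("mixed_assignment must be 'mixed' or 'parent'")
        if self.mixed_fraction > 0 and len(self.populations) < 2:
            raise ValidationError("mixed cells need ≥2 parent populations")
        seen = set()
        for pop in self.populations:
            if pop.n_cells < 2:
                raise ValidationError(f"population {pop.label}: need ≥2 cells")
            if pop.marker_fold <= 1:
                raise ValidationError(f"population {pop.label}: marker_fold must be >1")
            idx = set(int(i) for i in pop.marker_genes)
            if idx and max(idx) >= self.n_genes:
                raise ValidationError(
                    f"population {pop.label}: marker gene index ≥ n_genes"
                )
            if min(idx, default=0) < 0:
                raise ValidationError(f"population {pop.label}: negative marker index")
            if idx & seen:
                raise ValidationError("marker gene lists overlap across populations")
            seen |= idx


@dataclass
class TruthTable:
    """Ground truth of a simulation: full gene list and planted markers."""

    genes: list
    markers: pd.DataFrame  # columns: gene, population, fold

    def markers_of(self, labels) -> list:
        if isinstance(labels, str):
            labels = [labels]
        sub = self.markers[self.markers["population"].isin(list(labels))]
        return sub["gene"].tolist()

    @property
    def marker_genes(self) -> set:
        return set(self.markers["gene"])


def gene_names(n_genes: int) -> list:
    width = max(4, len(str(n_genes - 1)))
    return [f"G{i:0{width}d}" for i in range(n_genes)]


def simulate_counts(design: SimulationDesign):
    """Draw a count matrix, its cluster truth, and the marker truth table.

    Returns ``(CountMatrix, ClusterAssignment, TruthTable)``.  Cells are
    ordered population by population (design order) with mixed cells
    appended; barcodes are ``cell000000`` …

    The rng draw order is part of the contract (it lets tests replay the
    latent variables): gene baselines μ_g first, then library sizes s_c,
    then mixed-cell parent pairs, then the count matrix.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    genes = gene_names(design.n_genes)
    mu = rng.lognormal(design.baseline_mean_logmu, design.baseline_mean_logsigma, design.n_genes)

    n_listed = sum(p.n_cells for p in design.populations)
    f = design.mixed_fraction
    n_mixed = int(round(f / (1 - f) * n_listed)) if f > 0 else 0
    n_cells = n_listed + n_mixed

    libsize = rng.lognormal(0.0, design.libsize_logsigma, n_cells)

    # per-population mean vectors (library size applied per cell below)
    pop_means = []
    for pop in design.populations:
        fold = np.ones(design.n_genes)
        fold[np.asarray(pop.marker_genes, dtype=int)] = pop.marker_fold
        pop_means.append(mu * fold)
    pop_means = np.asarray(pop_means)  # n_pops × n_genes

    means = np.empty((n_cells, design.n_genes))
    labels = []
    col = 0
    for j, pop in enumerate(design.populations):
        means[col : col + pop.n_cells] = pop_means[j]
        labels.extend([pop.label] * pop.n_cells)
        col += pop.n_cells
    if n_mixed:
        n_pops = len(design.populations)
        parents = np.empty((n_mixed, 2), dtype=int)
        for i in range(n_mixed):
            parents[i] = rng.choice(n_pops, size=2, replace=False)
        means[col:] = 0.5 * (pop_means[parents[:, 0]] + pop_means[parents[:, 1]])
        if design.mixed_assignment == "mixed":
            labels.extend([design.mixed_label] * n_mixed)
        else:
            labels.extend(design.populations[p].label for p in parents[:, 0])

    means *= libsize[:, None]
    r = 1.0 / design.dispersion
    p = r / (r + means)
    counts = rng.negative_binomial(r, p).astype(np.int64)  # cells × genes

    barcodes = [f"cell{i:06d}" for i in range(n_cells)]
    cm = CountMatrix(genes, barcodes, sp.csr_matrix(counts.T))
    clusters = ClusterAssignment(dict(zip(barcodes, labels)))
    marker_rows = [
        {"gene": genes[int(g)], "population": pop.label, "fold": pop.marker_fold}
        for pop in design.populations
        for g in pop.marker_genes
    ]
    truth = TruthTable(genes, pd.DataFrame(marker_rows, columns=["gene", "population", "fold"]))
    return cm, clusters, truth


# ---------------------------------------------------------------------------
# plaque preset

#: Per-population fraction of all cells in the default plaque preset.
#: T-cell clusters sum to 0.524 and the myeloid block to 0.185, mirroring
#: the very unequal composition of an advanced carotid plaque; the
#: remaining mass covers the mixed cluster (0.10), B cells, smooth muscle
#: and the two endothelial clusters.
PLAQUE_PROPORTIONS = {
    "CD4T.0": 0.200,
    "CD8T.1": 0.140,
    "CD4T.3": 0.110,
    "CD8T.4": 0.074,
    "Mac.5": 0.060,
    "Mac.6": 0.050,
    "Mac.7": 0.040,
    "SMC.8": 0.060,
    "EC.9": 0.055,
    "EC.10": 0.046,
    "B.11": 0.030,
    "DC.12": 0.020,
    "Mast.13": 0.015,
}
PLAQUE_MIXED_FRACTION = 0.10
PLAQUE_MIXED_LABEL = "Mixed.2"


def plaque_preset(
    total_cells: int = 3282,
    n_genes: int = 2000,
    markers_per_population: int = 20,
    marker_fold: float = 4.0,
    seed: int = 0,
    **overrides,
) -> SimulationDesign:
    """The default 14-population plaque design (13 pure + 1 mixed cluster).

    Marker genes are consecutive blocks at the head of the gene list, one
    block per pure population; the mixed cluster has no markers of its own.
    """
    n_pops = len(PLAQUE_PROPORTIONS)
    if markers_per_population * n_pops > n_genes:
        raise ValidationError("not enough genes for the requested marker blocks")
    listed_mass = 1.0 - PLAQUE_MIXED_FRACTION
    n_listed_target = total_cells - int(round(total_cells * PLAQUE_MIXED_FRACTION))
    pops = []
    assigned = 0
    items = list(PLAQUE_PROPORTIONS.items())
    for i, (label, prop) in enumerate(items):
        if i < len(items) - 1:
            n = int(round(prop / listed_mass * n_listed_target))
        else:
            n = n_listed_target - assigned
        assigned += n
        lo = i * markers_per_population
        pops.append(
            Population(label, n, list(range(lo, lo + markers_per_population)), marker_fold)
        )
    design = SimulationDesign(
        n_genes=n_genes,
        populations=pops,
        mixed_fraction=PLAQUE_MIXED_FRACTION,
        mixed_label=PLAQUE_MIXED_LABEL,
        seed=seed,
    )
    return replace(design, **overrides) if overrides else design


# ---------------------------------------------------------------------------
# GWAS fixture


@dataclass
class GwasFixtureDesign:
    """Design for a synthetic GWAS table over a tiled gene annotation.

    Genes are laid out in order along the chromosomes at ``gene_spacing``
    bp with bodies of ``gene_length`` bp.  Each of the first ``n_loci``
    planted genes receives one genome-wide-significant variant inside its
    body; decoy variants with null p-values are scattered at
    ``decoy_density`` per Mb.
    """

    genes: list
    chrom_lengths: dict
    gene_spacing: int = 300_000
    gene_length: int = 100_000
    planted_genes: list = field(default_factory=list)
    n_loci: int | None = None
    decoy_density: float = 0.0
    sig_pval_range: tuple = (1e-12, 1e-9)
    null_pval_range: tuple = (1e-4, 1.0)
    maf_range: tuple = (0.05, 0.5)
    seed: int = 0

    def validate(self) -> None:
        if self.gene_length <= 0 or self.gene_spacing < self.gene_length:
            raise ValidationError("need 0 < gene_length ≤ gene_spacing")
        if max(self.sig_pval_range) >= GENOME_WIDE_SIG:
            raise ValidationError(
                f"sig_pval_range must lie entirely below {GENOME_WIDE_SIG}"
            )
        unknown = set(self.planted_genes) - set(self.genes)
        if unknown:
            raise ValidationError(f"planted genes absent from gene list: {sorted(unknown)[:5]}")
        n_loci = len(self.planted_genes) if self.n_loci is None else self.n_loci
        if n_loci > len(self.planted_genes):
            raise ValidationError("n_loci exceeds the number of planted genes")
        capacity = sum(length // self.gene_spacing for length in self.chrom_lengths.values())
        if capacity < len(self.genes):
            raise ValidationError(
                f"chromosomes hold {capacity} gene tiles but {len(self.genes)} genes given"
            )


def _tile_annotation(fix: GwasFixtureDesign) -> GeneAnnotation:
    rows = []
    it = iter(fix.genes)
    exhausted = False
    for chrom, length in fix.chrom_lengths.items():
        for k in range(length // fix.gene_spacing):
            gene = next(it, None)
            if gene is None:
                exhausted = True
                break
            start = k * fix.gene_spacing
            rows.append(
                {
                    "gene": gene,
                    "chrom": str(chrom),
                    "start": start,
                    "end": start + fix.gene_length,
                    "strand": "+",
                    "biotype": "protein_coding",
                }
            )
        if exhausted:
            break
    return GeneAnnotation(pd.DataFrame(rows))


def simulate_gwas(fix: GwasFixtureDesign):
    """Build ``(GwasTable, GeneAnnotation, planted_gene_list)``.

    Every planted gene carries one significant variant whose 1-based
    position lies within the gene body; all decoys draw p-values from the
    null range, so with default thresholds the loci recover exactly the
    planted genes.
    """
    fix.validate()
    rng = np.random.default_rng(fix.seed)
    annot = _tile_annotation(fix)
    ann = annot.table.set_index("gene")
    n_loci = len(fix.planted_genes) if fix.n_loci is None else fix.n_loci
    planted = list(fix.planted_genes[:n_loci])

    rows = []
    lo, hi = np.log10(fix.sig_pval_range[0]), np.log10(fix.sig_pval_range[1])
    for gene in planted:
        g = ann.loc[gene]
        pos = int(rng.integers(g["start"] + 1, g["end"] + 1))  # 1-based inside body
        rows.append(
            {
                "chrom": g["chrom"],
                "pos": pos,
                "variant_id": f"rs_sig_{gene}",
                "pval": float(10 ** rng.uniform(lo, hi)),
            }
        )
    nlo, nhi = np.log10(fix.null_pval_range[0]), np.log10(fix.null_pval_range[1])
    for chrom, length in fix.chrom_lengths.items():
        n_decoys = int(round(fix.decoy_density * length / 1e6))
        if not n_decoys:
            continue
        pos = rng.integers(1, length + 1, n_decoys)
        pvals = 10 ** rng.uniform(nlo, nhi, n_decoys)
        for i in range(n_decoys):
            rows.append(
                {
                    "chrom": str(chrom),
                    "pos": int(pos[i]),
                    "variant_id": f"rs_null_{chrom}_{i}",
                    "pval": float(pvals[i]),
                }
            )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "variant_id", "pval"])
    df["maf"] = rng.uniform(fix.maf_range[0], fix.maf_range[1], len(df))
    return GwasTable(df), annot, planted


# ---------------------------------------------------------------------------
# candidate gene sets


def plant_candidate_set(
    truth: TruthTable,
    pattern_target,
    n_candidates: int,
    enrich_frac: float,
    seed: int = 0,
) -> list:
    """Draw a candidate gene set enriched for markers of target populations.

    ``ceil(enrich_frac · n_candidates)`` genes come from the target
    populations' markers and the remainder uniformly from background
    (non-marker) genes.  With ``pattern_target=None`` (requires
    ``enrich_frac=0``) the whole set is drawn uniformly from all genes —
    the exact null the per-pattern permutation test assumes.
    """
    if not (0 <= enrich_frac <= 1):
        raise ValidationError("enrich_frac must lie in [0,1]")
    rng = np.random.default_rng(seed)
    if pattern_target is None:
        if enrich_frac != 0:
            raise ValidationError("enrich_frac must be 0 when no target is given")
        pool = np.asarray(truth.genes)
        if n_candidates > len(pool):
            raise ValidationError("more candidates requested than genes available")
        return sorted(rng.choice(pool, size=n_candidates, replace=False).tolist())
    target_markers = truth.markers_of(pattern_target)
    n_target = math.ceil(enrich_frac * n_candidates)
    if n_target > len(target_markers):
        raise ValidationError(
            f"target populations have {len(target_markers)} markers, "
            f"but {n_target} enriched candidates requested"
        )
    all_markers = truth.marker_genes
    background = [g for g in truth.genes if g not in all_markers]
    n_rest = n_candidates - n_target
    if n_rest > len(background):
        raise ValidationError("not enough background genes for the candidate set")
    chosen = rng.choice(np.asarray(target_markers), size=n_target, replace=False).tolist()
    chosen += rng.choice(np.asarray(background), size=n_rest, replace=False).tolist()
    return sorted(chosen)
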