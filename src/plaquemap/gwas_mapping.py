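"""From GWAS summary statistics to loci and candidate protein-coding genes.

Loci are formed by greedy distance-based clumping: after filtering to
genome-wide-significant variants with adequate minor allele frequency
(missing MAF passes with a warning), the most significant unassigned
variant on each chromosome becomes a lead, absorbing every remaining
significant variant within ``merge_dist`` of it.  A transparent
positional mapping then collects genes of the requested biotype whose
window-extended span intersects the locus span.  This is a deliberate,
configurable simplification: no LD reference panel or eQTL/chromatin
evidence is used.

GWAS positions are 1-based; the annotation is BED (0-based half-open).
Loci are converted to 0-based half-open before any interval arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation, GwasTable

log = logging.getLogger(__name__)

GENOME_WIDE_SIG = 5e-8


@dataclass
class Locus:
    """A clumped susceptibility locus (1-based inclusive span)."""

    locus_id: str
    chrom: str
    start: int
    end: int
    lead_variant_id: str
    lead_pval: float
    n_variants: int


@dataclass
class CandidateGeneSet:
    """Genes positionally mapped to loci, deduplicated by minimal distance."""

    table: pd.DataFrame  # gene, locus_id, distance_bp

    @property
    def genes(self) -> list:
        return self.table["gene"].tolist()

    def __len__(self):
        return len(self.table)


def clump_loci(
    gwas: GwasTable,
    p_thresh: float = GENOME_WIDE_SIG,
    maf_min: float = 0.01,
    merge_dist: int = 500_000,
) -> list:
    """Greedy lead-variant clumping of significant variants into loci."""
    df = gwas.table
    missing_maf = df["maf"].isna()
    if missing_maf.any():
        log.warning(
            "clump_loci: %d variants without MAF pass the MAF filter", int(missing_maf.sum())
        )
    sig = df[(df["pval"] <= p_thresh) & (missing_maf | (df["maf"] >= maf_min))]
    if sig.empty:
        log.warning("clump_loci: no variants pass p ≤ %g and MAF ≥ %g", p_thresh, maf_min)
        return []
    loci = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        pval = grp["pval"].to_numpy()
        vid = grp["variant_id"].to_numpy()
        # deterministic lead order: by p-value, then position, then id
        order = np.lexsort((vid, pos, pval))
        assigned = np.zeros(len(grp), dtype=bool)
        for i in order:
            if assigned[i]:
                continue
            members = ~assigned & (np.abs(pos - pos[i]) <= merge_dist)
            assigned |= members
            loci.append(
                Locus(
                    locus_id="",
                    chrom=str(chrom),
                    start=int(pos[members].min()),
                    end=int(pos[members].max()),
                    lead_variant_id=str(vid[i]),
                    lead_pval=float(pval[i]),
                    n_variants=int(members.sum()),
                )
            )
    loci.sort(key=lambda l: (l.chrom, l.start))
    for i, locus in enumerate(loci, start=1):
        locus.locus_id = f"L{i:03d}"
    return loci


def map_genes(
    loci,
    annot: GeneAnnotation,
    window: int = 100_000,
    biotype: str = "protein_coding",
) -> CandidateGeneSet:
    """Positional locus→gene mapping with a symmetric window.

    A gene is mapped to a locus when its window-extended body intersects
    the locus interval (both in 0-based half-open coordinates);
    ``distance_bp`` is 0 for genes whose body overlaps the locus, else
    the bp gap.  Genes mapping to several loci keep the closest row.
    """
    if window < 0:
        raise ValueError("window must be ≥0")
    ann = annot.table
    if biotype is not None:
        ann = ann[ann["biotype"] == biotype]
    known_chroms = set(ann["chrom"])
    rows = []
    for locus in loci:
        if locus.chrom not in known_chroms:
            log.warning("map_genes: locus %s on unknown chromosome %s skipped",
                        locus.locus_id, locus.chrom)
            continue
        ls, le = locus.start - 1, locus.end  # 0-based half-open
        sub = ann[ann["chrom"] == locus.chrom]
        gs = sub["start"].to_numpy()
        ge = sub["end"].to_numpy()
        hit = (gs - window < le) & (ge + window > ls)
        for g, s, e in zip(sub.loc[hit, "gene"], gs[hit], ge[hit]):
            if s < le and e > ls:
                dist = 0
            else:
                dist = int(max(s - le, ls - e))
            rows.append({"gene": g, "locus_id": locus.locus_id, "distance_bp": dist})
    if not rows:
        return CandidateGeneSet(pd.DataFrame(columns=["gene", "locus_id", "distance_bp"]))
    df = pd.DataFrame(rows)
    df = df.sort_values(["distance_bp", "locus_id", "gene"], kind="mergesort")
    df = df.drop_duplicates("gene", keep="first")
    df = df.sort_values(["locus_id", "gene"], kind="mergesort").reset_index(drop=True)
    return CandidateGeneSet(df)


def loci_to_frame(loci) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": l.locus_id,
                "chrom": l.chrom,
                "start": l.start,
                "end": l.end,
                "lead_variant_id": l.lead_variant_id,
                "lead_pval": l.lead_pval,
                "n_variants": l.n_variants,
            }
            for l in loci
        ],
        columns=[
            "locus_id",
            "chrom",
            "start",
            "end",
            "lead_variant_id",
            "lead_pval",
            "n_variants",
        ],
    )
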