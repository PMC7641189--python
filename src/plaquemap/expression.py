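"""Normalisation, per-cluster mean profiles, and one-vs-rest DEG calling.

The working expression scale is CP10K log1p: each cell's counts are
scaled to a fixed total (default 10⁴) and transformed with log(1+x), so
zero counts stay zero and the transform is monotone within each cell.

Differential expression is the standard cluster-marker contract: for
every (gene, cluster) pair, a two-sided Wilcoxon rank-sum test of the
cluster's cells against all other cells on the normalised values, using
the tie-corrected normal approximation with continuity correction, then
a single Benjamini–Hochberg pass over the whole (gene, cluster) table.
A gene is a DEG when it is significant (FDR < α and |log₂FC| ≥ lfc_min)
in at least one cluster.  The log₂ fold change is computed on the
expm1 scale of the cluster means with a small pseudocount.

The gene universe — all genes expressed in at least
``min_cells_expressing`` cells — is recorded on the returned table; the
enrichment stage must draw its permutation null from the same universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .io_formats import ClusterAssignment, CountMatrix, ValidationError

log = logging.getLogger(__name__)

LFC_PSEUDOCOUNT = 1e-9


@dataclass
class NormalizedMatrix:
    """log1p(count / cell_total × scale) values, same ids as the counts."""

    genes: list
    barcodes: list
    values: sp.csr_matrix
    scale: float

    def dense(self) -> np.ndarray:
        return self.values.toarray()


@dataclass
class ExpressionProfile:
    """Genes × clusters matrix of mean normalised expression."""

    table: pd.DataFrame  # index: genes, columns: cluster labels

    @property
    def clusters(self) -> list:
        return self.table.columns.tolist()


@dataclass
class DegTable:
    """Per-(gene, cluster) differential-expression results.

    ``universe`` is the ordered list of genes that passed the expression
    filter (and hence were tested); the DEG set is every gene significant
    in at least one cluster.
    """

    table: pd.DataFrame  # gene, cluster, log2_fold_change, pval, fdr, is_significant
    universe: list
    alpha: float
    lfc_min: float

    @property
    def deg_genes(self) -> list:
        sig = set(self.table.loc[self.table["is_significant"], "gene"])
        return [g for g in self.universe if g in sig]

    def markers_for(self, cluster, positive_only: bool = True) -> pd.DataFrame:
        sub = self.table[(self.table["cluster"] == cluster) & self.table["is_significant"]]
        if positive_only:
            sub = sub[sub["log2_fold_change"] > 0]
        return sub.sort_values(
            ["fdr", "log2_fold_change"], ascending=[True, False], kind="mergesort"
        )


def normalize(counts: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """CP-scale log1p normalisation; fatal on cells with zero total count."""
    totals = np.asarray(counts.counts.sum(axis=0)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = [counts.barcodes[i] for i in zero[:10]]
        raise ValidationError(f"{zero.size} cells with zero total count, e.g. {bad}")
    x = counts.counts.astype(np.float64)
    x = x @ sp.diags(scale / totals)
    x = x.log1p()
    return NormalizedMatrix(list(counts.genes), list(counts.barcodes), sp.csr_matrix(x), scale)


def _cluster_indices(norm: NormalizedMatrix, clusters: ClusterAssignment):
    """Column indices per cluster label, restricted to assigned barcodes."""
    pos = {b: i for i, b in enumerate(norm.barcodes)}
    out = {}
    for label in clusters.labels:
        idx = [pos[b] for b, l in clusters.mapping.items() if l == label and b in pos]
        if not idx:
            log.warning("cluster %s has no cells in the matrix; dropped", label)
            continue
        out[label] = np.asarray(sorted(idx), dtype=int)
    return out


def mean_profiles(norm: NormalizedMatrix, clusters: ClusterAssignment) -> ExpressionProfile:
    """Arithmetic mean of normalised expression per cluster."""
    by_label = _cluster_indices(norm, clusters)
    if not by_label:
        raise ValidationError("no cluster has cells in the matrix")
    cols = {
        label: np.asarray(norm.values[:, idx].mean(axis=1)).ravel()
        for label, idx in by_label.items()
    }
    return ExpressionProfile(pd.DataFrame(cols, index=norm.genes))


def _tie_terms(x: np.ndarray) -> np.ndarray:
    """Σ(t³ − t) over tied groups, per row."""
    out = np.empty(x.shape[0])
    for i in range(x.shape[0]):
        _, counts = np.unique(x[i], return_counts=True)
        t = counts[counts > 1].astype(np.float64)
        out[i] = np.sum(t**3 - t)
    return out


def rank_sum_one_vs_rest(
    x: np.ndarray,
    in_mask: np.ndarray,
    ranks: np.ndarray | None = None,
    tie: np.ndarray | None = None,
) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values, one row of ``x`` at a time.

    Normal approximation with tie correction and continuity correction;
    rows where every value is tied get p = 1.  ``x`` is genes × cells and
    ``in_mask`` flags the in-cluster cells.  ``ranks`` and ``tie`` may be
    passed precomputed (they depend on ``x`` only) when testing several
    clusters against the same matrix.
    """
    n = x.shape[1]
    n1 = int(in_mask.sum())
    n2 = n - n1
    if ranks is None:
        ranks = rankdata(x, axis=1)
    r1 = ranks[:, in_mask].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    if tie is None:
        tie = _tie_terms(x)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    var = np.maximum(var, 0.0)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(u1 - mu) - 0.5) / sd
    z = np.clip(z, 0.0, None)
    p = np.where(sd > 0, 2.0 * norm.sf(z), 1.0)
    return np.minimum(p, 1.0)


def find_degs(
    norm: NormalizedMatrix,
    clusters: ClusterAssignment,
    alpha: float = 0.05,
    lfc_min: float = 0.25,
    min_cells_expressing: int = 3,
) -> DegTable:
    """One-vs-rest Wilcoxon DEG calling over all (gene, cluster) pairs."""
    by_label = _cluster_indices(norm, clusters)
    if len(by_label) < 2:
        raise ValidationError("need ≥2 clusters with cells")
    cell_idx = np.asarray(sorted(set(np.concatenate(list(by_label.values())))), dtype=int)
    x = norm.values[:, cell_idx].toarray()
    col_of = {c: j for j, c in enumerate(cell_idx)}

    expressed = (x > 0).sum(axis=1) >= min_cells_expressing
    n_excluded = int((~expressed).sum())
    if n_excluded:
        log.info(
            "find_degs: excluded %d genes expressed in < %d cells",
            n_excluded,
            min_cells_expressing,
        )
    universe = [g for g, keep in zip(norm.genes, expressed) if keep]
    x = x[expressed]
    e = np.expm1(x)
    ranks = rankdata(x, axis=1)
    tie = _tie_terms(x)

    frames = []
    for label in sorted(by_label):
        idx = by_label[label]
        if idx.size < 3:
            log.warning("find_degs: cluster %s has <3 cells; skipped", label)
            continue
        in_mask = np.zeros(x.shape[1], dtype=bool)
        in_mask[[col_of[i] for i in idx]] = True
        pvals = rank_sum_one_vs_rest(x, in_mask, ranks=ranks, tie=tie)
        mean_in = e[:, in_mask].mean(axis=1)
        mean_out = e[:, ~in_mask].mean(axis=1)
        lfc = np.log2((mean_in + LFC_PSEUDOCOUNT) / (mean_out + LFC_PSEUDOCOUNT))
        frames.append(
            pd.DataFrame(
                {
                    "gene": universe,
                    "cluster": label,
                    "log2_fold_change": lfc,
                    "pval": pvals,
                }
            )
        )
    if not frames:
        raise ValidationError("no cluster had ≥3 cells")
    table = pd.concat(frames, ignore_index=True)
    _, fdr, _, _ = multipletests(table["pval"], method="fdr_bh")
    table["fdr"] = fdr
    table["is_significant"] = (table["fdr"] < alpha) & (
        table["log2_fold_change"].abs() >= lfc_min
    )
    return DegTable(table, universe, alpha, lfc_min)
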