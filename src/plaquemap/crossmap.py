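"""Cross-dataset cluster correspondence via marker-set overlap.

To match cell populations between two independently clustered datasets
(for instance human plaque macrophages against mouse lesion
macrophages), each query cluster's top marker genes are tested against
each reference cluster's top markers with an upper-tail hypergeometric
test over the shared gene universe, and BH correction runs jointly over
all query × reference pairs.  Gene symbols are harmonised beforehand —
by exact match, by case-folding (the usual human/mouse symbol bridge:
Trem2 ↔ TREM2), or through an explicit orthology map file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .expression import DegTable
from .io_formats import ValidationError

log = logging.getLogger(__name__)


@dataclass
class MarkerTable:
    """Per-cluster ordered marker lists (ascending FDR, then descending |log₂FC|)."""

    markers: dict  # cluster -> ordered, deduplicated gene list

    @property
    def clusters(self) -> list:
        return list(self.markers)


@dataclass
class OverlapCall:
    query_cluster: str
    ref_cluster: str
    n_shared_universe: int
    n_query_markers: int
    n_ref_markers: int
    n_overlap: int
    p_hyper: float
    q_bh: float = float("nan")
    significant: bool = False

    def to_dict(self) -> dict:
        return {
            "query_cluster": self.query_cluster,
            "ref_cluster": self.ref_cluster,
            "n_shared_universe": self.n_shared_universe,
            "n_query_markers": self.n_query_markers,
            "n_ref_markers": self.n_ref_markers,
            "n_overlap": self.n_overlap,
            "p_hyper": self.p_hyper,
            "q_bh": self.q_bh,
            "significant": self.significant,
        }


def markers_from_degs(degs: DegTable, top_n: int | None = None) -> MarkerTable:
    """Build per-cluster marker lists from positively significant DEG rows."""
    markers = {}
    for cluster in sorted(degs.table["cluster"].unique()):
        ordered = degs.markers_for(cluster)["gene"].tolist()
        seen = dict.fromkeys(ordered)  # dedup preserving order
        genes = list(seen)
        markers[cluster] = genes[:top_n] if top_n is not None else genes
    return MarkerTable(markers)


def harmonize_genes(
    query_genes,
    ref_genes,
    mode: str = "casefold",
    map_path=None,
    min_universe: int = 10,
):
    """Shared gene universe plus per-dataset renaming maps.

    ``exact`` intersects symbols as-is; ``casefold`` upper-cases both
    sides first; ``map_file`` applies a two-column (query, reference)
    orthology TSV, dropping many-to-many rows with a logged count.
    Returns ``(universe, query_map, ref_map)`` where each map renames an
    original symbol to its shared-universe name.  A universe below
    ``min_universe`` genes is fatal (set it to 0 for toy inputs); below
    100 genes a warning is logged.
    """
    query_genes = list(dict.fromkeys(query_genes))
    ref_genes = list(dict.fromkeys(ref_genes))
    if not query_genes or not ref_genes:
        raise ValidationError("gene lists must be nonempty")
    if mode == "exact":
        qmap = {g: g for g in query_genes}
        rmap = {g: g for g in ref_genes}
    elif mode == "casefold":
        qmap = {g: g.upper() for g in query_genes}
        rmap = {g: g.upper() for g in ref_genes}
    elif mode == "map_file":
        if map_path is None:
            raise ValueError("map_file mode needs map_path")
        df = pd.read_csv(map_path, sep="\t", header=None, dtype=str).iloc[:, :2]
        df.columns = ["query", "ref"]
        multi = df["query"].duplicated(keep=False) | df["ref"].duplicated(keep=False)
        if multi.any():
            log.warning("harmonize_genes: dropped %d many-to-many orthology rows",
                        int(multi.sum()))
        df = df[~multi]
        to_ref = dict(zip(df["query"], df["ref"]))
        qmap = {g: to_ref[g] for g in query_genes if g in to_ref}
        rmap = {g: g for g in ref_genes}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    universe = sorted(set(qmap.values()) & set(rmap.values()))
    if len(universe) < min_universe:
        raise ValidationError(f"shared gene universe has only {len(universe)} genes")
    if len(universe) < 100:
        log.warning("harmonize_genes: shared universe is small (%d genes)", len(universe))
    return universe, qmap, rmap


def rename_markers(table: MarkerTable, name_map: dict) -> MarkerTable:
    """Apply a harmonisation renaming map, keeping order and dropping unmapped."""
    out = {}
    for cluster, genes in table.markers.items():
        renamed = [name_map[g] for g in genes if g in name_map]
        out[cluster] = list(dict.fromkeys(renamed))
    return MarkerTable(out)


def crossmap_clusters(
    query: MarkerTable,
    ref: MarkerTable,
    universe,
    top_n: int = 100,
    alpha: float = 0.05,
) -> list:
    """All-pairs marker overlap calls with joint BH correction.

    Marker lists are restricted to the shared universe *before* capping
    at ``top_n``; a cluster left without markers yields calls with
    overlap 0 and p = 1 plus a warning.
    """
    uset = set(universe)
    q_lists = {c: [g for g in gs if g in uset][:top_n] for c, gs in query.markers.items()}
    r_lists = {c: [g for g in gs if g in uset][:top_n] for c, gs in ref.markers.items()}
    for side, lists in (("query", q_lists), ("reference", r_lists)):
        for c, gs in lists.items():
            if not gs:
                log.warning("crossmap_clusters: %s cluster %s has 0 markers in universe",
                            side, c)
    calls = []
    n_u = len(uset)
    for qc, qg in q_lists.items():
        qset = set(qg)
        for rc, rg in r_lists.items():
            k = len(qset & set(rg))
            if qg and rg:
                p = float(hypergeom.sf(k - 1, n_u, len(rg), len(qg)))
            else:
                p = 1.0
            calls.append(
                OverlapCall(
                    query_cluster=qc,
                    ref_cluster=rc,
                    n_shared_universe=n_u,
                    n_query_markers=len(qg),
                    n_ref_markers=len(rg),
                    n_overlap=k,
                    p_hyper=min(p, 1.0),
                )
            )
    if calls:
        _, q_bh, _, _ = multipletests([c.p_hyper for c in calls], method="fdr_bh")
        for call, q in zip(calls, q_bh):
            call.q_bh = float(q)
            call.significant = bool(q < alpha)
    return calls


def top_overlaps(calls, n_top: int = 5) -> pd.DataFrame:
    """Per query cluster, the top-N reference clusters by overlap count."""
    df = pd.DataFrame([c.to_dict() for c in calls])
    if df.empty:
        return df
    df = df.sort_values(
        ["query_cluster", "n_overlap", "p_hyper", "ref_cluster"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return df.groupby("query_cluster", sort=True).head(n_top).reset_index(drop=True)
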