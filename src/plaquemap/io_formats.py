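"""Readers and writers for every on-disk artifact of the pipeline.

Counts travel either as a Matrix Market triplet (``matrix.mtx`` +
``genes.tsv`` + ``barcodes.tsv``, the 10x-style layout) or as a dense TSV
with gene rows and cell columns.  Cluster labels are a two-column TSV,
GWAS summary statistics a tab-delimited table with user-named columns,
and gene annotations BED6+1 (seventh column = biotype, BED convention:
0-based half-open).  GWAS positions are 1-based, as is standard for
summary statistics; the conversion between the two conventions happens
only inside :mod:`plaquemap.gwas_mapping`.

Readers validate strictly and never coerce silently: every dropped or
rejected record increments a counter that is logged and kept on the
returned object.  Each writer emits canonical TSV plus a JSON metadata
sidecar so that reader∘writer round trips are lossless.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

log = logging.getLogger(__name__)

GWAS_COLUMNS = ["chrom", "pos", "variant_id", "pval", "maf"]
ANNOT_COLUMNS = ["gene", "chrom", "start", "end", "strand", "biotype"]


class FormatError(ValueError):
    """Malformed file: bad header, dimension mismatch, unparseable field."""


class ValidationError(ValueError):
    """Well-formed input whose content violates a domain invariant."""


# ---------------------------------------------------------------------------
# count matrices


@dataclass
class CountMatrix:
    """Gene × cell matrix of non-negative integer counts.

    Gene symbols and barcodes are unique and ordered; the matrix is held
    sparse (CSR, int64) with shape ``(len(genes), len(barcodes))``.
    """

    genes: list
    barcodes: list
    counts: sp.csr_matrix

    def __post_init__(self):
        self.genes = [str(g) for g in self.genes]
        self.barcodes = [str(b) for b in self.barcodes]
        if any(not g for g in self.genes):
            raise ValidationError("empty gene symbol")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene symbols")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValidationError("duplicate barcodes")
        m = sp.csr_matrix(self.counts)
        if m.shape != (len(self.genes), len(self.barcodes)):
            raise FormatError(
                f"matrix shape {m.shape} inconsistent with "
                f"{len(self.genes)} genes × {len(self.barcodes)} barcodes"
            )
        if m.nnz:
            if m.data.min() < 0:
                raise ValidationError("negative count entry")
            if not np.all(np.equal(np.mod(m.data, 1), 0)):
                raise ValidationError("non-integer count entry")
        self.counts = m.astype(np.int64)
        self.counts.sum_duplicates()

    @property
    def shape(self):
        return self.counts.shape

    def total(self) -> int:
        return int(self.counts.sum())

    def dense(self) -> np.ndarray:
        return self.counts.toarray()


def _read_id_column(path) -> list:
    ids = pd.read_csv(path, sep="\t", header=None, dtype=str)[0].tolist()
    return ids


def read_counts(
    path_matrix=None,
    path_genes=None,
    path_barcodes=None,
    path_dense_tsv=None,
) -> CountMatrix:
    """Read a count matrix from an MTX triplet or a dense TSV.

    Exactly one of the two input styles must be given.  Gene and barcode
    order is preserved from the files.
    """
    if path_dense_tsv is not None:
        if path_matrix is not None:
            raise ValueError("give either an MTX triplet or a dense TSV, not both")
        df = pd.read_csv(path_dense_tsv, sep="\t", index_col=0)
        mat = df.to_numpy()
        if mat.size and not np.issubdtype(mat.dtype, np.number):
            raise FormatError(f"non-numeric entries in {path_dense_tsv}")
        return CountMatrix(df.index.tolist(), df.columns.tolist(), sp.csr_matrix(mat))
    if path_matrix is None or path_genes is None or path_barcodes is None:
        raise ValueError("MTX input needs path_matrix, path_genes and path_barcodes")
    try:
        mat = sp.csr_matrix(mmread(path_matrix))
    except ValueError as exc:
        raise FormatError(f"invalid Matrix Market file {path_matrix}: {exc}") from exc
    genes = _read_id_column(path_genes)
    barcodes = _read_id_column(path_barcodes)
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"{path_matrix} declares {mat.shape} but id files list "
            f"{len(genes)} genes and {len(barcodes)} barcodes"
        )
    return CountMatrix(genes, barcodes, mat)


def write_counts(cm: CountMatrix, path_matrix, path_genes, path_barcodes) -> None:
    mmwrite(str(path_matrix), cm.counts.tocoo(), field="integer")
    Path(path_genes).write_text("".join(g + "\n" for g in cm.genes))
    Path(path_barcodes).write_text("".join(b + "\n" for b in cm.barcodes))


# ---------------------------------------------------------------------------
# cluster assignments


@dataclass
class ClusterAssignment:
    """Barcode → cluster-label mapping with the distinct labels ordered."""

    mapping: dict
    labels: list = field(default=None)
    n_dropped: int = 0

    def __post_init__(self):
        if self.labels is None:
            self.labels = sorted(set(self.mapping.values()))
        if len(self.labels) < 2:
            raise ValidationError("need ≥2 clusters")
        if set(self.mapping.values()) - set(self.labels):
            raise ValidationError("mapping uses labels missing from the label list")

    @property
    def barcodes(self) -> list:
        return list(self.mapping)

    def size_of(self, label) -> int:
        return sum(1 for v in self.mapping.values() if v == label)


def read_clusters(path_tsv, counts: CountMatrix, header: bool = False) -> ClusterAssignment:
    """Read a two-column (barcode, label) TSV restricted to ``counts`` barcodes.

    Barcodes absent from ``counts`` are dropped with a logged count;
    duplicate barcode rows and an empty intersection are fatal.
    """
    df = pd.read_csv(path_tsv, sep="\t", header=0 if header else None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path_tsv}: expected 2 columns (barcode, label)")
    df = df.iloc[:, :2]
    df.columns = ["barcode", "label"]
    if df["barcode"].duplicated().any():
        dups = df.loc[df["barcode"].duplicated(), "barcode"].head(5).tolist()
        raise ValidationError(f"duplicate barcode rows in {path_tsv}: {dups}")
    known = set(counts.barcodes)
    keep = df["barcode"].isin(known)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("read_clusters: dropped %d barcodes absent from counts", n_dropped)
    df = df[keep]
    if df.empty:
        raise ValidationError(f"{path_tsv}: no barcodes overlap the count matrix")
    mapping = dict(zip(df["barcode"], df["label"]))
    return ClusterAssignment(mapping, n_dropped=n_dropped)


def write_clusters(clusters: ClusterAssignment, path_tsv) -> None:
    df = pd.DataFrame(
        {"barcode": list(clusters.mapping), "label": list(clusters.mapping.values())}
    )
    df.to_csv(path_tsv, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GWAS summary statistics


@dataclass
class GwasTable:
    """Summary statistics rows (chrom, pos, variant_id, pval, maf), sorted.

    Positions are 1-based; p-values lie in (0, 1]; MAF in [0, 0.5] or NaN
    (missing MAF passes downstream MAF filters with a logged warning).
    """

    table: pd.DataFrame
    n_rejected: int = 0

    def __post_init__(self):
        df = self.table[GWAS_COLUMNS].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        df["variant_id"] = df["variant_id"].astype(str)
        df["pval"] = df["pval"].astype(float)
        df["maf"] = df["maf"].astype(float)
        if (df["pos"] < 1).any():
            raise ValidationError("GWAS position < 1")
        bad_p = ~((df["pval"] > 0) & (df["pval"] <= 1))
        bad_maf = df["maf"].notna() & ~((df["maf"] >= 0) & (df["maf"] <= 0.5))
        bad = bad_p | bad_maf
        if bad.any():
            raise ValidationError(f"{int(bad.sum())} invalid pval/maf rows")
        self.table = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    def __len__(self):
        return len(self.table)


def read_gwas(path_tsv, column_map: dict, sep: str = "\t") -> GwasTable:
    """Read GWAS summary statistics with user-named columns.

    ``column_map`` binds the logical names {chrom,pos,id,pval,maf} to header
    names; ``maf`` may be omitted.  Rows with pval outside (0,1] or MAF
    outside [0,0.5] are rejected with a logged count.
    """
    required = ["chrom", "pos", "id", "pval"]
    missing_keys = [k for k in required if k not in column_map]
    if missing_keys:
        raise FormatError(f"column_map lacks mandatory keys: {missing_keys}")
    df = pd.read_csv(path_tsv, sep=sep)
    missing_cols = [c for k, c in column_map.items() if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path_tsv}: missing mandatory columns {missing_cols}")
    out = pd.DataFrame(
        {
            "chrom": df[column_map["chrom"]].astype(str),
            "pos": df[column_map["pos"]].astype(np.int64),
            "variant_id": df[column_map["id"]].astype(str),
            "pval": pd.to_numeric(df[column_map["pval"]], errors="coerce"),
        }
    )
    if "maf" in column_map:
        out["maf"] = pd.to_numeric(df[column_map["maf"]], errors="coerce")
        n_missing_maf = int(out["maf"].isna().sum())
        if n_missing_maf:
            log.warning("read_gwas: %d rows without MAF (treated as passing)", n_missing_maf)
    else:
        out["maf"] = np.nan
        log.warning("read_gwas: no MAF column bound; all rows treated as passing MAF filters")
    ok = (out["pval"] > 0) & (out["pval"] <= 1) & (out["pos"] >= 1)
    ok &= out["maf"].isna() | ((out["maf"] >= 0) & (out["maf"] <= 0.5))
    n_rejected = int((~ok).sum())
    if n_rejected:
        log.warning("read_gwas: rejected %d invalid rows", n_rejected)
    return GwasTable(out[ok].reset_index(drop=True), n_rejected=n_rejected)


def write_gwas(gwas: GwasTable, path_tsv) -> None:
    gwas.table.to_csv(path_tsv, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene annotation


@dataclass
class GeneAnnotation:
    """BED-convention gene spans (0-based half-open) with a biotype."""

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table[ANNOT_COLUMNS].copy()
        df["gene"] = df["gene"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            raise ValidationError("gene with start >= end")
        if (df["start"] < 0).any():
            raise ValidationError("negative gene start")
        if df["gene"].duplicated().any():
            raise ValidationError("duplicate gene symbols in annotation")
        if not df["strand"].isin(["+", "-", "."]).all():
            raise ValidationError("strand must be one of +, -, .")
        self.table = df.reset_index(drop=True)

    def __len__(self):
        return len(self.table)


def read_annotation(path_bed) -> GeneAnnotation:
    """Read a BED6+1 annotation (chrom start end gene score strand biotype)."""
    df = pd.read_csv(path_bed, sep="\t", header=None, dtype=str)
    if df.shape[1] < 7:
        raise FormatError(f"{path_bed}: expected BED6+1 (7 columns), got {df.shape[1]}")
    out = pd.DataFrame(
        {
            "gene": df[3],
            "chrom": df[0],
            "start": df[1].astype(np.int64),
            "end": df[2].astype(np.int64),
            "strand": df[5],
            "biotype": df[6],
        }
    )
    return GeneAnnotation(out)


def write_annotation(annot: GeneAnnotation, path_bed) -> None:
    df = annot.table
    bed = pd.DataFrame(
        {
            0: df["chrom"],
            1: df["start"],
            2: df["end"],
            3: df["gene"],
            4: 0,
            5: df["strand"],
            6: df["biotype"],
        }
    )
    bed.to_csv(path_bed, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# generic result tables


def write_table(df: pd.DataFrame, path_tsv, meta: dict | None = None) -> None:
    """Write a result table as TSV with header plus a JSON metadata sidecar."""
    df.to_csv(path_tsv, sep="\t", index=False)
    if meta is not None:
        sidecar = Path(str(path_tsv) + ".meta.json")
        sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_table(path_tsv) -> pd.DataFrame:
    return pd.read_csv(path_tsv, sep="\t")
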