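"""One-config orchestration: simulate → degs → patterns → map-loci → enrich.

Every stage draws its seed deterministically from the master seed and
its own name (SHA-256, reduced to 31 bits), so adding or toggling a
stage never perturbs another stage's randomness.  Each stage writes its
TSV outputs before the next starts; a failure leaves earlier outputs
intact and surfaces the failing stage.  The consolidated report JSON is
fully deterministic under a fixed master seed; per-stage wall-clock goes
to a separate ``timings.json`` that is volatile by nature and excluded
from the determinism contract.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import global_overlap_test, pattern_accumulation_test, summarize_enrichment
from .expression import find_degs, mean_profiles, normalize
from .gwas_mapping import clump_loci, loci_to_frame, map_genes
from .io_formats import ValidationError, write_annotation, write_clusters, write_counts, write_gwas, write_table
from .patterns import annotate_patterns, build_patterns, zscore_profiles
from .synthetic_data import (
    GwasFixtureDesign,
    plant_candidate_set,
    plaque_preset,
    simulate_counts,
    simulate_gwas,
)

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "master_seed": 42,
    "stages": ["simulate", "degs", "patterns", "map_loci", "enrich"],
    "simulate": {
        "total_cells": 3282,
        "n_genes": 2000,
        "markers_per_population": 20,
        "marker_fold": 4.0,
        "dispersion": 0.5,
        "baseline_mean_logmu": -1.2,
        "baseline_mean_logsigma": 0.8,
        "libsize_logsigma": 0.35,
    },
    "degs": {"alpha": 0.05, "lfc_min": 0.25, "min_cells": 3},
    "patterns": {"k": 15, "restarts": 50, "z_annot": 1.0},
    "gwas": {
        "n_candidates": 30,
        "enrich_frac": 0.5,
        "target_population": "EC.9",
        "gene_spacing": 300000,
        "gene_length": 100000,
        "decoy_density": 5.0,
        "n_chromosomes": 10,
        "chrom_length": 61000000,
        "p_thresh": 5e-8,
        "maf_min": 0.01,
        "merge_dist": 500000,
        "window": 100000,
        "biotype": "protein_coding",
    },
    "enrich": {"n_perm": 10000},
}


class StageError(RuntimeError):
    """A pipeline stage failed; earlier stage outputs remain on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic 31-bit per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path=None) -> dict:
    """Merge a YAML config file over the built-in defaults."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    try:
        user = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark else ""
        raise ValidationError(f"cannot parse config {path}{line}: {exc}") from exc
    if not isinstance(user, dict):
        raise ValidationError(f"config {path} must be a mapping")
    return _merge(DEFAULT_CONFIG, user)


def validate_config(cfg: dict) -> list:
    """Return a list of violation strings (empty when the config is valid)."""
    v = []

    def check(cond, msg):
        if not cond:
            v.append(msg)

    sim = cfg.get("simulate", {})
    check(sim.get("total_cells", 1) >= 28, "simulate.total_cells must be ≥28 (2 cells per population)")
    check(sim.get("n_genes", 1) >= 1, "simulate.n_genes must be ≥1")
    check(sim.get("marker_fold", 2) > 1, f"simulate.marker_fold must be >1, got {sim.get('marker_fold')}")
    check(sim.get("dispersion", 1) > 0, f"simulate.dispersion must be >0, got {sim.get('dispersion')}")
    deg = cfg.get("degs", {})
    check(0 < deg.get("alpha", 0.05) < 1, f"degs.alpha must lie in (0,1), got {deg.get('alpha')}")
    check(deg.get("lfc_min", 0) >= 0, f"degs.lfc_min must be ≥0, got {deg.get('lfc_min')}")
    check(deg.get("min_cells", 0) >= 0, f"degs.min_cells must be ≥0, got {deg.get('min_cells')}")
    pat = cfg.get("patterns", {})
    check(pat.get("k", 2) >= 2, f"patterns.k must be ≥2, got {pat.get('k')}")
    check(pat.get("restarts", 1) >= 1, f"patterns.restarts must be ≥1, got {pat.get('restarts')}")
    gw = cfg.get("gwas", {})
    check(gw.get("window", 0) >= 0, f"gwas.window must be ≥0, got {gw.get('window')}")
    check(gw.get("merge_dist", 0) >= 0, f"gwas.merge_dist must be ≥0, got {gw.get('merge_dist')}")
    check(0 < gw.get("p_thresh", 5e-8) < 1, f"gwas.p_thresh must lie in (0,1), got {gw.get('p_thresh')}")
    check(0 <= gw.get("enrich_frac", 0) <= 1, f"gwas.enrich_frac must lie in [0,1], got {gw.get('enrich_frac')}")
    check(gw.get("n_candidates", 1) >= 1, f"gwas.n_candidates must be ≥1, got {gw.get('n_candidates')}")
    enr = cfg.get("enrich", {})
    check(enr.get("n_perm", 1) >= 1, f"enrich.n_perm must be ≥1, got {enr.get('n_perm')}")
    check(isinstance(cfg.get("master_seed", 0), int), "master_seed must be an integer")
    known = {"simulate", "degs", "patterns", "map_loci", "enrich"}
    for stage in cfg.get("stages", []):
        check(stage in known, f"unknown stage '{stage}'")
    return v


def run_all(cfg: dict, outdir) -> dict:
    """Execute the configured stages in dependency order; return the report."""
    violations = validate_config(cfg)
    if violations:
        raise ValidationError("invalid config: " + "; ".join(violations))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = cfg["master_seed"]
    stages = cfg["stages"]
    report = {"version": __version__, "config": cfg, "stages": {}}
    timings = {}
    state = {}

    def run_stage(name, fn):
        if name not in stages:
            return
        t0 = time.perf_counter()
        try:
            report["stages"][name] = fn(stage_seed(master, name))
        except Exception as exc:
            raise StageError(name, exc) from exc
        finally:
            timings[name] = round(time.perf_counter() - t0, 3)

    def _simulate(seed):
        sim = cfg["simulate"]
        design = plaque_preset(
            total_cells=sim["total_cells"],
            n_genes=sim["n_genes"],
            markers_per_population=sim["markers_per_population"],
            marker_fold=sim["marker_fold"],
            seed=seed,
            dispersion=sim["dispersion"],
            baseline_mean_logmu=sim["baseline_mean_logmu"],
            baseline_mean_logsigma=sim["baseline_mean_logsigma"],
            libsize_logsigma=sim["libsize_logsigma"],
        )
        counts, clusters, truth = simulate_counts(design)
        write_counts(counts, outdir / "counts.mtx", outdir / "genes.tsv", outdir / "barcodes.tsv")
        write_clusters(clusters, outdir / "clusters.tsv")
        write_table(truth.markers, outdir / "truth_markers.tsv")
        state.update(counts=counts, clusters=clusters, truth=truth)
        return {
            "n_cells": len(counts.barcodes),
            "n_genes": len(counts.genes),
            "n_clusters": len(clusters.labels),
            "cluster_sizes": {l: clusters.size_of(l) for l in clusters.labels},
        }

    def _degs(seed):
        deg_cfg = cfg["degs"]
        norm = normalize(state["counts"])
        degs = find_degs(
            norm,
            state["clusters"],
            alpha=deg_cfg["alpha"],
            lfc_min=deg_cfg["lfc_min"],
            min_cells_expressing=deg_cfg["min_cells"],
        )
        write_table(degs.table, outdir / "degs.tsv", meta={"universe_size": len(degs.universe)})
        state.update(norm=norm, degs=degs)
        return {"n_tested_genes": len(degs.universe), "n_deg_genes": len(degs.deg_genes)}

    def _patterns(seed):
        pat_cfg = cfg["patterns"]
        profile = mean_profiles(state["norm"], state["clusters"])
        z = zscore_profiles(profile, state["degs"].deg_genes)
        ps = build_patterns(z, K=pat_cfg["k"], n_restarts=pat_cfg["restarts"], seed=seed)
        ps = annotate_patterns(ps, z_annot=pat_cfg["z_annot"])
        membership = pd.DataFrame(
            {"gene": ps.assignments.index, "pattern": ps.assignments.values}
        )
        write_table(membership, outdir / "patterns.tsv")
        cent = ps.centroids.reset_index(names="pattern")
        write_table(cent, outdir / "pattern_centroids.tsv")
        state["patterns"] = ps
        return {
            "k": ps.K,
            "pattern_sizes": {int(k): int(n) for k, n in ps.sizes().items()},
            "annotations": {int(k): v for k, v in ps.annotations.items()},
        }

    def _map_loci(seed):
        gw = cfg["gwas"]
        candidates = plant_candidate_set(
            state["truth"],
            gw["target_population"] if gw["enrich_frac"] > 0 else None,
            gw["n_candidates"],
            gw["enrich_frac"],
            seed=seed,
        )
        fix = GwasFixtureDesign(
            genes=state["truth"].genes,
            chrom_lengths={f"chr{i + 1}": gw["chrom_length"] for i in range(gw["n_chromosomes"])},
            gene_spacing=gw["gene_spacing"],
            gene_length=gw["gene_length"],
            planted_genes=candidates,
            decoy_density=gw["decoy_density"],
            seed=seed,
        )
        gwas, annot, planted = simulate_gwas(fix)
        write_gwas(gwas, outdir / "gwas.tsv")
        write_annotation(annot, outdir / "annotation.bed")
        loci = clump_loci(gwas, p_thresh=gw["p_thresh"], maf_min=gw["maf_min"],
                          merge_dist=gw["merge_dist"])
        genes = map_genes(loci, annot, window=gw["window"], biotype=gw["biotype"])
        write_table(loci_to_frame(loci), outdir / "loci.tsv")
        write_table(genes.table, outdir / "candidate_genes.tsv")
        state.update(candidates=genes.genes, loci=loci)
        return {
            "n_variants": len(gwas),
            "n_loci": len(loci),
            "n_candidate_genes": len(genes.genes),
            "n_planted": len(planted),
        }

    def _enrich(seed):
        n_perm = cfg["enrich"]["n_perm"]
        degs = state["degs"]
        res_global = global_overlap_test(
            state["candidates"], degs.deg_genes, degs.universe, n_perm=n_perm, seed=seed
        )
        res_patterns = pattern_accumulation_test(
            state["candidates"], state["patterns"], degs.deg_genes, n_perm=n_perm, seed=seed
        )
        summary = summarize_enrichment([res_global] + res_patterns)
        write_table(summary, outdir / "enrichment.tsv")
        return {
            "global": res_global.to_dict(),
            "patterns": [r.to_dict() for r in res_patterns],
        }

    run_stage("simulate", _simulate)
    run_stage("degs", _degs)
    run_stage("patterns", _patterns)
    run_stage("map_loci", _map_loci)
    run_stage("enrich", _enrich)

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    (outdir / "timings.json").write_text(json.dumps(timings, indent=2, sort_keys=True) + "\n")
    return report
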