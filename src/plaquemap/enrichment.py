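"""Permutation enrichment of candidate genes in the DEG set and its patterns.

The global test asks whether GWAS candidate genes overlap the DEG set
more than random gene sets of the same size drawn uniformly (without
replacement) from the expression universe.  The per-pattern test then
asks whether the overlapping candidates accumulate in particular
expression patterns, with the null drawn from the DEG set itself.  Both
report the empirical permutation p-value with pseudocount,
``(b+1)/(n+1)`` where b permutations reach the observed overlap — so an
estimated p of exactly 0 is impossible — alongside the exact
hypergeometric upper tail, the analytic twin of uniform resampling.
Tests are one-sided for enrichment; depletion shows up only as
``fold_enrichment < 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import ValidationError
from .patterns import PatternSet

log = logging.getLogger(__name__)

_BATCH_ELEMENTS = 20_000_000  # cap on random-key matrix size per batch


@dataclass
class EnrichmentResult:
    scope: str  # "global" or "pattern <k>"
    n_universe: int
    n_candidates_in_universe: int
    n_observed_overlap: int
    expected_overlap: float
    fold_enrichment: float
    p_perm: float
    p_hyper: float
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "n_universe": self.n_universe,
            "n_candidates_in_universe": self.n_candidates_in_universe,
            "n_observed_overlap": self.n_observed_overlap,
            "expected_overlap": self.expected_overlap,
            "fold_enrichment": self.fold_enrichment,
            "p_perm": self.p_perm,
            "p_hyper": self.p_hyper,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def _draw_index_batches(rng, universe_size: int, draw_size: int, n_perm: int):
    """Yield (batch × draw_size) index matrices of uniform draws w/o replacement."""
    batch = max(1, _BATCH_ELEMENTS // max(universe_size, 1))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        keys = rng.random((b, universe_size))
        yield np.argpartition(keys, draw_size - 1, axis=1)[:, :draw_size]
        done += b


def _fold(observed: float, expected: float) -> float:
    if expected > 0:
        return observed / expected
    return float("nan")


def global_overlap_test(
    candidates,
    deg_set,
    universe,
    n_perm: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Overlap of the candidate set with the DEG set against a uniform null.

    The null redraws ``|candidates ∩ universe|`` genes uniformly without
    replacement from the universe; the exact hypergeometric upper tail is
    co-reported.  Candidates outside the universe are dropped with a
    logged count; an empty intersection is fatal.
    """
    universe = list(dict.fromkeys(universe))
    uset = {g: i for i, g in enumerate(universe)}
    deg_set = list(dict.fromkeys(deg_set))
    outside = [g for g in deg_set if g not in uset]
    if outside:
        raise ValidationError(f"DEG set not contained in universe, e.g. {outside[:5]}")
    candidates = list(dict.fromkeys(candidates))
    cand_in = [g for g in candidates if g in uset]
    dropped = [g for g in candidates if g not in uset]
    if dropped:
        log.warning("global_overlap_test: dropped %d candidates outside the universe",
                    len(dropped))
    if not cand_in:
        raise ValidationError(
            "no candidate gene matches the universe; first unmatched symbols: "
            f"{dropped[:10]}"
        )
    deg_mask = np.zeros(len(universe), dtype=bool)
    deg_mask[[uset[g] for g in deg_set]] = True
    observed = int(sum(deg_mask[uset[g]] for g in cand_in))

    rng = np.random.default_rng(seed)
    n_at_least = 0
    total = 0.0
    for idx in _draw_index_batches(rng, len(universe), len(cand_in), n_perm):
        overlaps = deg_mask[idx].sum(axis=1)
        n_at_least += int((overlaps >= observed).sum())
        total += float(overlaps.sum())
    p_perm = (1 + n_at_least) / (n_perm + 1)
    expected = total / n_perm
    p_hyper = float(hypergeom.sf(observed - 1, len(universe), len(deg_set), len(cand_in)))
    return EnrichmentResult(
        scope="global",
        n_universe=len(universe),
        n_candidates_in_universe=len(cand_in),
        n_observed_overlap=observed,
        expected_overlap=expected,
        fold_enrichment=_fold(observed, expected),
        p_perm=p_perm,
        p_hyper=p_hyper,
        n_perm=n_perm,
        seed=seed,
    )


def pattern_accumulation_test(
    candidates,
    patterns: PatternSet,
    deg_set,
    n_perm: int = 10_000,
    seed: int = 0,
) -> list:
    """Per-pattern accumulation of candidate∩DEG genes, one shared null stream.

    Let S = candidates ∩ deg_set.  The null redraws |S| genes uniformly
    without replacement from the DEG set and counts them per pattern via
    the fixed assignment map; the same draws are reused across patterns,
    which makes the per-pattern p-values reproducible as a set and cheap.
    Returns one :class:`EnrichmentResult` per pattern, in pattern order.
    """
    deg_set = list(dict.fromkeys(deg_set))
    unassigned = [g for g in deg_set if g not in patterns.assignments.index]
    if unassigned:
        raise ValidationError(
            f"pattern assignments do not cover the DEG set, e.g. {unassigned[:5]}"
        )
    cand = set(candidates)
    s_genes = [g for g in deg_set if g in cand]
    if not s_genes:
        raise ValidationError(
            "no candidate genes overlap the DEG set; run the global test first"
        )
    K = patterns.K
    codes = patterns.assignments.loc[deg_set].to_numpy()
    obs = np.bincount(patterns.assignments.loc[s_genes].to_numpy(), minlength=K)
    pattern_sizes = np.bincount(codes, minlength=K)

    rng = np.random.default_rng(seed)
    n_at_least = np.zeros(K, dtype=np.int64)
    totals = np.zeros(K)
    s = len(s_genes)
    for idx in _draw_index_batches(rng, len(deg_set), s, n_perm):
        drawn = codes[idx]  # batch × s pattern codes
        counts = np.zeros((drawn.shape[0], K), dtype=np.int64)
        np.add.at(counts, (np.arange(drawn.shape[0])[:, None], drawn), 1)
        n_at_least += (counts >= obs[None, :]).sum(axis=0)
        totals += counts.sum(axis=0)
    results = []
    for k in range(K):
        expected = totals[k] / n_perm
        p_perm = (1 + int(n_at_least[k])) / (n_perm + 1)
        p_hyper = float(hypergeom.sf(int(obs[k]) - 1, len(deg_set), int(pattern_sizes[k]), s))
        results.append(
            EnrichmentResult(
                scope=f"pattern {k}",
                n_universe=len(deg_set),
                n_candidates_in_universe=s,
                n_observed_overlap=int(obs[k]),
                expected_overlap=float(expected),
                fold_enrichment=_fold(obs[k], expected),
                p_perm=p_perm,
                p_hyper=p_hyper,
                n_perm=n_perm,
                seed=seed,
            )
        )
    return results


def summarize_enrichment(results, fdr_method: str = "BH") -> pd.DataFrame:
    """Tabulate results with BH-adjusted q-values and q<0.05 flags.

    Raw permutation p-values are the primary output of the pipeline; the
    adjustment here is an explicitly flagged add-on.  Rows are ordered by
    (p_perm, pattern index).
    """
    if not results:
        raise ValidationError("no enrichment results to summarize")
    if fdr_method not in ("BH", "fdr_bh"):
        raise ValueError(f"unsupported fdr_method {fdr_method!r}")
    df = pd.DataFrame([r.to_dict() for r in results])
    _, q, _, _ = multipletests(df["p_perm"], method="fdr_bh")
    df["q_value"] = q
    df["significant"] = df["q_value"] < 0.05
    df["_order"] = range(len(df))
    df = df.sort_values(["p_perm", "_order"], kind="mergesort").drop(columns="_order")
    return df.reset_index(drop=True)
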