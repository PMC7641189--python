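"""Grouping of DEGs into expression patterns matched to cell populations.

Each DEG's per-cluster mean profile is z-scored across clusters (so
genes of different magnitude become comparable) and the rows are
clustered with k-means (Lloyd, k-means++ initialisation, multiple
restarts keeping the lowest within-cluster sum of squares).  Patterns
are re-indexed by descending member count (ties broken by smallest
original index) and annotated with every population whose centroid
z-score reaches ``z_annot``; a pattern whose centroid never reaches the
threshold is annotated with its argmax population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .expression import ExpressionProfile
from .io_formats import ValidationError

log = logging.getLogger(__name__)


@dataclass
class PatternSet:
    """A partition of the DEG set into K expression patterns.

    ``assignments`` maps every DEG to a pattern index in ``0..K-1``;
    ``centroids`` holds the mean member z-profile per pattern; and
    ``annotations`` the population labels each pattern represents.
    """

    K: int
    assignments: pd.Series  # index: gene, value: pattern index
    centroids: pd.DataFrame | None = None  # index: pattern, columns: clusters
    annotations: dict | None = None

    def members(self, k: int) -> list:
        return self.assignments.index[self.assignments == k].tolist()

    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().reindex(range(self.K), fill_value=0)


def zscore_profiles(profile: ExpressionProfile, deg_genes) -> pd.DataFrame:
    """Center and scale each DEG's profile to mean 0, variance 1 across clusters.

    Uses the population standard deviation; zero-variance rows become
    all-zero vectors with a warning.
    """
    missing = [g for g in deg_genes if g not in profile.table.index]
    if missing:
        raise ValidationError(f"DEGs missing from the profile: {missing[:5]}")
    sub = profile.table.loc[list(deg_genes)]
    vals = sub.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        log.warning("zscore_profiles: %d zero-variance rows set to 0", int(flat.sum()))
    z = np.where(sd > 0, (vals - mean) / np.where(sd == 0, 1.0, sd), 0.0)
    return pd.DataFrame(z, index=sub.index, columns=sub.columns)


def build_patterns(
    z_profiles: pd.DataFrame,
    K: int = 15,
    n_restarts: int = 50,
    seed: int = 0,
) -> PatternSet:
    """K-means over z-profiles; deterministic for a fixed seed.

    Keeps the restart with minimum within-cluster sum of squares and
    re-indexes patterns by descending member count (ties by smallest
    original index).  Centroids are recomputed as the mean of member
    rows.
    """
    if K < 2:
        raise ValidationError("K must be ≥2")
    if len(z_profiles) < K:
        raise ValidationError(f"{len(z_profiles)} DEGs is fewer than K={K} patterns")
    km = KMeans(
        n_clusters=K,
        init="k-means++",
        n_init=n_restarts,
        algorithm="lloyd",
        random_state=int(seed) & 0x7FFFFFFF,
    )
    raw = km.fit_predict(z_profiles.to_numpy(dtype=float))
    counts = np.bincount(raw, minlength=K)
    order = sorted(range(K), key=lambda j: (-counts[j], j))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.asarray([remap[l] for l in raw], dtype=int)
    assignments = pd.Series(labels, index=z_profiles.index, name="pattern")
    centroids = pd.DataFrame(
        [z_profiles.to_numpy()[labels == k].mean(axis=0) for k in range(K)],
        index=range(K),
        columns=z_profiles.columns,
    )
    return PatternSet(K, assignments, centroids)


def annotate_patterns(patterns: PatternSet, z_annot: float = 1.0) -> PatternSet:
    """Annotate every pattern with the populations its centroid is high in."""
    if patterns.centroids is None:
        raise ValidationError("patterns carry no centroids to annotate")
    annotations = {}
    for k, row in patterns.centroids.iterrows():
        high = row.index[row >= z_annot].tolist()
        annotations[int(k)] = high if high else [row.idxmax()]
    return replace(patterns, annotations=annotations)
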