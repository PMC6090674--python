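"""Temporal clustering of ceRNA profiles and sample-level stage discovery.

k-means (k=6 by default, mirroring the six observed temporal classes) on
per-transcript z-scored log profiles; hierarchical average-linkage clustering
of samples under 1 - Pearson distance with a two-group cut; and the fixed
day-threshold growth/senescence partition (growth = Day <= 18, senescence =
Day >= 20).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .expression import ExpressionMatrix, day_of

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    k: int
    assignment: pd.Series  # transcript -> cluster index in 1..k
    centroids: pd.DataFrame  # k x time points (z-score space)
    inertia: float
    seed: int
    n_init: int
    excluded: list[str] = field(default_factory=list)


@dataclass
class StagePartition:
    growth: list[str]
    senescence: list[str]

    def as_dict(self) -> dict[str, list[str]]:
        return {"growth": list(self.growth), "senescence": list(self.senescence)}


@dataclass
class SampleClustering:
    linkage: np.ndarray
    labels: list[str]
    groups: tuple[frozenset, frozenset]
    method: str = "average, 1 - Pearson"

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node):
            if node.is_leaf():
                return self.labels[node.id]
            return f"({walk(node.left)},{walk(node.right)}):{node.dist:.6g}"

        return walk(tree) + ";"


def cluster_cernas(
    expr: ExpressionMatrix, k: int = 6, seed: int = 0, n_init: int = 50,
    zscore: bool = True, sd_floor_frac: float = 0.5,
) -> ClusterResult:
    """Euclidean k-means over per-transcript standardized temporal profiles.

    Rows are centered and scaled across time points before clustering so
    that the grouping reflects profile shape, not magnitude. The scale is
    floored at ``sd_floor_frac`` times the median row standard deviation:
    without the floor, a near-constant profile is inflated to pure noise of
    unit norm and scatters across clusters instead of forming a
    low-variability group. Constant rows (standardization undefined) are
    excluded with a warning. Best of ``n_init`` restarts by inertia;
    deterministic given ``seed``.
    """
    if expr.scale != "log2p1":
        raise ValueError("clustering expects log2p1-scale profiles")
    vals = expr.values.to_numpy(float)
    sd = vals.std(axis=1)
    keep = sd > 0
    excluded = [t for t, ok in zip(expr.transcripts, keep) if not ok]
    if excluded:
        logger.warning("cluster_cernas: %d constant profile(s) excluded", len(excluded))
    vals = vals[keep]
    ids = [t for t, ok in zip(expr.transcripts, keep) if ok]
    if len(ids) < k:
        raise ValueError(f"need >= k={k} non-constant transcripts, have {len(ids)}")
    if zscore:
        sd_rows = vals.std(axis=1, keepdims=True)
        floor = sd_floor_frac * float(np.median(sd_rows))
        vals = (vals - vals.mean(axis=1, keepdims=True)) / np.maximum(sd_rows, floor)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(vals)
    assignment = pd.Series(labels + 1, index=pd.Index(ids, name="transcript"), name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_, index=range(1, k + 1), columns=expr.samples)
    return ClusterResult(
        k=k, assignment=assignment, centroids=centroids,
        inertia=float(km.inertia_), seed=seed, n_init=n_init, excluded=excluded,
    )


def cluster_samples(expr: ExpressionMatrix) -> SampleClustering:
    """Average-linkage hierarchical clustering of sample columns.

    Distance is 1 - Pearson correlation between sample expression profiles;
    returns the two-group cut alongside the dendrogram.
    """
    labels = expr.samples
    if len(labels) < 4:
        raise ValueError("need >= 4 samples")
    vals = expr.values.to_numpy(float).T  # samples x transcripts
    if (vals.std(axis=1) == 0).any():
        bad = [l for l, s in zip(labels, vals.std(axis=1)) if s == 0]
        raise ValueError(f"constant sample column(s): {bad}")
    corr = np.corrcoef(vals)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    cut = hierarchy.fcluster(z, t=2, criterion="maxclust")
    g1 = frozenset(l for l, c in zip(labels, cut) if c == 1)
    g2 = frozenset(l for l, c in zip(labels, cut) if c == 2)
    return SampleClustering(linkage=z, labels=labels, groups=(g1, g2))


def default_stage_partition(sample_labels) -> StagePartition:
    """Fixed-day growth/senescence split: growth Day <= 18, senescence Day >= 20."""
    growth, senescence = [], []
    for label in sample_labels:
        day = day_of(label)
        if not 4 <= day <= 30:
            logger.warning("sample %s: day %d outside the Day4-Day30 grid", label, day)
        (growth if day <= 18 else senescence).append(label)
    return StagePartition(growth=growth, senescence=senescence)
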