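"""K-means clustering of joint nascent-RNA/RNAPII fold-change patterns
and rule-based assignment of the four biological gene groups."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)

GROUP_NAMES = ("promoter_up", "promoter_down", "glpt_high", "remainder")


@dataclass
class GeneGroupLabels:
    """Cluster assignments mapped to the four biological groups."""

    groups: pd.Series  # gene_id -> group name
    clusters: pd.Series  # gene_id -> cluster index
    centroids: pd.DataFrame  # cluster x feature, original (log2FC) units
    cluster_to_group: dict[int, str]

    def counts(self) -> pd.Series:
        return self.groups.value_counts().reindex(GROUP_NAMES, fill_value=0)


def cluster_genes(
    eu_3bin: pd.DataFrame,
    chip_3bin: pd.DataFrame,
    n_clusters: int = 8,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """K-means on the six-dimensional per-gene log2 fold-change vector.

    Features are the three nascent-RNA plus three RNAPII gene-body
    aggregates; they are standardized before clustering, but the
    returned centroids are cluster means in the original log2 units.
    """
    if not eu_3bin.index.equals(chip_3bin.index):
        chip_3bin = chip_3bin.reindex(eu_3bin.index)
    feats = (
        pd.concat([eu_3bin.add_prefix("eu_"), chip_3bin.add_prefix("chip_")], axis=1)
        .dropna()
        .sort_index()  # canonical gene order: the partition is input-order invariant
    )
    if n_clusters > len(feats):
        raise ValueError(f"n_clusters={n_clusters} exceeds {len(feats)} genes")
    X = feats.to_numpy(dtype=float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    assign = km.fit_predict(Z)
    clusters = pd.Series(assign, index=feats.index, name="cluster")
    centroids = (
        feats.assign(cluster=assign).groupby("cluster").mean().sort_index()
    )
    return clusters, centroids


def assign_groups(
    clusters: pd.Series,
    centroids: pd.DataFrame,
    delta: float = 0.26,
) -> GeneGroupLabels:
    """Map cluster centroids to the four biological groups.

    Rules on the centroid pattern (three EU + three ChIP log2FC bins):
    all-positive EU and ChIP -> promoter_up; all-negative both ->
    promoter_down; EU dropping by >= delta from first to third aggregate
    while ChIP rises by >= delta -> glpt_high (steep progressive loss
    with steep occupancy gain); anything else -> remainder. Ambiguity is
    broken by rule priority up > down > glpt_high > remainder.
    """
    eu = centroids.filter(like="eu_").to_numpy()
    chip = centroids.filter(like="chip_").to_numpy()
    mapping: dict[int, str] = {}
    for i, c in enumerate(centroids.index):
        matches = []
        if (eu[i] > 0).all() and (chip[i] > 0).all():
            matches.append("promoter_up")
        if (eu[i] < 0).all() and (chip[i] < 0).all():
            matches.append("promoter_down")
        if eu[i, -1] - eu[i, 0] <= -delta and chip[i, -1] - chip[i, 0] >= delta:
            matches.append("glpt_high")
        if len(matches) > 1:
            log.warning("cluster %s matches %s; using %s", c, matches, matches[0])
        mapping[c] = matches[0] if matches else "remainder"
    groups = clusters.map(mapping).rename("group")
    return GeneGroupLabels(
        groups=groups, clusters=clusters, centroids=centroids, cluster_to_group=mapping
    )
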