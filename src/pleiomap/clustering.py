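"""Clustering of embedded phenotype coordinates (k-means or hierarchical)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .phenomap import PhenotypeMap

__all__ = ["ClusterResult", "cluster_phenotypes"]

_METHODS = ("kmeans", "hierarchical")
_LINKAGES = ("complete", "average", "single", "ward")


@dataclass(frozen=True)
class ClusterResult:
    """Cluster labels in {1..n_clusters}, renumbered by first occurrence."""

    labels: np.ndarray
    method: str
    n_clusters: int
    seed: int | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        if labels.min(initial=1) < 1 or labels.max(initial=1) > self.n_clusters:
            raise ValueError("labels must lie in {1..n_clusters}")
        object.__setattr__(self, "labels", labels)


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1, 2, ... in order of first occurrence."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for pos, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[pos] = mapping[lab]
    return out


def cluster_phenotypes(
    pmap: PhenotypeMap,
    n_clusters: int,
    method: str = "kmeans",
    seed: int = 0,
    n_restarts: int = 10,
    linkage_method: str = "complete",
) -> ClusterResult:
    """Partition the embedded coordinates into ``n_clusters`` groups.

    k-means runs ``n_restarts`` seeded restarts and keeps the best
    within-cluster sum of squares; hierarchical clustering is agglomerative
    on Euclidean distances of the coordinates (complete linkage by default)
    with the tree cut at ``n_clusters``.
    """
    coords = np.asarray(pmap.coords, dtype=float)
    k = coords.shape[0]
    if not 1 <= n_clusters <= k:
        raise ValueError(f"n_clusters must lie in [1, {k}], got {n_clusters}")
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")

    if method == "kmeans":
        km = KMeans(
            n_clusters=n_clusters, n_init=n_restarts, random_state=seed
        ).fit(coords)
        raw = km.labels_ + 1
        used_seed: int | None = seed
    else:
        if linkage_method not in _LINKAGES:
            raise ValueError(f"linkage must be one of {_LINKAGES}")
        if n_clusters == k:
            raw = np.arange(1, k + 1)
        else:
            tree = linkage(coords, method=linkage_method, metric="euclidean")
            raw = fcluster(tree, t=n_clusters, criterion="maxclust")
        used_seed = None

    return ClusterResult(
        labels=_canonical(np.asarray(raw, dtype=int)),
        method=method,
        n_clusters=n_clusters,
        seed=used_seed,
    )
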