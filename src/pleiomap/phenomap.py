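"""Phenotype map: Box-Cox distance transform and isomap embedding.

Pipeline: pleiotropy p-values -> Box-Cox transform with a user-chosen zoom
parameter ``lambda`` -> min-max normalization of the off-diagonal entries to
[0, 1] -> epsilon-neighborhood graph -> Floyd-Warshall shortest-path
(geodesic) distances -> classical MDS on the doubly-centered squared-distance
matrix.

Two conventions the transform relies on:

* min-max normalization of the transformed off-diagonal values makes the
  result a proper distance-like matrix in [0, 1] (so ``epsilon = 0.15`` is
  meaningful on an absolute scale) and cancels any positive scale factor,
  which is also why the natural-log branch at ``lambda = 0`` is equivalent to
  a base-10 log transform here;
* eigenvector signs are fixed by making the largest-magnitude loading on
  each axis positive, so repeated runs cannot flip coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .exceptions import DegenerateDistanceError, FragmentedDataError

__all__ = [
    "TransformedDistances",
    "EmbeddingConfig",
    "PhenotypeMap",
    "box_cox",
    "transform_distance_matrix",
    "epsilon_graph",
    "shortest_path_distances",
    "classical_mds",
    "isomap_embed",
    "auto_epsilon",
]

# exponent cap: exp(>700) overflows float64; extreme values saturate monotonically
_EXP_CAP = 700.0


@dataclass(frozen=True)
class EmbeddingConfig:
    """Isomap settings: neighborhood radius, output dimension, zoom parameter."""

    epsilon: float | None = 0.15  # None requests the auto (smallest-connected) choice
    ndim: int = 2
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.ndim < 1:
            raise ValueError("ndim must be at least 1")


@dataclass(frozen=True)
class TransformedDistances:
    """Normalized Box-Cox-transformed pleiotropy distances in [0, 1]."""

    dist: np.ndarray
    lam: float
    raw_range: tuple[float, float]
    phenotype_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        d = np.asarray(self.dist, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("dist must be square")
        if not np.allclose(d, d.T):
            raise ValueError("dist must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("dist must have a zero diagonal")

    @property
    def n_pheno(self) -> int:
        return self.dist.shape[0]


@dataclass(frozen=True)
class PhenotypeMap:
    """Embedded phenotype coordinates plus the geodesic distances behind them."""

    coords: np.ndarray
    eigenvalues: np.ndarray
    config: EmbeddingConfig
    graph_distances: np.ndarray
    phenotype_names: tuple[str, ...] = ()
    cluster_labels: np.ndarray | None = None

    def with_clusters(self, labels: np.ndarray) -> "PhenotypeMap":
        return PhenotypeMap(
            coords=self.coords,
            eigenvalues=self.eigenvalues,
            config=self.config,
            graph_distances=self.graph_distances,
            phenotype_names=self.phenotype_names,
            cluster_labels=np.asarray(labels),
        )


def box_cox(y, lam: float):
    """Power-family transform ``(y**lam - 1) / lam``, natural log at ``lam = 0``.

    Strictly increasing in ``y`` for every ``lam`` and continuous in ``lam``.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0) or np.any(y > 1):
        raise ValueError("y must lie in (0, 1]")
    out = _box_cox_from_log(np.log(y), lam)
    return out if out.ndim else float(out)


def _box_cox_from_log(logy: np.ndarray, lam: float) -> np.ndarray:
    """Box-Cox evaluated from log(y), stable for p-values far below underflow."""
    lam = float(lam)
    if lam == 0.0:
        return np.asarray(logy, dtype=float)
    expo = np.minimum(lam * np.asarray(logy, dtype=float), _EXP_CAP)
    return np.expm1(expo) / lam


def transform_distance_matrix(pm, lam: float = 0.0) -> TransformedDistances:
    """Box-Cox transform the pleiotropy p-value matrix into [0, 1] distances.

    Accepts a ``PleiotropyMatrix`` (whose exact log p-values are used, so
    pairs whose p-values underflow double precision remain distinguishable)
    or any square symmetric array of p-values in (0, 1].

    Off-diagonal entries are transformed elementwise and then min-max
    rescaled to [0, 1]; the diagonal is 0. The map is monotone, so the rank
    order of the raw p-values is preserved: a smaller pleiotropy p-value
    yields a smaller distance.
    """
    names: tuple[str, ...] = ()
    if hasattr(pm, "log_pvalues"):
        logy = np.asarray(pm.log_pvalues, dtype=float)
        names = tuple(pm.phenotype_names)
    else:
        y = np.asarray(pm, dtype=float)
        if np.any(y <= 0) or np.any(y > 1):
            raise ValueError("p-values must lie in (0, 1]")
        logy = np.log(y)
    k = logy.shape[0]
    if k < 3:
        raise ValueError(f"need at least 3 phenotypes, got {k}")
    off = ~np.eye(k, dtype=bool)
    s = _box_cox_from_log(logy, lam)
    lo, hi = float(s[off].min()), float(s[off].max())
    if hi == lo:
        raise DegenerateDistanceError(
            "all off-diagonal p-values are identical; normalization is undefined"
        )
    dist = np.zeros_like(s)
    dist[off] = (s[off] - lo) / (hi - lo)
    dist = (dist + dist.T) / 2.0  # exact symmetry despite float rounding
    np.fill_diagonal(dist, 0.0)
    return TransformedDistances(dist=dist, lam=float(lam), raw_range=(lo, hi),
                                phenotype_names=names)


def epsilon_graph(td: TransformedDistances, epsilon: float) -> nx.Graph:
    """Undirected graph with an edge (i, j) iff ``dist_ij <= epsilon``.

    Raises ``FragmentedDataError`` when the graph is disconnected.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    k = td.n_pheno
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if td.dist[i, j] <= epsilon:
                g.add_edge(i, j, weight=float(td.dist[i, j]))
    if not nx.is_connected(g):
        raise FragmentedDataError(
            f"epsilon={epsilon} yields a fragmented neighborhood graph; "
            "increase epsilon"
        )
    return g


def shortest_path_distances(graph: nx.Graph) -> np.ndarray:
    """All-pairs shortest-path (geodesic) distances by Floyd-Warshall.

    Initializes d(i, j) to the edge weight where an edge exists and infinity
    otherwise, then relaxes d(i, j) <- min(d(i, j), d(i, k) + d(k, j)) over
    every intermediate node k.
    """
    nodes = sorted(graph.nodes())
    k = len(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    d = np.full((k, k), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v, w in graph.edges(data="weight"):
        d[idx[u], idx[v]] = d[idx[v], idx[u]] = float(w)
    for mid in range(k):
        d = np.minimum(d, d[:, mid, None] + d[None, mid, :])
    if np.isinf(d).any():
        raise FragmentedDataError("graph is disconnected; geodesics undefined")
    return d


def classical_mds(d: np.ndarray, ndim: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers the squared distances, ``B = -0.5 * H (D o D) H`` with
    ``H = I - 11'/n``, and returns coordinates built from the top ``ndim``
    eigenvectors scaled by the square roots of their eigenvalues, together
    with those eigenvalues in non-increasing order. Axes whose eigenvalue is
    not positive are zero-padded with a warning. Each axis's sign is fixed so
    its largest-magnitude loading is positive.
    """
    d = np.asarray(d, dtype=float)
    k = d.shape[0]
    if d.shape != (k, k) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(d < 0) or np.any(np.diag(d) != 0):
        raise ValueError("distances must be non-negative with a zero diagonal")
    h = np.eye(k) - np.full((k, k), 1.0 / k)
    b = -0.5 * h @ (d * d) @ h
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals, kind="stable")[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    top_vals = eigvals[:ndim]
    # eigenvalues within rounding error of zero count as non-positive
    eig_tol = max(eigvals[0], 0.0) * 1e-12
    n_pos = int(np.sum(top_vals > eig_tol))
    if n_pos < ndim:
        warnings.warn(
            f"only {n_pos} positive eigenvalues for ndim={ndim}; "
            "remaining coordinates set to zero",
            stacklevel=2,
        )
    coords = np.zeros((k, ndim))
    for a in range(min(ndim, k)):
        if eigvals[a] <= eig_tol:
            continue
        axis = eigvecs[:, a] * np.sqrt(eigvals[a])
        pivot = int(np.argmax(np.abs(axis)))
        if axis[pivot] < 0:
            axis = -axis
        coords[:, a] = axis
    return coords, top_vals.copy()


def isomap_embed(
    td: TransformedDistances, config: EmbeddingConfig | None = None
) -> PhenotypeMap:
    """epsilon-graph -> geodesic distances -> classical MDS, deterministically."""
    config = config or EmbeddingConfig()
    eps = config.epsilon if config.epsilon is not None else auto_epsilon(td)
    graph = epsilon_graph(td, eps)
    d_g = shortest_path_distances(graph)
    coords, eigvals = classical_mds(d_g, config.ndim)
    resolved = EmbeddingConfig(epsilon=eps, ndim=config.ndim, lam=config.lam)
    return PhenotypeMap(
        coords=coords,
        eigenvalues=eigvals,
        config=resolved,
        graph_distances=d_g,
        phenotype_names=td.phenotype_names,
    )


def auto_epsilon(td: TransformedDistances, grid_step: float = 0.05) -> float:
    """Smallest grid epsilon for which the neighborhood graph is connected.

    Scans the grid {grid_step, 2*grid_step, ..., 1}; epsilon = 1 always
    connects a min-max-normalized distance matrix.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    n_steps = int(np.ceil(1.0 / grid_step))
    for step in range(1, n_steps + 1):
        eps = min(step * grid_step, 1.0)
        try:
            epsilon_graph(td, eps)
        except FragmentedDataError:
            continue
        return eps
    return 1.0
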