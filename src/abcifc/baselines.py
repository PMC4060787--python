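"""Fuzzy c-means and plain intuitionistic-fuzzy-clustering comparators.

FCM is the classic alternating minimisation of
``J = Σ_i Σ_j u_ij^m ||x_i − v_j||²`` with

    u_ij = 1 / Σ_t (d_ij² / d_it²)^{1/(m−1)},
    v_j  = Σ_i u_ij^m x_i / Σ_i u_ij^m,

fuzzifier ``m = 2`` by default.  To run it on a graph, each node is
embedded as its row of the normalised weighted adjacency matrix — the
minimal coordinate system an edge list supports — and distances are
Euclidean there.

Plain IFC has no center-update rule of its own: a center set is drawn
at random, the intuitionistic membership matrix induces a partition,
and the best of several such restarts (by the clustering criterion) is
returned.  It is the no-search control for the bee-colony optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .graph_model import Clustering, PPINetwork
from .ifc_core import IFCParams, assign_clusters, compute_membership_matrix
from .objective import objective_value

__all__ = ["FCMParams", "fcm_cluster", "fcm_on_network", "ifc_cluster"]


@dataclass(frozen=True)
class FCMParams:
    """Fuzzy c-means settings (``m`` is the fuzzifier exponent)."""

    c: int
    m: float = 2.0
    tol: float = 1e-6
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError("need at least 2 clusters")
        if not self.m > 1.0:
            raise ValueError("fuzzifier m must exceed 1")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")


def _fcm_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Standard FCM membership update; crisp rows where a point sits on a center."""
    n, c = d2.shape
    u = np.zeros((n, c))
    zero_rows = np.any(d2 <= 0.0, axis=1)
    if np.any(zero_rows):
        # coincident point/center: full membership to the (first) matching center
        hit = np.argmin(d2[zero_rows], axis=1)
        u[np.where(zero_rows)[0], hit] = 1.0
    ok = ~zero_rows
    if np.any(ok):
        power = 1.0 / (m - 1.0)
        ratio = (d2[ok, :, None] / d2[ok, None, :]) ** power  # (n_ok, c, c)
        u[ok] = 1.0 / ratio.sum(axis=2)
    return u


def fcm_cluster(
    X: Sequence[Sequence[float]] | np.ndarray, params: FCMParams
) -> tuple[np.ndarray, np.ndarray, float]:
    """Run fuzzy c-means on feature vectors.

    Returns ``(centers, U, J)`` where rows of ``U`` sum to 1 and ``J``
    is the weighted within-cluster squared-distance objective at the
    final iterate.  Initial centers are seeded maximin-style: a random
    first data point, then repeatedly the point farthest from the
    centers chosen so far, which spreads the starting centers across
    well-separated groups regardless of the draw.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be an (n, p) array of equal-length vectors")
    n = X.shape[0]
    if n <= params.c:
        raise ValueError(f"need more samples ({n}) than clusters ({params.c})")

    rng = np.random.default_rng(params.seed)
    chosen = [int(rng.integers(n))]
    while len(chosen) < params.c:
        d2 = np.min(
            ((X[:, None, :] - X[chosen][None, :, :]) ** 2).sum(axis=2), axis=1
        )
        chosen.append(int(np.argmax(d2)))  # ties to the lowest index
    centers = X[chosen].copy()

    u = np.zeros((n, params.c))
    for _ in range(params.max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        u = _fcm_memberships(d2, params.m)
        um = u**params.m
        denom = um.sum(axis=0)
        # keep an empty (zero-mass) center in place rather than dividing by 0
        new_centers = centers.copy()
        nonzero = denom > 0
        new_centers[nonzero] = (um.T @ X)[nonzero] / denom[nonzero, None]
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < params.tol:
            break

    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    u = _fcm_memberships(d2, params.m)
    J = float((u**params.m * d2).sum())
    return centers, u, J


def fcm_on_network(net: PPINetwork, params: FCMParams) -> Clustering:
    """FCM on the graph via normalised-adjacency-row embedding.

    Hard assignment by argmax membership; each cluster's center is the
    member node whose embedding lies nearest the FCM centroid (the
    centroid-nearest node overall if the hard cluster came out empty).
    """
    nodes = net.nodes
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((n, n))
    for a, b, _, nw in net.edges():
        A[index[a], index[b]] = nw
        A[index[b], index[a]] = nw

    centers, u, _ = fcm_cluster(A, params)
    hard = np.argmax(u, axis=1)
    clusters: list[set[str]] = [set() for _ in range(params.c)]
    for i, v in enumerate(nodes):
        clusters[hard[i]].add(v)

    center_nodes: list[str] = []
    for j in range(params.c):
        d2 = ((A - centers[j][None, :]) ** 2).sum(axis=1)
        member_idx = [i for i in range(n) if hard[i] == j]
        pool = member_idx if member_idx else list(range(n))
        best = min(pool, key=lambda i: (d2[i], nodes[i]))
        center_nodes.append(nodes[best])
        clusters[j].add(nodes[best])
        if not member_idx:
            # centroid-nearest node was borrowed from another cluster
            other = hard[best]
            if nodes[best] in clusters[other] and other != j:
                clusters[other].discard(nodes[best])
    return Clustering(clusters=clusters, centers=center_nodes)


def ifc_cluster(
    net: PPINetwork,
    c: int,
    restarts: Optional[int] = None,
    ifc_params: IFCParams = IFCParams(),
    seed: int = 0,
    include_diagonal: bool = False,
) -> Clustering:
    """Best-of-random-restarts intuitionistic fuzzy clustering.

    ``restarts`` defaults to ``2c``, matching the bee colony's
    population budget.  The restart with the smallest objective wins.
    """
    n = net.number_of_nodes()
    if c >= n:
        raise ValueError(f"cluster count {c} must be below node count {n}")
    if restarts is None:
        restarts = 2 * c
    if restarts < 1:
        raise ValueError("restarts must be >= 1")

    rng = np.random.default_rng(seed)
    nodes = net.nodes
    best: tuple[float, Clustering] | None = None
    for _ in range(restarts):
        idx = rng.choice(n, size=c, replace=False)
        centers = tuple(nodes[i] for i in idx)
        matrix = compute_membership_matrix(net, centers, ifc_params)
        clustering = assign_clusters(matrix, ifc_params)
        fval = objective_value(net, clustering, include_diagonal).fval
        if best is None or fval < best[0]:
            best = (fval, clustering)
    assert best is not None
    return best[1]
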