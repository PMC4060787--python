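"""Clustering criterion for weighted PPI partitions.

The objective to minimise combines two pressures: clusters should be
mutually dissimilar (small inter-cluster connection mass) and internally
dense and heavy (large mean density-plus-weight):

    fval = (1/c²) Σ_{i≠j} sim(I_i, I_j)  +  1 / DEW      (DEW ≠ 0)
         = (1/c²) Σ_{i≠j} sim(I_i, I_j)                  (DEW = 0)

with ``sim(I, J) = Σ_{x∈I, y∈J} c(x, y) / max(|I|, |J|)`` built on the
connection strength ``c(x, y)`` (1 on the diagonal, the normalised edge
weight for interacting pairs, 0 otherwise), and

    DEW = (1/c) Σ_i (den(i) + dw(i)),
    den(i) = 2 e_i / (n_i (n_i − 1)),   dw(i) = Σ w̄_e / (n_i (n_i − 1)),

where ``e_i`` counts intra-cluster edges, each undirected edge once.
Smaller is better on both terms.  The self-similarity terms ``i = j``
are excluded from the double sum by default (they reward sparse
clusters, fighting the DEW term); ``include_diagonal=True`` restores
the literal double sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .graph_model import Clustering, PPINetwork

__all__ = [
    "ObjectiveBreakdown",
    "connection_strength",
    "cluster_similarity",
    "cluster_density",
    "objective_value",
]


@dataclass(frozen=True)
class ObjectiveBreakdown:
    """The objective and its parts for one clustering."""

    sim_term: float
    dew: float
    fval: float
    per_cluster: tuple[tuple[float, float], ...]  # (den_i, dw_i)

    def to_dict(self) -> dict:
        return {
            "fval": self.fval,
            "sim_term": self.sim_term,
            "dew": self.dew,
            "per_cluster": [
                {"den": den, "dw": dw} for den, dw in self.per_cluster
            ],
        }


def connection_strength(net: PPINetwork, x: str, y: str) -> float:
    """c(x, y): 1 if x = y, w̄(x, y) if they interact, 0 otherwise."""
    if x not in net or y not in net:
        raise KeyError("both nodes must belong to the network")
    if x == y:
        return 1.0
    if net.has_edge(x, y):
        return net.norm_weight(x, y)
    return 0.0


def cluster_similarity(
    net: PPINetwork, I: Iterable[str], J: Iterable[str]
) -> float:
    """sim(I, J) = Σ_{x∈I, y∈J} c(x, y) / max(|I|, |J|); symmetric."""
    I, J = set(I), set(J)
    if not I or not J:
        raise ValueError("clusters must be non-empty")
    total = float(len(I & J))  # the c(x,y)=1 diagonal pairs
    for x in I:
        for y in net.neighbors(x):
            if y in J and y != x:
                total += net.norm_weight(x, y)
    return total / max(len(I), len(J))


def cluster_density(net: PPINetwork, cluster: Iterable[str]) -> tuple[float, float]:
    """(den, dw) of one cluster; (0, 0) for singletons and empty sets.

    ``den`` is the ordinary edge density 2e / (n(n−1)); ``dw`` is the sum
    of normalised intra-cluster edge weights over the same ordered-pair
    denominator, so a complete unit-weight cluster has den = 1, dw = 0.5.
    """
    members = set(cluster)
    for node in members:
        if node not in net:
            raise KeyError(f"unknown node {node!r}")
    n = len(members)
    if n < 2:
        return 0.0, 0.0
    e = 0
    sw = 0.0
    for x in members:
        for y in net.neighbors(x):
            if y in members and x < y:  # each undirected edge once
                e += 1
                sw += net.norm_weight(x, y)
    denom = n * (n - 1)
    return 2.0 * e / denom, sw / denom


def objective_value(
    net: PPINetwork,
    clustering: Clustering,
    include_diagonal: bool = False,
) -> ObjectiveBreakdown:
    """Evaluate the clustering criterion; smaller fval is better."""
    c = clustering.c
    if c < 2:
        raise ValueError("the objective needs at least 2 clusters")
    if any(not cl for cl in clustering.clusters):
        raise ValueError("clusters must be non-empty")

    # sim is symmetric, so the ordered-pair double sum is twice the
    # upper triangle, plus the diagonal when requested
    sim_total = 0.0
    for i in range(c):
        for j in range(i + 1, c):
            sim_total += 2.0 * cluster_similarity(
                net, clustering.clusters[i], clustering.clusters[j]
            )
    if include_diagonal:
        for i in range(c):
            sim_total += cluster_similarity(
                net, clustering.clusters[i], clustering.clusters[i]
            )
    sim_term = sim_total / (c * c)

    per_cluster = tuple(
        cluster_density(net, cl) for cl in clustering.clusters
    )
    dew = sum(den + dw for den, dw in per_cluster) / c
    fval = sim_term + (1.0 / dew if dew != 0.0 else 0.0)
    return ObjectiveBreakdown(
        sim_term=sim_term, dew=dew, fval=fval, per_cluster=per_cluster
    )
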