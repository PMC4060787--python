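"""Weighted PPI networks, reference module catalogs, and clusterings.

The clustering substrate is an undirected graph whose nodes are opaque,
case-sensitive protein identifiers and whose edges carry a positive raw
interaction weight.  Alongside each raw weight the network stores a
max-normalised weight ``w̄ = w / max_w`` in ``(0, 1]``; downstream
components use ``w̄`` wherever a quantity must live on the unit interval
(hesitation degrees, connection strengths, intra-cluster weight sums).

Per-node "information" is the weighted degree (sum of raw incident
weights): the only per-node quantity the edge-list data supports that is
monotone both in connectivity and in interaction strength.  The onlooker
bees of the colony optimizer rank candidate centers by it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkFormatError",
    "PPINetwork",
    "ReferenceCatalog",
    "Clustering",
    "load_network",
    "write_network",
    "load_reference",
    "write_reference",
]


class NetworkFormatError(ValueError):
    """Raised for malformed edge-list or catalog files."""


class PPINetwork:
    """Undirected, positively weighted protein-protein interaction graph.

    Parameters
    ----------
    graph:
        An undirected :class:`networkx.Graph` whose edges carry a positive
        ``weight`` attribute.  Self-loops must already have been removed.
    self_loops_dropped:
        Number of self-loops discarded while building the graph (kept for
        reporting).

    Notes
    -----
    Normalised weights (``nweight`` edge attribute) are computed on
    construction as raw weight divided by the maximum raw weight, so the
    strongest interaction always has ``w̄ = 1`` exactly.
    """

    def __init__(self, graph: nx.Graph, self_loops_dropped: int = 0) -> None:
        if graph.is_directed():
            raise ValueError("PPI networks are undirected")
        if any(a == b for a, b in graph.edges):
            raise ValueError("self-loops must be removed before construction")
        for a, b, w in graph.edges(data="weight"):
            if w is None:
                raise NetworkFormatError(f"edge ({a}, {b}) has no weight")
            if not w > 0:
                raise NetworkFormatError(
                    f"edge ({a}, {b}) has non-positive weight {w!r}"
                )
        self._g = graph
        self.self_loops_dropped = int(self_loops_dropped)
        self._max_weight = (
            max(w for _, _, w in graph.edges(data="weight"))
            if graph.number_of_edges()
            else None
        )
        if self._max_weight is not None:
            for a, b, w in graph.edges(data="weight"):
                graph.edges[a, b]["nweight"] = w / self._max_weight
        self._info: dict[str, float] = {}
        self._node_list: tuple[str, ...] = tuple(sorted(graph.nodes))

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        nodes: Iterable[str] = (),
    ) -> "PPINetwork":
        """Build a network from ``(a, b, weight)`` triples.

        Duplicate edges are collapsed keeping the maximum weight (order
        independent); self-loops are dropped and counted.  ``nodes`` may
        add isolated nodes beyond the edge endpoints.
        """
        g = nx.Graph()
        g.add_nodes_from(nodes)
        dropped = 0
        for a, b, w in edges:
            if a == b:
                dropped += 1
                continue
            if not w > 0:
                raise NetworkFormatError(
                    f"edge ({a}, {b}) has non-positive weight {w!r}"
                )
            if g.has_edge(a, b):
                g.edges[a, b]["weight"] = max(g.edges[a, b]["weight"], w)
            else:
                g.add_edge(a, b, weight=float(w))
        if dropped:
            logger.warning("dropped %d self-loop(s)", dropped)
        return cls(g, self_loops_dropped=dropped)

    # -- basic queries -------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> tuple[str, ...]:
        """All node IDs in sorted order (deterministic iteration)."""
        return self._node_list

    @property
    def max_weight(self) -> Optional[float]:
        return self._max_weight

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def neighbors(self, node: str) -> list[str]:
        self._require(node)
        return sorted(self._g.neighbors(node))

    def weight(self, a: str, b: str) -> float:
        """Raw weight of edge ``(a, b)``; raises if absent."""
        return self._g.edges[a, b]["weight"]

    def norm_weight(self, a: str, b: str) -> float:
        """Normalised weight ``w̄`` of edge ``(a, b)``; raises if absent."""
        return self._g.edges[a, b]["nweight"]

    def edges(self) -> Iterator[tuple[str, str, float, float]]:
        """Yield ``(a, b, raw_weight, norm_weight)`` with ``a < b``."""
        for a, b, data in self._g.edges(data=True):
            lo, hi = (a, b) if a <= b else (b, a)
            yield lo, hi, data["weight"], data["nweight"]

    def _require(self, node: str) -> None:
        if node not in self._g:
            raise KeyError(f"unknown node {node!r}")

    # -- information and neighbor ranking ------------------------------

    def information(self, node: str) -> float:
        """Amount of information of ``node``: its weighted degree.

        Sum of the raw weights of incident edges; 0 for isolated nodes.
        """
        self._require(node)
        if node not in self._info:
            self._info[node] = float(
                sum(d["weight"] for d in self._g[node].values())
            )
        return self._info[node]

    def neighbor_ranking(self, node: str) -> list[str]:
        """Neighbors of ``node`` ordered by decreasing information.

        Ties break lexicographically on node ID, so the ranking is a
        deterministic function of the network alone.
        """
        return sorted(self.neighbors(node), key=lambda v: (-self.information(v), v))

    def ranked_neighbors(self, node: str, rank: str) -> Optional[str]:
        """Neighbor with the largest (``rank='first'``) or second-largest
        (``rank='second'``) information, or ``None`` if too few neighbors."""
        idx = {"first": 0, "second": 1}
        if rank not in idx:
            raise ValueError(f"rank must be 'first' or 'second', got {rank!r}")
        ranking = self.neighbor_ranking(node)
        return ranking[idx[rank]] if len(ranking) > idx[rank] else None


@dataclass(frozen=True)
class ReferenceCatalog:
    """Named reference modules (complex catalog) used by the evaluation."""

    modules: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.modules]
        if len(set(names)) != len(names):
            raise ValueError("module names must be unique")
        if any(not members for _, members in self.modules):
            raise ValueError("modules must be non-empty")

    def __len__(self) -> int:
        return len(self.modules)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.modules]

    def module(self, name: str) -> frozenset[str]:
        for n, members in self.modules:
            if n == name:
                return members
        raise KeyError(name)

    def all_proteins(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.modules:
            out |= members
        return frozenset(out)


@dataclass
class Clustering:
    """A list of node sets with the center that seeds each cluster."""

    clusters: list[set[str]]
    centers: list[str]

    def __post_init__(self) -> None:
        if len(self.clusters) != len(self.centers):
            raise ValueError("one center per cluster required")
        for center, cluster in zip(self.centers, self.clusters):
            if center not in cluster:
                raise ValueError(f"center {center!r} not in its own cluster")

    @property
    def c(self) -> int:
        return len(self.clusters)

    def membership_of(self, node: str) -> list[int]:
        return [i for i, cl in enumerate(self.clusters) if node in cl]


# -- file I/O ----------------------------------------------------------


def _parse_weight(token: str, lineno: int) -> float:
    try:
        w = float(token)
    except ValueError as exc:
        raise NetworkFormatError(
            f"line {lineno}: cannot parse weight {token!r}"
        ) from exc
    if not w > 0:
        raise NetworkFormatError(f"line {lineno}: non-positive weight {w!r}")
    return w


def load_network(path: str | Path, dialect: str = "tsv") -> PPINetwork:
    """Load a weighted edge list.

    ``tsv`` rows are ``idA idB [weight]`` (tab or whitespace separated,
    weight defaults to 1.0); ``sif`` rows are ``idA relation idB`` with
    weight 1.0.  ``#`` lines are comments.  Duplicate edges keep the
    maximum weight; self-loops are dropped with a logged warning count.
    """
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if dialect == "sif":
                if len(toks) != 3:
                    raise NetworkFormatError(
                        f"line {lineno}: SIF rows need 3 tokens, got {len(toks)}"
                    )
                edges.append((toks[0], toks[2], 1.0))
            else:
                if len(toks) == 2:
                    edges.append((toks[0], toks[1], 1.0))
                elif len(toks) == 3:
                    edges.append((toks[0], toks[1], _parse_weight(toks[2], lineno)))
                else:
                    raise NetworkFormatError(
                        f"line {lineno}: expected 2 or 3 tokens, got {len(toks)}"
                    )
    return PPINetwork.from_edges(edges)


def write_network(net: PPINetwork, path: str | Path) -> Path:
    """Write the raw-weight edge list as TSV (round-trips with load)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# idA\tidB\tweight\n")
        for a, b, w, _ in sorted(net.edges()):
            fh.write(f"{a}\t{b}\t{w!r}\n")
    return path


def load_reference(path: str | Path, named: bool = False) -> ReferenceCatalog:
    """Load a reference catalog: one module per line, whitespace-separated IDs.

    With ``named=True`` the first token of each line is the module name;
    otherwise modules are named ``module_<k>`` in file order.  Duplicate
    IDs within a line are deduplicated; empty lines are skipped.
    """
    path = Path(path)
    modules: list[tuple[str, frozenset[str]]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if named:
                if len(toks) < 2:
                    raise NetworkFormatError(
                        f"line {lineno}: named module needs a name and >=1 ID"
                    )
                name, members = toks[0], frozenset(toks[1:])
            else:
                name, members = f"module_{len(modules) + 1}", frozenset(toks)
            modules.append((name, members))
    if not modules:
        raise NetworkFormatError(f"{path}: no modules found")
    return ReferenceCatalog(tuple(modules))


def write_reference(catalog: ReferenceCatalog, path: str | Path, named: bool = False) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for name, members in catalog.modules:
            ids = " ".join(sorted(members))
            fh.write(f"{name} {ids}\n" if named else f"{ids}\n")
    return path
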