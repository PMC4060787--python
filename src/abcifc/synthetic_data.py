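"""Planted-module weighted networks with known ground truth.

The generator emulates the character of a sparse, weighted yeast
interactome slice: a handful of dense protein modules (intra-module edge
probability ``p_in``, weights drawn high) embedded in a weak background
(inter-module probability ``p_out``, weights drawn low), optionally with
extra preferentially attached edges that thicken the degree tail the way
hub proteins do.  The planted modules double as the reference catalog,
so every downstream component can be tested without any database
download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph_model import (
    PPINetwork,
    ReferenceCatalog,
    write_network,
    write_reference,
)

__all__ = ["PlantedConfig", "generate_planted_network", "write_fixture"]


@dataclass(frozen=True)
class PlantedConfig:
    """Parameters of the planted-partition generator.

    Defaults are the benchmark conditions used throughout the test
    suite: three modules of ten proteins, strong intra-module signal
    (``p_in = 0.9``, weights U(0.6, 1)) over a weak background
    (``p_out = 0.05``, weights U(0.1, 0.3)), no extra hub edges.
    """

    k: int = 3
    sizes: tuple[int, ...] = (10, 10, 10)
    p_in: float = 0.9
    p_out: float = 0.05
    w_in: tuple[float, float] = (0.6, 1.0)
    w_out: tuple[float, float] = (0.1, 0.3)
    hub_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k != len(self.sizes):
            raise ValueError("k must equal len(sizes)")
        if any(s < 2 for s in self.sizes):
            raise ValueError("module sizes must be >= 2")
        if not (0.0 <= self.p_out < self.p_in <= 1.0) and not (
            self.p_in == self.p_out == 0.0
        ):
            raise ValueError("need 0 <= p_out < p_in <= 1 (or both zero)")
        for lo, hi in (self.w_in, self.w_out):
            if not (0.0 < lo <= hi):
                raise ValueError("weight ranges must be positive and ordered")
        if not 0.0 <= self.hub_fraction:
            raise ValueError("hub_fraction must be >= 0")


def _module_labels(cfg: PlantedConfig) -> list[list[str]]:
    width = len(str(sum(cfg.sizes)))
    labels, counter = [], 0
    for m, size in enumerate(cfg.sizes, start=1):
        block = []
        for _ in range(size):
            counter += 1
            block.append(f"P{counter:0{width}d}")
        labels.append(block)
    return labels


def generate_planted_network(
    cfg: PlantedConfig,
) -> tuple[PPINetwork, ReferenceCatalog]:
    """Draw one planted-module network and its ground-truth catalog.

    Each intra-module pair is edged with probability ``p_in`` and weight
    ``U(w_in)``; each inter-module pair with probability ``p_out`` and
    weight ``U(w_out)``.  Then ``hub_fraction * |E|`` extra edges are
    attached preferentially by current degree (both endpoints drawn
    degree-proportionally) with background weights.  Fully reproducible
    from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    blocks = _module_labels(cfg)
    all_nodes = [v for block in blocks for v in block]
    module_of = {v: m for m, block in enumerate(blocks) for v in block}

    edges: list[tuple[str, str, float]] = []
    n = len(all_nodes)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = all_nodes[i], all_nodes[j]
            same = module_of[a] == module_of[b]
            p = cfg.p_in if same else cfg.p_out
            if p > 0 and rng.random() < p:
                lo, hi = cfg.w_in if same else cfg.w_out
                edges.append((a, b, float(rng.uniform(lo, hi))))

    if cfg.hub_fraction > 0 and edges:
        n_extra = int(round(cfg.hub_fraction * len(edges)))
        degree = {v: 0 for v in all_nodes}
        existing = {frozenset((a, b)) for a, b, _ in edges}
        for a, b, _ in edges:
            degree[a] += 1
            degree[b] += 1
        lo, hi = cfg.w_out
        attempts = 0
        added = 0
        while added < n_extra and attempts < 50 * n_extra:
            attempts += 1
            weights = np.array([degree[v] + 1 for v in all_nodes], dtype=float)
            probs = weights / weights.sum()
            a, b = rng.choice(all_nodes, size=2, replace=False, p=probs)
            key = frozenset((a, b))
            if key in existing:
                continue
            existing.add(key)
            edges.append((str(a), str(b), float(rng.uniform(lo, hi))))
            degree[str(a)] += 1
            degree[str(b)] += 1
            added += 1

    net = PPINetwork.from_edges(edges, nodes=all_nodes)
    catalog = ReferenceCatalog(
        tuple(
            (f"planted_{m + 1}", frozenset(block))
            for m, block in enumerate(blocks)
        )
    )
    return net, catalog


def write_fixture(
    net: PPINetwork, catalog: ReferenceCatalog, directory: str | Path
) -> tuple[Path, Path]:
    """Write ``network.tsv`` + ``reference.txt`` in the formats the
    loaders read; the pair round-trips exactly (weights via ``repr``)."""
    if len(catalog) == 0:
        raise ValueError("catalog must be non-empty")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    net_path = write_network(net, directory / "network.tsv")
    ref_path = write_reference(catalog, directory / "reference.txt")
    return net_path, ref_path
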