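"""Artificial-bee-colony search over cluster-center sets.

A nectar source is an ordered set of ``c`` distinct protein nodes — a
candidate group of cluster centers.  Its quality is the clustering
criterion evaluated on the intuitionistic fuzzy partition those centers
induce; smaller is better.  The colony holds ``pop_size`` sources
(default ``2c``).  Each iteration every source is exploited once:

* an employed/onlooker move replaces one center, chosen uniformly, by a
  neighbor of that center ranked by "information" (weighted degree) —
  the top-ranked neighbor with probability ``1 − prob``, otherwise the
  second-ranked, falling back through the remaining ranking until the
  center set stays distinct;
* the move is accepted only if it strictly lowers the objective
  (greedy acceptance), else the source's trial counter grows;
* a source whose trial counter exceeds ``max_limit`` is abandoned and a
  scout draws a fresh uniformly random center set.

The best source ever seen (``gbest``) is tracked across iterations; its
objective trace is non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .graph_model import Clustering, PPINetwork
from .ifc_core import IFCParams, assign_clusters, compute_membership_matrix
from .objective import ObjectiveBreakdown, objective_value

__all__ = [
    "NectarSource",
    "ABCConfig",
    "ABCResult",
    "evaluate_centers",
    "init_population",
    "neighbor_move",
    "greedy_accept",
    "scout_phase",
    "run_abc_ifc",
]


@dataclass(frozen=True)
class NectarSource:
    """One candidate center set with its fitness and trial counter."""

    centers: tuple[str, ...]
    fval: float
    clustering: Clustering
    breakdown: ObjectiveBreakdown
    trial: int = 0

    def __post_init__(self) -> None:
        if len(set(self.centers)) != len(self.centers):
            raise ValueError("centers must be distinct")
        if self.trial < 0:
            raise ValueError("trial must be >= 0")


@dataclass(frozen=True)
class ABCConfig:
    """Colony configuration.

    ``prob = 0.4`` and ``max_limit = 5`` are the settings at which the
    clustering is reported to behave best; ``pop_size`` defaults to
    twice the cluster count.
    """

    c: int
    maxiter: int = 100
    prob: float = 0.4
    max_limit: int = 5
    pop_size: Optional[int] = None
    seed: int = 0
    ifc_params: IFCParams = field(default_factory=IFCParams)
    include_diagonal: bool = False

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError("need at least 2 clusters")
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("prob must lie in [0, 1]")
        if self.max_limit < 1:
            raise ValueError("max_limit must be >= 1")
        if self.maxiter < 0:
            raise ValueError("maxiter must be >= 0")
        if self.pop_size is not None and self.pop_size < 1:
            raise ValueError("pop_size must be >= 1")

    @property
    def effective_pop_size(self) -> int:
        return self.pop_size if self.pop_size is not None else 2 * self.c


@dataclass(frozen=True)
class ABCResult:
    """Outcome of one colony run."""

    gbest_centers: tuple[str, ...]
    gbest_clustering: Clustering
    gbest_fval: float
    gbest_breakdown: ObjectiveBreakdown
    fval_trace: tuple[float, ...]
    scout_events: int


def evaluate_centers(
    net: PPINetwork, centers: Sequence[str], cfg: ABCConfig, trial: int = 0
) -> NectarSource:
    """Membership -> assignment -> objective for one center set."""
    matrix = compute_membership_matrix(net, centers, cfg.ifc_params)
    clustering = assign_clusters(matrix, cfg.ifc_params)
    breakdown = objective_value(net, clustering, cfg.include_diagonal)
    return NectarSource(
        centers=tuple(centers),
        fval=breakdown.fval,
        clustering=clustering,
        breakdown=breakdown,
        trial=trial,
    )


def _random_centers(
    net: PPINetwork, c: int, rng: np.random.Generator
) -> tuple[str, ...]:
    nodes = net.nodes
    idx = rng.choice(len(nodes), size=c, replace=False)
    return tuple(nodes[i] for i in idx)


def init_population(
    net: PPINetwork, cfg: ABCConfig, rng: np.random.Generator
) -> list[NectarSource]:
    """Seed the colony with uniformly random distinct center sets."""
    n = net.number_of_nodes()
    if cfg.c >= n:
        raise ValueError(f"cluster count {cfg.c} must be below node count {n}")
    return [
        evaluate_centers(net, _random_centers(net, cfg.c, rng), cfg)
        for _ in range(cfg.effective_pop_size)
    ]


def neighbor_move(
    net: PPINetwork,
    source: NectarSource,
    cfg: ABCConfig,
    rng: np.random.Generator,
) -> Optional[NectarSource]:
    """Propose a source with one center swapped for a ranked neighbor.

    A random draw above ``prob`` targets the information-richest
    neighbor of the chosen center, otherwise the second richest; if the
    preferred neighbor would collide with another center, the remaining
    neighbors are tried in ranking order.  Returns ``None`` when no
    admissible neighbor exists (failed search).
    """
    idx = int(rng.integers(len(source.centers)))
    center = source.centers[idx]
    ranking = net.neighbor_ranking(center)
    if not ranking:
        return None
    preferred = 0 if rng.random() > cfg.prob else 1
    if preferred >= len(ranking):
        preferred = 0
    order = [ranking[preferred]] + [
        v for k, v in enumerate(ranking) if k != preferred
    ]
    occupied = set(source.centers)
    for candidate in order:
        if candidate in occupied:
            continue
        centers = list(source.centers)
        centers[idx] = candidate
        return evaluate_centers(net, centers, cfg, trial=source.trial)
    return None


def greedy_accept(
    source: NectarSource, candidate: Optional[NectarSource]
) -> NectarSource:
    """Keep the candidate only on strict improvement; else count a failure."""
    if candidate is not None and candidate.fval < source.fval:
        return replace(candidate, trial=0)
    return replace(source, trial=source.trial + 1)


def scout_phase(
    net: PPINetwork,
    source: NectarSource,
    cfg: ABCConfig,
    rng: np.random.Generator,
) -> NectarSource:
    """Abandon an exhausted source for a fresh uniformly random one."""
    if source.trial <= cfg.max_limit:
        raise ValueError("scout fires only when trial exceeds max_limit")
    return evaluate_centers(net, _random_centers(net, cfg.c, rng), cfg)


def run_abc_ifc(net: PPINetwork, cfg: ABCConfig) -> ABCResult:
    """Full colony loop; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    population = init_population(net, cfg, rng)
    gbest = min(population, key=lambda s: s.fval)
    trace = [gbest.fval]
    scout_events = 0

    for _ in range(cfg.maxiter):
        for k, source in enumerate(population):
            candidate = neighbor_move(net, source, cfg, rng)
            source = greedy_accept(source, candidate)
            if source.trial > cfg.max_limit:
                source = scout_phase(net, source, cfg, rng)
                scout_events += 1
            population[k] = source
            if source.fval < gbest.fval:
                gbest = source
        trace.append(gbest.fval)

    return ABCResult(
        gbest_centers=gbest.centers,
        gbest_clustering=gbest.clustering,
        gbest_fval=gbest.fval,
        gbest_breakdown=gbest.breakdown,
        fval_trace=tuple(trace),
        scout_events=scout_events,
    )
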