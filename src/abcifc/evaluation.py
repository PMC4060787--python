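"""Matching-based quality metrics for clusterings against a reference.

Each experimental cluster ``C`` is matched to the reference module ``F``
maximising the matching score ``MMS(C, F) = |C ∩ F|``; then

    precision(C|F) = MMS / |C|,   recall(C|F) = MMS / |F|,
    f-measure = 2 · precision · recall / (precision + recall),

and an enrichment P value — the upper hypergeometric tail probability
that a cluster of size ``m`` drawn from a background of ``M`` proteins
contains at least ``d`` of the ``D`` proteins sharing the matched
function:

    P = Σ_{j=d}^{m} C(D, j) C(M−D, m−j) / C(M, m).

Composite precision/recall are cluster-size-weighted means (so an
everything-in-one-cluster solution scores high recall but collapses in
precision, and vice versa for singletons), combined into a composite
f-measure by the harmonic mean; the composite P value is the plain mean
of the per-cluster tails.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional

import numpy as np
from scipy.special import gammaln, logsumexp

from .graph_model import Clustering, ReferenceCatalog

__all__ = [
    "mms",
    "pair_metrics",
    "p_value",
    "ClusterMatch",
    "EvaluationReport",
    "evaluate_clustering",
]


def mms(C: Iterable[str], F: Iterable[str]) -> int:
    """Maximum matching score: size of the intersection."""
    C, F = set(C), set(F)
    if not C or not F:
        raise ValueError("both sets must be non-empty")
    return len(C & F)


def pair_metrics(C: Iterable[str], F: Iterable[str]) -> tuple[float, float, float]:
    """(precision, recall, f-measure) of one cluster/module pair."""
    C, F = set(C), set(F)
    score = mms(C, F)
    precision = score / len(C)
    recall = score / len(F)
    f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f


def _log_binom(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def p_value(M: int, D: int, m: int, d: int) -> float:
    """Upper hypergeometric tail P(X >= d) for X ~ Hypergeom(M, D, m).

    Computed in log space for stability; terms with ``j > D`` or
    ``m − j > M − D`` are structurally zero and skipped.
    """
    if not (0 <= d <= m <= M):
        raise ValueError(f"need 0 <= d <= m <= M, got d={d}, m={m}, M={M}")
    if not (0 <= D <= M):
        raise ValueError(f"need 0 <= D <= M, got D={D}, M={M}")
    if d == 0:
        return 1.0
    j_lo = max(d, m - (M - D))
    j_hi = min(m, D)
    if j_lo > j_hi:
        return 0.0
    log_terms = [
        _log_binom(D, j) + _log_binom(M - D, m - j) for j in range(j_lo, j_hi + 1)
    ]
    log_p = logsumexp(log_terms) - _log_binom(M, m)
    return float(min(1.0, np.exp(log_p)))


class ClusterMatch(NamedTuple):
    """Per-cluster evaluation row."""

    cluster_index: int
    reference_name: str
    mms: int
    precision: float
    recall: float
    f_measure: float
    p_value: float


@dataclass(frozen=True)
class EvaluationReport:
    """Per-cluster matches plus size-weighted composite statistics."""

    per_cluster: tuple[ClusterMatch, ...]
    precision: float
    recall: float
    f_measure: float
    mean_p_value: float

    def to_dict(self) -> dict:
        return {
            "composite": {
                "precision": self.precision,
                "recall": self.recall,
                "f_measure": self.f_measure,
                "mean_p_value": self.mean_p_value,
            },
            "per_cluster": [row._asdict() for row in self.per_cluster],
        }


def _best_match(
    cluster: set[str], catalog: ReferenceCatalog
) -> tuple[str, frozenset[str], int]:
    """Reference module maximising MMS; ties to the larger module, then name."""
    best_key: tuple[int, int, str] | None = None
    best: tuple[str, frozenset[str], int] | None = None
    for name, members in catalog.modules:
        score = len(cluster & members)
        key = (-score, -len(members), name)
        if best_key is None or key < best_key:
            best_key = key
            best = (name, members, score)
    assert best is not None
    return best


def evaluate_clustering(
    clustering: Clustering,
    catalog: ReferenceCatalog,
    annotation: Optional[Mapping[str, str]] = None,
) -> EvaluationReport:
    """Match every cluster to the reference and aggregate the metrics.

    Without an ``annotation`` map the matched reference module itself
    plays the function class: the background ``M`` is the union of
    catalog and clustering proteins, ``D`` the matched module size,
    ``m`` the cluster size and ``d`` the matching score.  With a
    ``protein -> function-class`` map, ``M`` is the number of annotated
    proteins and ``D`` the size of the dominant function class of the
    matched module.
    """
    if clustering.c == 0:
        raise ValueError("clustering must contain at least one cluster")
    if any(not cl for cl in clustering.clusters):
        raise ValueError("clusters must be non-empty")

    if annotation is not None:
        background = set(annotation)
    else:
        background = set(catalog.all_proteins())
        for cl in clustering.clusters:
            background |= cl
    M = len(background)

    rows: list[ClusterMatch] = []
    for k, cluster in enumerate(clustering.clusters):
        name, members, score = _best_match(cluster, catalog)
        precision, recall, f = pair_metrics(cluster, members)
        if annotation is not None:
            classes = [annotation[p] for p in members if p in annotation]
            if classes:
                dominant = max(set(classes), key=lambda c: (classes.count(c), c))
                D = sum(1 for c in annotation.values() if c == dominant)
            else:
                D = 0
            m_eff = min(len(cluster), M)
            d_eff = min(score, m_eff)
        else:
            D = len(members)
            m_eff = len(cluster)
            d_eff = score
        rows.append(
            ClusterMatch(
                cluster_index=k,
                reference_name=name,
                mms=score,
                precision=precision,
                recall=recall,
                f_measure=f,
                p_value=p_value(M, D, m_eff, d_eff),
            )
        )

    weights = np.array([len(cl) for cl in clustering.clusters], dtype=float)
    precisions = np.array([r.precision for r in rows])
    recalls = np.array([r.recall for r in rows])
    comp_p = float(np.average(precisions, weights=weights))
    comp_r = float(np.average(recalls, weights=weights))
    comp_f = (
        0.0 if comp_p + comp_r == 0 else 2 * comp_p * comp_r / (comp_p + comp_r)
    )
    mean_pv = float(np.mean([r.p_value for r in rows]))
    return EvaluationReport(
        per_cluster=tuple(rows),
        precision=comp_p,
        recall=comp_r,
        f_measure=comp_f,
        mean_p_value=mean_pv,
    )
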