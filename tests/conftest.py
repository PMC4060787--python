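import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from abcifc.graph_model import Clustering, PPINetwork
from abcifc.synthetic_data import PlantedConfig, generate_planted_network

settings.register_profile(
    "default",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def two_triangles() -> PPINetwork:
    """Two disjoint unit-weight triangles: abc and def."""
    return PPINetwork.from_edges(
        [
            ("a", "b", 1.0),
            ("b", "c", 1.0),
            ("a", "c", 1.0),
            ("d", "e", 1.0),
            ("e", "f", 1.0),
            ("d", "f", 1.0),
        ]
    )


@pytest.fixture
def triangle_partition(two_triangles) -> Clustering:
    return Clustering(
        clusters=[{"a", "b", "c"}, {"d", "e", "f"}], centers=["a", "d"]
    )


@pytest.fixture
def planted() -> tuple:
    """Benchmark planted-module instance (3 x 10 nodes, seed 0)."""
    return generate_planted_network(PlantedConfig(seed=0))


def grid_scan_root(a, d2) -> float:
    """Two-stage dense grid scan for the root of Σ a_i/(e^{d_i²}+t) = 1.

    Independent of the secant solver: locates the sign change on a
    1e6-point grid over the whole domain, then rescans the bracketing
    step at the same density.
    """
    a = np.asarray(a, dtype=float)
    b = np.exp(np.asarray(d2, dtype=float))
    t_min = -float(np.min(b[a > 0.0]))
    hi = 1.0
    while np.sum(a / (b + hi)) > 1.0:
        hi *= 2.0

    def scan(lo: float, hi: float) -> tuple[float, float]:
        grid = np.linspace(lo, hi, 1_000_000)
        g = np.zeros_like(grid)
        for ai, bi in zip(a, b):
            g += ai / (bi + grid)
        idx = min(int(np.searchsorted(-(g - 1.0), 0.0)), grid.size - 1)
        return grid[max(idx - 1, 0)], grid[idx]

    eps = 1e-9 * (hi - t_min)
    lo1, hi1 = scan(t_min + eps, hi)
    _, root = scan(lo1, hi1)
    return float(root)


def random_network(seed: int, n: int = 20, p: float = 0.3) -> PPINetwork:
    """Small random weighted graph for property tests."""
    rng = np.random.default_rng(seed)
    nodes = [f"n{i:02d}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((nodes[i], nodes[j], float(rng.uniform(0.05, 3.0))))
    return PPINetwork.from_edges(edges, nodes=nodes)
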