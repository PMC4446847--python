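import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from simmod.multiplex import MultiplexNetwork, NetworkSlice, Partition

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

TRIANGLES = {
    ("a", "b"): 1.0,
    ("a", "c"): 1.0,
    ("b", "c"): 1.0,
    ("d", "e"): 1.0,
    ("d", "f"): 1.0,
    ("e", "f"): 1.0,
}


@pytest.fixture
def two_triangles():
    """Single slice: two disjoint unit-weight triangles."""
    return NetworkSlice("tri", frozenset("abcdef"), dict(TRIANGLES))


@pytest.fixture
def triangle_multiplex(two_triangles):
    """Two identical triangle slices: exact optimum is the two triangles, Q=0.5."""
    other = NetworkSlice("tri2", two_triangles.nodes, dict(two_triangles.edges))
    return MultiplexNetwork((two_triangles, other))


@pytest.fixture
def triangle_partition():
    return Partition({"a": 1, "b": 1, "c": 1, "d": 2, "e": 2, "f": 2})


def random_slice(rng: np.random.Generator, n: int, slice_id: str = "s",
                 p: float = 0.4) -> NetworkSlice:
    """Random weighted slice with ≥1 edge, weights uniform in (0, 1]."""
    nodes = [f"v{i:02d}" for i in range(n)]
    while True:
        edges = {}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    edges[(nodes[i], nodes[j])] = 1.0 - rng.random()
        if edges:
            return NetworkSlice(slice_id, frozenset(nodes), edges)


def random_multiplex(rng: np.random.Generator, n_lo: int = 6, n_hi: int = 8,
                     p: float = 0.4) -> MultiplexNetwork:
    """Small random multiplex: 6-8 shared nodes, 2-3 slices."""
    n = int(rng.integers(n_lo, n_hi + 1))
    n_slices = int(rng.integers(2, 4))
    return MultiplexNetwork(
        tuple(random_slice(rng, n, f"s{k}", p) for k in range(n_slices))
    )


def random_partition(rng: np.random.Generator, nodes, max_modules: int) -> Partition:
    labels = rng.integers(1, max_modules + 1, size=len(nodes))
    return Partition({v: int(m) for v, m in zip(sorted(nodes), labels)})
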