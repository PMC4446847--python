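"""Planted-partition multiplex generator.

Emulates the structure of real multi-interaction datasets — two or three
positive-weight slices over a partially overlapping node universe — with a
known ground-truth community structure, so that recovery can be measured
with normalized mutual information. Communities are equal-sized
(round-robin assignment); within each slice, node pairs present in the
slice are connected independently with probability ``p_in`` inside a
community and ``p_out`` between communities, and edges carry uniform
positive weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from simmod.errors import InputError, SimModError
from simmod.multiplex import MultiplexNetwork, NetworkSlice, Partition

_MAX_RESAMPLE = 10


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of a planted multiplex.

    Defaults describe the benchmark condition used throughout the test
    suite: 60 nodes in 4 equal communities observed in 2 slices with strong
    assortative signal (p_in 0.8 vs p_out 0.05), full coverage, and
    confidence-style weights uniform in (0.5, 1.0].
    """

    n_nodes: int = 60
    n_communities: int = 4
    n_slices: int = 2
    p_in: float = 0.8
    p_out: float = 0.05
    coverage: float = 1.0
    weight_low: float = 0.5
    weight_high: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2 or self.n_communities < 1 or self.n_slices < 1:
            raise InputError("need n_nodes ≥ 2, n_communities ≥ 1, n_slices ≥ 1")
        if self.n_nodes < 2 * self.n_communities:
            raise InputError("expected community size must be ≥ 2")
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise InputError("require 0 ≤ p_out ≤ p_in ≤ 1")
        if not (0.0 < self.coverage <= 1.0):
            raise InputError("coverage must be in (0, 1]")
        if not (0.0 < self.weight_low <= self.weight_high):
            raise InputError("require 0 < weight_low ≤ weight_high")


def generate(spec: PlantedSpec) -> tuple[MultiplexNetwork, Partition]:
    """Sample a multiplex and its ground-truth partition, deterministically.

    Node ``i`` belongs to community ``i mod n_communities``. Each slice
    contains a shared core (half of the per-slice quota, with every
    community represented) plus a per-slice random sample, so the planted
    structure stays detectable in every slice even at partial coverage.
    A slice that comes out edgeless is resampled up to 10 times.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    width = len(str(n - 1))
    nodes = [f"n{i:0{width}d}" for i in range(n)]
    community = np.arange(n) % spec.n_communities

    slice_size = max(spec.n_communities, int(round(spec.coverage * n)))
    core = _shared_core(rng, n, community, spec.n_communities, slice_size)

    slices = []
    for s in range(spec.n_slices):
        present = _slice_nodes(rng, n, core, slice_size)
        edges = None
        for _ in range(_MAX_RESAMPLE):
            edges = _sample_edges(rng, present, community, nodes, spec)
            if edges:
                break
        if not edges:
            raise SimModError(
                f"slice {s} came out edgeless after {_MAX_RESAMPLE} attempts; "
                "increase p_in/p_out or coverage"
            )
        slices.append(
            NetworkSlice(
                slice_id=f"slice{s + 1}",
                nodes=frozenset(nodes[i] for i in present),
                edges=edges,
            )
        )
    multiplex = MultiplexNetwork(slices=tuple(slices))
    truth = Partition(
        {nodes[i]: int(community[i]) + 1 for i in range(n) if nodes[i] in multiplex.universe}
    )
    return multiplex, truth


def _shared_core(rng, n: int, community: np.ndarray, n_comm: int, slice_size: int) -> list[int]:
    """Core present in every slice: one node per community plus random fill
    up to half the per-slice quota."""
    core_size = max(n_comm, math.ceil(slice_size / 2))
    core: list[int] = []
    for c in range(n_comm):
        members = np.flatnonzero(community == c)
        core.append(int(rng.choice(members)))
    rest = np.setdiff1d(np.arange(n), np.array(core))
    extra = core_size - len(core)
    if extra > 0:
        core.extend(int(i) for i in rng.choice(rest, size=min(extra, rest.size), replace=False))
    return sorted(core)


def _slice_nodes(rng, n: int, core: list[int], slice_size: int) -> list[int]:
    rest = np.setdiff1d(np.arange(n), np.array(core))
    extra = slice_size - len(core)
    chosen = set(core)
    if extra > 0 and rest.size:
        chosen |= {int(i) for i in rng.choice(rest, size=min(extra, rest.size), replace=False)}
    return sorted(chosen)


def _sample_edges(rng, present: list[int], community: np.ndarray, nodes: list[str], spec: PlantedSpec):
    idx = np.array(present)
    m = idx.size
    iu, ju = np.triu_indices(m, k=1)
    a, b = idx[iu], idx[ju]
    prob = np.where(community[a] == community[b], spec.p_in, spec.p_out)
    keep = rng.random(prob.size) < prob
    # open-at-low, closed-at-high uniform weights stay strictly positive
    weights = spec.weight_high - rng.random(int(keep.sum())) * (
        spec.weight_high - spec.weight_low
    )
    edges: dict[tuple[str, str], float] = {}
    for (i, j), w in zip(zip(a[keep], b[keep]), weights):
        u, v = nodes[int(i)], nodes[int(j)]
        edges[(u, v) if u <= v else (v, u)] = float(w)
    return edges
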