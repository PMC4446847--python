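"""Data model and I/O for network slices, multiplex networks and partitions.

A *slice* is one weighted undirected graph (one interaction type); a
*multiplex network* is an ordered collection of slices whose node universe is
the union of the slice node sets. A *partition* assigns every node of a
domain to exactly one module, with labels canonicalized to ``1..m``.

Edge weights are strictly positive confidences. Following the construction
used for interaction datasets, each slice is normalized by dividing all
weights by the slice's largest weight, and slices are aggregated into a
combined network whose edge weights are sums of the normalized per-slice
weights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from simmod.errors import InputError, SimModError

logger = logging.getLogger(__name__)

#: unordered node pair, stored as a sorted tuple
Pair = tuple[str, str]

_NORM_TOL = 1e-9


def _pair(u: str, v: str) -> Pair:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class NetworkSlice:
    """One interaction type: a weighted undirected graph with positive weights.

    Parameters
    ----------
    slice_id:
        Short label for the slice (e.g. ``"physical"``).
    nodes:
        Node identifiers (opaque, case-sensitive strings). May include
        isolated nodes.
    edges:
        Mapping from unordered node pair (sorted 2-tuple) to weight.
        Weights must be strictly positive; self-pairs are not allowed.
    """

    slice_id: str
    nodes: frozenset[str]
    edges: dict[Pair, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        canon: dict[Pair, float] = {}
        for (u, v), w in self.edges.items():
            if u == v:
                raise InputError(f"slice {self.slice_id!r}: self-pair on node {u!r}")
            if not (w > 0) or not math.isfinite(w):
                raise InputError(
                    f"slice {self.slice_id!r}: non-positive weight {w!r} on edge ({u}, {v})"
                )
            if u not in self.nodes or v not in self.nodes:
                raise InputError(
                    f"slice {self.slice_id!r}: edge ({u}, {v}) has endpoint outside node set"
                )
            canon[_pair(u, v)] = float(w)
        object.__setattr__(self, "edges", canon)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def total_weight(self) -> float:
        """Sum of all edge weights in the slice (the null-model denominator)."""
        return sum(self.edges.values())

    @property
    def max_weight(self) -> float:
        if not self.edges:
            raise SimModError(f"slice {self.slice_id!r} has no edges")
        return max(self.edges.values())

    def adjacency(self) -> dict[str, dict[str, float]]:
        """Node -> {neighbor: weight} map (isolated nodes map to {})."""
        adj: dict[str, dict[str, float]] = {v: {} for v in self.nodes}
        for (u, v), w in self.edges.items():
            adj[u][v] = w
            adj[v][u] = w
        return adj

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from((u, v, w) for (u, v), w in self.edges.items())
        return g


@dataclass(frozen=True)
class MultiplexNetwork:
    """Ordered collection of slices over the union of their node sets."""

    slices: tuple[NetworkSlice, ...]

    def __post_init__(self) -> None:
        slices = tuple(self.slices)
        if not slices:
            raise InputError("a multiplex network needs at least one slice")
        ids = [s.slice_id for s in slices]
        if len(set(ids)) != len(ids):
            raise InputError(f"duplicate slice ids: {ids}")
        object.__setattr__(self, "slices", slices)

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.slices:
            out |= s.nodes
        return frozenset(out)

    @property
    def n_slices(self) -> int:
        return len(self.slices)


@dataclass(frozen=True)
class Partition:
    """Disjoint assignment of every domain node to exactly one module.

    Labels are canonicalized to ``1..m`` in order of first appearance when
    the domain is traversed in sorted node order, so two partitions with the
    same grouping compare equal regardless of original labels.
    """

    assignment: dict[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", _canonicalize(self.assignment))

    @property
    def domain(self) -> frozenset[str]:
        return frozenset(self.assignment)

    @property
    def n_modules(self) -> int:
        return max(self.assignment.values(), default=0)

    @property
    def labels(self) -> tuple[int, ...]:
        """Sorted module labels, 1..m."""
        return tuple(range(1, self.n_modules + 1))

    def modules(self) -> dict[int, frozenset[str]]:
        out: dict[int, set[str]] = {}
        for node, label in self.assignment.items():
            out.setdefault(label, set()).add(node)
        return {k: frozenset(v) for k, v in sorted(out.items())}

    def members(self, label: int) -> frozenset[str]:
        if label not in set(self.assignment.values()):
            raise InputError(f"unknown module label {label!r}")
        return frozenset(n for n, m in self.assignment.items() if m == label)

    def restrict(self, nodes: Iterable[str]) -> "Partition":
        """Sub-partition on ``nodes`` ∩ domain, re-canonicalized."""
        keep = set(nodes) & set(self.assignment)
        return Partition({n: self.assignment[n] for n in keep})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.assignment == other.assignment

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.assignment.items())))


def _canonicalize(assignment: Mapping[str, int]) -> dict[str, int]:
    if not assignment:
        return {}
    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for node in sorted(assignment):
        old = assignment[node]
        if old not in relabel:
            relabel[old] = len(relabel) + 1
        out[node] = relabel[old]
    return out


# ---------------------------------------------------------------------------
# edge-list I/O
# ---------------------------------------------------------------------------

def read_slice(path: str | Path, slice_id: str | None = None) -> NetworkSlice:
    """Read a slice from a tab-separated edge list (node_a, node_b, weight).

    Lines starting with ``#`` are skipped; an optional header row is
    recognized when the third field of the first data line is the literal
    ``weight``. Duplicate pairs are merged keeping the maximum weight
    (weights are confidences, so the maximum is the conservative merge);
    self-pairs are dropped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"edge-list file not found: {path}")
    if slice_id is None:
        slice_id = path.stem
    nodes: set[str] = set()
    edges: dict[Pair, float] = {}
    first_data = True
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: expected ≥3 tab-separated columns")
            a, b, wtext = fields[0].strip(), fields[1].strip(), fields[2].strip()
            if first_data:
                first_data = False
                if wtext.lower() == "weight":
                    continue  # header row
            try:
                w = float(wtext)
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-numeric weight {wtext!r}") from None
            if not (w > 0) or not math.isfinite(w):
                raise InputError(f"{path}:{lineno}: weight must be a positive real, got {wtext!r}")
            if a == b:
                logger.warning("%s:%d: dropping self-pair on node %r", path, lineno, a)
                nodes.add(a)
                continue
            nodes.update((a, b))
            key = _pair(a, b)
            if key in edges:
                edges[key] = max(edges[key], w)
            else:
                edges[key] = w
    return NetworkSlice(slice_id=slice_id, nodes=frozenset(nodes), edges=edges)


def write_slice(slc: NetworkSlice, path: str | Path) -> None:
    """Write a slice as a tab-separated edge list with a header row.

    Isolated nodes have no row in an edge list and are not preserved.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for (u, v), w in sorted(slc.edges.items()):
            fh.write(f"{u}\t{v}\t{w!r}\n")


# ---------------------------------------------------------------------------
# normalization, aggregation, component extraction
# ---------------------------------------------------------------------------

def normalize_weights(slc: NetworkSlice) -> NetworkSlice:
    """Divide every weight by the slice's largest weight (max becomes 1.0).

    Idempotent and scale-invariant; raises on an edgeless slice, where no
    maximum exists.
    """
    if not slc.edges:
        raise SimModError(f"cannot normalize edgeless slice {slc.slice_id!r}")
    wmax = slc.max_weight
    return NetworkSlice(
        slice_id=slc.slice_id,
        nodes=slc.nodes,
        edges={pair: w / wmax for pair, w in slc.edges.items()},
    )


def aggregate(multiplex: MultiplexNetwork, slice_id: str = "combined") -> NetworkSlice:
    """Combine all slices into one network by summing normalized weights.

    Every slice must already be normalized (max weight 1 within 1e-9); the
    combined node set is the universe and each edge's weight is the sum of
    that pair's weights over the slices containing it.
    """
    for s in multiplex.slices:
        if abs(s.max_weight - 1.0) > _NORM_TOL:
            raise SimModError(
                f"slice {s.slice_id!r} is not normalized (max weight {s.max_weight}); "
                "call normalize_weights first to avoid mixing scales"
            )
    combined: dict[Pair, float] = {}
    for s in multiplex.slices:
        for pair, w in s.edges.items():
            combined[pair] = combined.get(pair, 0.0) + w
    return NetworkSlice(slice_id=slice_id, nodes=multiplex.universe, edges=combined)


def main_component(slc: NetworkSlice) -> NetworkSlice:
    """Induced subgraph on the largest connected component.

    Size ties are broken by the component containing the lexicographically
    smallest node, so the result is deterministic and input-order
    independent. Isolated nodes count as singleton components.
    """
    if not slc.nodes:
        raise SimModError(f"slice {slc.slice_id!r} is empty")
    comps = [set(c) for c in nx.connected_components(slc.to_networkx())]
    biggest = max(len(c) for c in comps)
    best = min((c for c in comps if len(c) == biggest), key=min)
    edges = {pair: w for pair, w in slc.edges.items() if pair[0] in best}
    return NetworkSlice(slice_id=slc.slice_id, nodes=frozenset(best), edges=edges)


# ---------------------------------------------------------------------------
# partition I/O
# ---------------------------------------------------------------------------

def read_partition(path: str | Path) -> Partition:
    """Read a partition from a tab-separated (node, module) file.

    An optional ``node<TAB>module`` header is recognized. A node listed
    twice with different modules violates disjointness and is an error.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"partition file not found: {path}")
    assignment: dict[str, int] = {}
    first_data = True
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise InputError(f"{path}:{lineno}: expected ≥2 tab-separated columns")
            node, mtext = fields[0].strip(), fields[1].strip()
            if first_data:
                first_data = False
                if mtext.lower() == "module":
                    continue
            try:
                label = int(mtext)
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-integer module label {mtext!r}") from None
            if node in assignment and assignment[node] != label:
                raise InputError(
                    f"{path}:{lineno}: node {node!r} assigned to two modules "
                    f"({assignment[node]} and {label})"
                )
            assignment[node] = label
    return Partition(assignment)


def write_partition(partition: Partition, path: str | Path) -> None:
    """Write a partition as a tab-separated (node, module) file with header."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("node\tmodule\n")
        for node in sorted(partition.assignment):
            fh.write(f"{node}\t{partition.assignment[node]}\n")
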