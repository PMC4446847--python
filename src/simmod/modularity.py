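"""Per-slice modularity and the shared-partition average-modularity objective.

For a slice ``s`` with total edge weight ``W_s`` and a partition into modules
``m``, modularity is

    Q_s = sum_m [ l_{m,s} / W_s  -  ( d_{m,s} / (2 W_s) )^2 ]

where ``l_{m,s}`` is the sum of weights of edges with both endpoints in
module ``m`` and ``d_{m,s}`` is the sum of the strengths (weighted degrees)
of the module's members in slice ``s``. The objective optimized over a
multiplex is the arithmetic mean of ``Q_s`` over its slices, evaluated on a
single partition of the node universe.

Nodes absent from a slice are treated as present with strength 0 and no
incident edges: they change no ``Q_s``, and they make one shared partition
over the universe well-defined in every slice.
"""

from __future__ import annotations

from dataclasses import dataclass

from simmod.errors import InputError, SimModError
from simmod.multiplex import MultiplexNetwork, NetworkSlice, Partition


@dataclass(frozen=True)
class ModuleSliceStats:
    """Modularity bookkeeping for one (module, slice) pair.

    ``intra_weight`` — total weight of edges with both endpoints in the
    module; ``total_degree`` — sum of member strengths in the slice;
    ``slice_total_weight`` — sum of all edge weights in the slice.
    """

    intra_weight: float
    total_degree: float
    slice_total_weight: float


def node_strength(slc: NetworkSlice, node: str) -> float:
    """Sum of weights of edges incident to ``node`` in the slice.

    Returns 0 for isolated nodes and for nodes absent from the slice.
    """
    if node not in slc.nodes:
        return 0.0
    total = 0.0
    for (u, v), w in slc.edges.items():
        if u == node or v == node:
            total += w
    return total


def module_stats(slc: NetworkSlice, partition: Partition, module: int) -> ModuleSliceStats:
    """Intra-module weight and total degree of one module in one slice.

    Requires the partition domain to cover the slice's nodes; module members
    absent from the slice contribute 0 to both statistics.
    """
    missing = slc.nodes - partition.domain
    if missing:
        raise InputError(
            f"partition does not cover slice {slc.slice_id!r} "
            f"(missing e.g. {sorted(missing)[:3]})"
        )
    if module not in set(partition.assignment.values()):
        raise InputError(f"unknown module label {module!r}")
    assign = partition.assignment
    intra = 0.0
    degree = 0.0
    for (u, v), w in slc.edges.items():
        in_u = assign[u] == module
        in_v = assign[v] == module
        if in_u and in_v:
            intra += w
        if in_u:
            degree += w
        if in_v:
            degree += w
    return ModuleSliceStats(
        intra_weight=intra, total_degree=degree, slice_total_weight=slc.total_weight
    )


def slice_modularity(slc: NetworkSlice, partition: Partition) -> float:
    """Modularity of one slice under the given partition.

    Exactly ``sum_m [ l_m/W - (d_m/2W)^2 ]``; lies in [-1, 1). A slice with
    no edges has W = 0 and no defined modularity.
    """
    if not slc.edges:
        raise SimModError(f"slice {slc.slice_id!r} has no edges; modularity undefined")
    missing = slc.nodes - partition.domain
    if missing:
        raise InputError(
            f"partition does not cover slice {slc.slice_id!r} "
            f"(missing e.g. {sorted(missing)[:3]})"
        )
    assign = partition.assignment
    total = slc.total_weight
    intra: dict[int, float] = {}
    degree: dict[int, float] = {}
    for (u, v), w in slc.edges.items():
        mu, mv = assign[u], assign[v]
        if mu == mv:
            intra[mu] = intra.get(mu, 0.0) + w
        degree[mu] = degree.get(mu, 0.0) + w
        degree[mv] = degree.get(mv, 0.0) + w
    q = 0.0
    for m, d in degree.items():
        q += intra.get(m, 0.0) / total - (d / (2.0 * total)) ** 2
    return q


def average_modularity(multiplex: MultiplexNetwork, partition: Partition) -> float:
    """Arithmetic mean of per-slice modularities under one shared partition.

    Every universe node must be allocated to a module; every slice must have
    at least one edge.
    """
    missing = multiplex.universe - partition.domain
    if missing:
        raise InputError(
            f"partition is missing {len(missing)} universe node(s), "
            f"e.g. {sorted(missing)[:3]}; every node must be allocated"
        )
    qs = [slice_modularity(s, partition) for s in multiplex.slices]
    return sum(qs) / len(qs)
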