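"""Maximization of average modularity over a single shared partition.

Two solvers share one objective:

``solve_exact``
    Exhaustive enumeration of all set partitions of the universe (guarded at
    12 nodes — Bell numbers explode past that). Serves as the exactness
    oracle for small instances.

``solve_heuristic``
    Multi-restart local search. Each restart draws a uniform random
    assignment of the universe into ``max_modules`` labels, then repeats
    sweeps of (i) best single-node relocations to any label within the bound
    and (ii) greedy all-pairs module merges, accepting only strict
    improvements (> 1e-9), until a full sweep changes nothing. The best
    restart wins; ties go to the lexicographically smallest canonical
    assignment. Deterministic given the seed: restart ``r`` uses an
    independent generator seeded with ``(seed + r) mod 2**31``.

Empty module labels are allowed during the search — the number of modules in
the returned partition is decided by the objective, not by the bound — and
are removed by canonicalization on output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from simmod.errors import InputError, SimModError
from simmod.modularity import average_modularity
from simmod.multiplex import MultiplexNetwork, Partition

_EXACT_GUARD = 12
_IMPROVE_TOL = 1e-9


@dataclass(frozen=True)
class SolveResult:
    """Outcome of one optimization run.

    ``objective`` is recomputed from scratch on the returned canonical
    partition, so it always equals ``average_modularity(multiplex,
    partition)``.
    """

    partition: Partition
    objective: float
    restarts_run: int
    best_restart_index: int
    seed: int


class _SliceData:
    """Flat per-slice arrays over a fixed node indexing (absent nodes: strength 0)."""

    __slots__ = ("W", "strength", "adj", "edges")

    def __init__(self, slc, index: dict[str, int]):
        n = len(index)
        self.W = slc.total_weight
        self.strength = np.zeros(n)
        self.adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        self.edges: list[tuple[int, int, float]] = []
        for (u, v), w in sorted(slc.edges.items()):
            i, j = index[u], index[v]
            self.strength[i] += w
            self.strength[j] += w
            self.adj[i].append((j, w))
            self.adj[j].append((i, w))
            self.edges.append((i, j, w))


class _State:
    """Mutable search state: labels in 0..M-1 plus per-slice (l, d) arrays."""

    def __init__(self, slices: list[_SliceData], labels: np.ndarray, max_modules: int):
        self.slices = slices
        self.labels = labels
        self.M = max_modules
        S = len(slices)
        self.l = np.zeros((S, max_modules))
        self.d = np.zeros((S, max_modules))
        for s, sd in enumerate(slices):
            np.add.at(self.d[s], labels, sd.strength)
            for i, j, w in sd.edges:
                if labels[i] == labels[j]:
                    self.l[s, labels[i]] += w

    def objective(self) -> float:
        total = 0.0
        for s, sd in enumerate(self.slices):
            total += self.l[s].sum() / sd.W - float(((self.d[s] / (2.0 * sd.W)) ** 2).sum())
        return total / len(self.slices)

    def relocation_pass(self) -> bool:
        """Best-target relocation of each node in index order; immediate accept."""
        improved = False
        n = len(self.labels)
        S = len(self.slices)
        for v in range(n):
            a = int(self.labels[v])
            delta = np.zeros(self.M)
            wts = []
            for s, sd in enumerate(self.slices):
                wt = np.zeros(self.M)
                for j, w in sd.adj[v]:
                    wt[self.labels[j]] += w
                wts.append(wt)
                k = sd.strength[v]
                if k == 0.0 and not wt.any():
                    continue
                d = self.d[s]
                ds = (wt - wt[a]) / sd.W - (2.0 * k * (d - d[a]) + 2.0 * k * k) / (
                    4.0 * sd.W * sd.W
                )
                ds[a] = 0.0
                delta += ds
            delta /= S
            b = int(np.argmax(delta))  # ties -> smallest label
            if b != a and delta[b] > _IMPROVE_TOL:
                for s, sd in enumerate(self.slices):
                    k = sd.strength[v]
                    self.d[s, a] -= k
                    self.d[s, b] += k
                    self.l[s, a] -= wts[s][a]
                    self.l[s, b] += wts[s][b]
                self.labels[v] = b
                improved = True
        return improved

    def merge_pass(self) -> bool:
        """Greedy best-pair module merges until none improves."""
        improved = False
        S = len(self.slices)
        while True:
            counts = np.bincount(self.labels, minlength=self.M)
            used = np.flatnonzero(counts > 0)
            if used.size < 2:
                return improved
            cross = np.zeros((S, self.M, self.M))
            for s, sd in enumerate(self.slices):
                for i, j, w in sd.edges:
                    a, b = self.labels[i], self.labels[j]
                    if a != b:
                        cross[s, a, b] += w
                        cross[s, b, a] += w
            delta = np.zeros((self.M, self.M))
            for s, sd in enumerate(self.slices):
                delta += cross[s] / sd.W - (2.0 * np.outer(self.d[s], self.d[s])) / (
                    4.0 * sd.W * sd.W
                )
            delta /= S
            mask = np.full((self.M, self.M), -np.inf)
            iu = np.ix_(used, used)
            mask[iu] = delta[iu]
            np.fill_diagonal(mask, -np.inf)
            flat = int(np.argmax(mask))
            a, b = divmod(flat, self.M)
            if mask[a, b] <= _IMPROVE_TOL:
                return improved
            a, b = min(a, b), max(a, b)  # keep the smaller label
            self.labels[self.labels == b] = a
            self.l[:, a] += self.l[:, b] + cross[:, a, b]
            self.l[:, b] = 0.0
            self.d[:, a] += self.d[:, b]
            self.d[:, b] = 0.0
            improved = True

    def sweep(self) -> bool:
        r = self.relocation_pass()
        m = self.merge_pass()
        return r or m

    def run(self) -> None:
        while self.sweep():
            pass


def _prepare(multiplex: MultiplexNetwork) -> tuple[list[str], list[_SliceData]]:
    nodes = sorted(multiplex.universe)
    index = {v: i for i, v in enumerate(nodes)}
    for s in multiplex.slices:
        if not s.edges:
            raise SimModError(f"slice {s.slice_id!r} has no edges; objective undefined")
    return nodes, [_SliceData(s, index) for s in multiplex.slices]


def _to_partition(nodes: list[str], labels: np.ndarray) -> Partition:
    return Partition({v: int(labels[i]) + 1 for i, v in enumerate(nodes)})


def default_max_modules(n_nodes: int) -> int:
    """Module-count bound used when none is supplied: ceil(sqrt(n))."""
    return max(1, math.ceil(math.sqrt(n_nodes)))


def solve_exact(multiplex: MultiplexNetwork) -> SolveResult:
    """Enumerate every set partition of the universe; return a maximizer.

    Partitions are enumerated as restricted-growth strings in lexicographic
    order, which is also canonical label order, so ties resolve to the
    lexicographically smallest canonical assignment. Guarded at 12 nodes.
    """
    nodes, slices = _prepare(multiplex)
    n = len(nodes)
    if n > _EXACT_GUARD:
        raise SimModError(
            f"solve_exact enumerates all set partitions and is limited to "
            f"{_EXACT_GUARD} nodes (got {n}); use solve_heuristic"
        )
    Ws = [sd.W for sd in slices]
    best_obj = -math.inf
    best_labels: np.ndarray | None = None
    labels = np.zeros(n, dtype=np.int64)

    def evaluate() -> float:
        total = 0.0
        for sd, W in zip(slices, Ws):
            intra = 0.0
            for i, j, w in sd.edges:
                if labels[i] == labels[j]:
                    intra += w
            deg = np.zeros(n)
            np.add.at(deg, labels, sd.strength)
            total += intra / W - float(((deg / (2.0 * W)) ** 2).sum())
        return total / len(slices)

    def recurse(pos: int, n_used: int) -> None:
        nonlocal best_obj, best_labels
        if pos == n:
            obj = evaluate()
            if obj > best_obj:
                best_obj = obj
                best_labels = labels.copy()
            return
        for lab in range(n_used + 1):
            labels[pos] = lab
            recurse(pos + 1, max(n_used, lab + 1))

    recurse(0, 0)
    assert best_labels is not None
    partition = _to_partition(nodes, best_labels)
    return SolveResult(
        partition=partition,
        objective=average_modularity(multiplex, partition),
        restarts_run=1,
        best_restart_index=0,
        seed=0,
    )


def local_search_step(
    multiplex: MultiplexNetwork, partition: Partition, max_modules: int
) -> tuple[Partition, bool]:
    """Apply one full sweep (relocations then merges) to ``partition``.

    Returns the updated partition and whether any strict improvement was
    made. Exposed for testing the search against the exact oracle.
    """
    nodes, slices = _prepare(multiplex)
    missing = multiplex.universe - partition.domain
    if missing:
        raise InputError(f"partition is missing universe nodes, e.g. {sorted(missing)[:3]}")
    if max_modules < partition.n_modules:
        raise InputError(
            f"max_modules={max_modules} is below the partition's module count "
            f"({partition.n_modules})"
        )
    labels = np.array([partition.assignment[v] - 1 for v in nodes], dtype=np.int64)
    state = _State(slices, labels, max_modules)
    improved = state.sweep()
    return _to_partition(nodes, state.labels), improved


def solve_heuristic(
    multiplex: MultiplexNetwork,
    max_modules: int | None = None,
    restarts: int = 100,
    seed: int = 0,
) -> SolveResult:
    """Multi-restart relocation+merge local search on average modularity.

    Parameters
    ----------
    max_modules:
        Upper bound on the number of module labels available during the
        search (the returned partition may use fewer). Defaults to
        ``ceil(sqrt(|universe|))``.
    restarts:
        Number of independent random initializations (default 100).
    seed:
        Root seed; restart ``r`` uses ``(seed + r) mod 2**31``.
    """
    if restarts < 1:
        raise InputError(f"restarts must be ≥ 1, got {restarts}")
    nodes, slices = _prepare(multiplex)
    n = len(nodes)
    if max_modules is None:
        max_modules = default_max_modules(n)
    if max_modules < 1:
        raise InputError(f"max_modules must be ≥ 1, got {max_modules}")
    best_obj = -math.inf
    best_key: tuple[int, ...] | None = None
    best_partition: Partition | None = None
    best_index = -1
    for r in range(restarts):
        rng = np.random.default_rng((seed + r) % 2**31)
        labels = rng.integers(0, max_modules, size=n)
        state = _State(slices, labels.astype(np.int64), max_modules)
        state.run()
        partition = _to_partition(nodes, state.labels)
        obj = average_modularity(multiplex, partition)
        key = tuple(partition.assignment[v] for v in nodes)
        if (
            obj > best_obj + _IMPROVE_TOL
            or (abs(obj - best_obj) <= _IMPROVE_TOL and best_key is not None and key < best_key)
        ):
            best_obj, best_key, best_partition, best_index = obj, key, partition, r
    assert best_partition is not None
    return SolveResult(
        partition=best_partition,
        objective=average_modularity(multiplex, best_partition),
        restarts_run=restarts,
        best_restart_index=best_index,
        seed=seed,
    )
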