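"""Normalized mutual information between two partitions.

Uses the confusion-matrix normalization of Danon et al.: with joint counts
``n_ij`` over the ``n`` nodes common to both partitions and marginals
``n_i``, ``n_j``,

    NMI = -2 * sum_ij n_ij ln(n_ij n / (n_i n_j))
          / ( sum_i n_i ln(n_i / n) + sum_j n_j ln(n_j / n) )

which is 0 for independent community structures and 1 for identical ones.
When the two partitions cover different node sets, only the common nodes
enter the calculation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from simmod.errors import InputError
from simmod.multiplex import Partition


@dataclass(frozen=True)
class ConfusionTable:
    """Joint module-membership counts of two partitions over common nodes."""

    counts: np.ndarray  # (modules of p1) x (modules of p2), integer node counts

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def confusion_table(p1: Partition, p2: Partition) -> ConfusionTable:
    """Joint counts of (module in p1, module in p2) over the common nodes."""
    common = sorted(p1.domain & p2.domain)
    if len(common) < 2:
        raise InputError(
            f"partitions share only {len(common)} node(s); need at least 2 for comparison"
        )
    r1 = p1.restrict(common)
    r2 = p2.restrict(common)
    counts = np.zeros((r1.n_modules, r2.n_modules), dtype=np.int64)
    for node in common:
        counts[r1.assignment[node] - 1, r2.assignment[node] - 1] += 1
    return ConfusionTable(counts=counts)


def nmi(p1: Partition, p2: Partition) -> float:
    """Normalized mutual information in [0, 1]; 1 means identical grouping.

    Degenerate cases: if both partitions place all common nodes in a single
    module the structures are identical and the value is 1; if exactly one
    does, no information is shared and the value is 0.
    """
    # order the arguments canonically so the float summation is identical
    # either way round and symmetry holds exactly
    common = sorted(p1.domain & p2.domain)
    k1 = tuple(p1.restrict(common).assignment[v] for v in common)
    k2 = tuple(p2.restrict(common).assignment[v] for v in common)
    if k2 < k1:
        p1, p2 = p2, p1
    table = confusion_table(p1, p2)
    counts = table.counts
    n = table.n
    ni = table.row_marginals
    nj = table.col_marginals
    num = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            c = counts[i, j]
            if c > 0:
                num += c * math.log(c * n / (ni[i] * nj[j]))
    num *= -2.0
    den = float(np.sum(ni * np.log(ni / n)) + np.sum(nj * np.log(nj / n)))
    if den == 0.0:  # both single-module
        return 1.0
    value = num / den
    # clamp floating-point spill just outside [0, 1]
    return min(1.0, max(0.0, value))
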