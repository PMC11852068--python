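"""Independent brute-force oracles for the graph metrics.

Everything here is deliberately naive and independent of the package's
implementation: exact rational hypergeometric sums for Surprise, the literal
pairwise double sum for modularity, and exhaustive enumeration over all set
partitions for the detectors.  Only usable for small graphs (n <= 8 or so).
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def set_partitions(items: list[int]):
    """All partitions of ``items`` (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1 :]
        yield [[first]] + smaller


def partition_to_labels(blocks: list[list[int]], n: int) -> np.ndarray:
    labels = np.empty(n, dtype=int)
    for cid, block in enumerate(blocks):
        for node in block:
            labels[node] = cid
    return labels


def exact_surprise(adj: np.ndarray, labels: np.ndarray) -> float:
    """S = -log10 of the exact hypergeometric tail, via integer arithmetic."""
    n = adj.shape[0]
    M = n * (n - 1) // 2
    m = int(adj.sum()) // 2
    if m == 0:
        return 0.0
    m_int = 0
    M_int = 0
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j]:
                M_int += 1
                if adj[i, j]:
                    m_int += 1
    tail = Fraction(0)
    denom = math.comb(M, m)
    for j in range(m_int, min(m, M_int) + 1):
        tail += Fraction(math.comb(M_int, j) * math.comb(M - M_int, m - j), denom)
    if tail >= 1:
        return 0.0
    return -math.log10(float(tail)) if tail > 0 else math.inf


def modularity_double_sum(adj: np.ndarray, labels: np.ndarray) -> float:
    """Literal pairwise definition: (1/2m) sum_ij [A_ij - k_i k_j / 2m] delta."""
    m = int(adj.sum()) // 2
    if m == 0:
        return 0.0
    deg = adj.sum(axis=1)
    n = adj.shape[0]
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += adj[i, j] - deg[i] * deg[j] / (2.0 * m)
    return q / (2.0 * m)


def best_partition(adj: np.ndarray, objective) -> tuple[float, np.ndarray]:
    """Exhaustive maximum of ``objective(adj, labels)`` over all partitions."""
    n = adj.shape[0]
    best_val = -math.inf
    best_labels = None
    for blocks in set_partitions(list(range(n))):
        labels = partition_to_labels(blocks, n)
        val = objective(adj, labels)
        if val > best_val:
            best_val = val
            best_labels = labels
    return best_val, best_labels


def random_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Erdos-Renyi adjacency matrix, symmetric uint8, zero diagonal."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    return (adj | adj.T).astype(np.uint8)
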