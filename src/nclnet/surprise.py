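"""Threshold selection by Surprise maximization with percolation diagnostics.

Weighted coherence matrices are sparsified over a grid of 100 thresholds on
(0, 1) (interior points ``i / 101``).  At each threshold every
(trial, window) matrix is binarized (strict ``weight > tau``), its community
structure is found by greedy Surprise maximization, and the S-value of the
detected partition is recorded; the per-band optimal threshold is the grid
point with maximum mean S over all matrices of all subjects, ties broken
toward the smallest threshold.  The largest-connected-component fraction is
tracked alongside as a percolation diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from . import _community
from .coherence import CoherenceTensor
from .errors import DataError, ParameterError

log = logging.getLogger(__name__)

__all__ = [
    "BinaryGraph",
    "Partition",
    "ThresholdSweep",
    "binarize",
    "surprise_of_partition",
    "detect_communities_surprise",
    "percolation_profile",
    "select_optimal_threshold",
    "threshold_grid",
]

DEFAULT_GRID_SIZE = 100


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected simple graph as a symmetric hollow 0/1 adjacency matrix."""

    adjacency: np.ndarray  # n x n, uint8, zero diagonal

    def __post_init__(self) -> None:
        adj = self.adjacency
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise DataError("adjacency must be square")
        if (adj != adj.T).any():
            raise DataError("adjacency must be symmetric")
        if np.diag(adj).any():
            raise DataError("adjacency must have a zero diagonal")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def m(self) -> int:
        """Edge count."""
        return int(self.adjacency.sum()) // 2

    @property
    def total_pairs(self) -> int:
        """M = n(n-1)/2, the number of node pairs."""
        return self.n * (self.n - 1) // 2


@dataclass(frozen=True)
class Partition:
    """Node community labels, contiguous ids starting at 0."""

    labels: tuple[int, ...]

    @property
    def n_communities(self) -> int:
        return len(set(self.labels))

    @staticmethod
    def from_labels(raw: np.ndarray) -> "Partition":
        """Relabel arbitrary ids to contiguous 0..k-1 in order of first appearance."""
        mapping: dict[int, int] = {}
        out = []
        for v in np.asarray(raw).tolist():
            if v not in mapping:
                mapping[v] = len(mapping)
            out.append(mapping[v])
        return Partition(labels=tuple(out))


@dataclass
class ThresholdSweep:
    """Result of the 100-tier sweep for one band."""

    thresholds: np.ndarray
    mean_surprise: np.ndarray
    lcc_fraction: np.ndarray
    optimal: float

    @property
    def optimal_index(self) -> int:
        return int(np.argmax(self.mean_surprise))


def threshold_grid(grid_size: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    """``grid_size`` evenly spaced interior thresholds ``i / (grid_size + 1)``."""
    return np.arange(1, grid_size + 1) / (grid_size + 1)


def binarize(weights: np.ndarray, tau: float) -> BinaryGraph:
    """Keep edges with weight strictly above ``tau``; discard the diagonal."""
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise DataError("weights must be a square matrix")
    if np.abs(w - w.T).max(initial=0.0) > 1e-9:
        raise DataError("weights must be symmetric (tolerance 1e-9)")
    if not 0.0 <= tau <= 1.0:
        raise ParameterError(f"tau must lie in [0, 1], got {tau}")
    adj = (w > tau).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    adj = np.minimum(adj, adj.T)  # exact symmetry even with asymmetry below tolerance
    return BinaryGraph(adjacency=adj)


def _lgf(M: int) -> np.ndarray:
    """Table of log-factorials, lgf[i] = lgamma(i + 1), i = 0..M."""
    return gammaln(np.arange(M + 1) + 1.0)


def surprise_of_partition(graph: BinaryGraph, partition: Partition) -> float:
    """Hypergeometric Surprise of a partition, in -log10 units (>= 0).

    With M node pairs, m edges, M_int intra-community pairs and m_int
    intra-community edges, S is the negative log10 of the probability that a
    uniformly random placement of m edges yields at least m_int
    intra-community edges.
    """
    labels = np.asarray(partition.labels)
    if labels.size != graph.n:
        raise ParameterError(
            f"partition covers {labels.size} nodes but graph has {graph.n}"
        )
    m = graph.m
    if m == 0:
        log.info("surprise of an empty graph is 0 by convention")
        return 0.0
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(graph.n, k=1)
    m_int = int(graph.adjacency[iu][same[iu]].sum())
    M_int = int(same[iu].sum())
    lgf = _lgf(graph.total_pairs)
    return float(
        _community._surprise_value(lgf, graph.total_pairs, m, M_int, m_int)
    )


def detect_communities_surprise(graph: BinaryGraph, seed: int = 0) -> Partition:
    """Greedy agglomerative Surprise maximization (merges + single-node relabels)."""
    lgf = _lgf(graph.total_pairs)
    labels, _ = _community.surprise_greedy(
        np.ascontiguousarray(graph.adjacency, dtype=np.uint8), seed, lgf
    )
    return Partition.from_labels(labels)


def percolation_profile(weights: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Largest-connected-component fraction after binarizing at each threshold."""
    taus = np.asarray(thresholds, dtype=float)
    if taus.size > 1 and (np.diff(taus) < 0).any():
        raise ParameterError("thresholds must be sorted ascending")
    out = np.empty(taus.size)
    for i, tau in enumerate(taus):
        graph = binarize(weights, tau)
        out[i] = _community.lcc_fraction(
            np.ascontiguousarray(graph.adjacency, dtype=np.uint8)
        )
    return out


def select_optimal_threshold(
    tensors: list[CoherenceTensor],
    grid_size: int = DEFAULT_GRID_SIZE,
    seed: int = 0,
) -> ThresholdSweep:
    """Per-band optimal threshold: argmax of mean Surprise over all matrices.

    All tensors must share the band; every (trial, window) matrix of every
    subject contributes one S-value per threshold.  Ties at the maximum mean
    S resolve to the smallest threshold (first argmax).
    """
    if not tensors:
        raise ParameterError("select_optimal_threshold needs at least one tensor")
    band = tensors[0].band
    for t in tensors[1:]:
        if t.band.name != band.name:
            raise ParameterError(
                f"all tensors must share one band; got {band.name!r} and {t.band.name!r}"
            )
    mats = np.concatenate(
        [t.values.reshape(-1, t.n_channels, t.n_channels) for t in tensors], axis=0
    )
    if mats.shape[0] == 0:
        raise ParameterError("tensors contain no windows")
    n = mats.shape[1]
    taus = threshold_grid(grid_size)
    lgf = _lgf(n * (n - 1) // 2)
    s_sums, lcc_sums = _community.surprise_sweep(
        np.ascontiguousarray(mats), taus, seed, lgf
    )
    mean_s = s_sums / mats.shape[0]
    mean_lcc = lcc_sums / mats.shape[0]
    optimal = float(taus[int(np.argmax(mean_s))])
    log.info(
        "band %s: optimal threshold %.4f (mean S %.3f over %d matrices)",
        band.name,
        optimal,
        mean_s.max(),
        mats.shape[0],
    )
    return ThresholdSweep(
        thresholds=taus,
        mean_surprise=mean_s,
        lcc_fraction=mean_lcc,
        optimal=optimal,
    )
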