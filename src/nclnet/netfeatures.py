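"""Graph features of the binarized coherence networks.

Two features summarize each (trial, window) network: the average node degree

    k_bar = (1/N) sum_i k_i = 2m / N,

a proxy for overall functional-connectivity density, and the Newman
modularity of a modularity-maximizing partition

    Q = (1/2m) sum_ij [A_ij - k_i k_j / (2m)] delta(c_i, c_j),

which quantifies how cleanly the network splits into modules.  Features are
computed on graphs binarized at the band's optimal threshold; isolated nodes
stay in the graph (N is fixed at the channel count).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from . import _community
from .coherence import CoherenceTensor
from .errors import ParameterError
from .surprise import BinaryGraph, Partition, binarize

log = logging.getLogger(__name__)

__all__ = [
    "node_degrees",
    "average_node_degree",
    "detect_communities_modularity",
    "modularity",
    "features_per_window",
    "FEATURE_COLUMNS",
]

#: Schema of the tidy per-window feature table.
FEATURE_COLUMNS = ["subject_id", "band", "trial", "window", "condition", "k_bar", "Q"]


def node_degrees(graph: BinaryGraph) -> np.ndarray:
    """Degree of each node (row sums of the adjacency matrix)."""
    return graph.adjacency.sum(axis=1).astype(int)


def average_node_degree(graph: BinaryGraph) -> float:
    """k_bar = 2m / N."""
    return 2.0 * graph.m / graph.n


def detect_communities_modularity(graph: BinaryGraph, seed: int = 0) -> Partition:
    """Greedy agglomerative modularity maximization (merges + relabels).

    An edgeless graph has no meaningful partition; all singletons are
    returned with a warning.
    """
    if graph.m == 0:
        warnings.warn("empty graph: returning the all-singleton partition", stacklevel=2)
        return Partition(labels=tuple(range(graph.n)))
    labels, _ = _community.modularity_greedy(
        np.ascontiguousarray(graph.adjacency, dtype=np.uint8), seed
    )
    return Partition.from_labels(labels)


def modularity(graph: BinaryGraph, partition: Partition) -> float:
    """Newman modularity Q of a partition, via the community-sum identity.

    Q = sum_c [e_c / m - (d_c / 2m)^2] with e_c the intra-community edge
    count and d_c the community degree sum; equal to the pairwise double
    sum over the adjacency matrix.  Q = 0 by convention for an edgeless
    graph.
    """
    labels = np.asarray(partition.labels)
    if labels.size != graph.n:
        raise ParameterError(
            f"partition covers {labels.size} nodes but graph has {graph.n}"
        )
    m = graph.m
    if m == 0:
        log.info("modularity of an empty graph is 0 by convention")
        return 0.0
    deg = node_degrees(graph)
    q = 0.0
    for c in set(labels.tolist()):
        members = labels == c
        e_c = graph.adjacency[np.ix_(members, members)].sum() / 2
        d_c = deg[members].sum()
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return float(q)


def features_per_window(
    tensor: CoherenceTensor, tau: float, seed: int = 0
) -> pd.DataFrame:
    """Tidy table of (k_bar, Q) for every (trial, window) of one tensor.

    Each row carries the subject, band, trial and window indices plus the
    window's pre/post condition label from the window plan; ``tau`` should be
    the band's optimal threshold from the Surprise sweep.
    """
    plan = tensor.window_plan
    rows: list[tuple] = []
    for t in range(tensor.n_trials):
        for w in range(plan.n_windows):
            graph = binarize(tensor.values[t, w], tau)
            k_bar = average_node_degree(graph)
            if graph.m == 0:
                q = 0.0
            else:
                part = detect_communities_modularity(graph, seed=seed)
                q = modularity(graph, part)
            rows.append(
                (
                    tensor.subject_id,
                    tensor.band.name,
                    t,
                    w,
                    plan.condition_of_window[w],
                    k_bar,
                    q,
                )
            )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
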