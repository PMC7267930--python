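"""Coclassification (module allegiance) and network-specific stability.

For each node pair, the coclassification score is the proportion of time
windows in which the two nodes land in the same module.  High scores mean
stable shared module membership; low scores mean the pair stays
consistently segregated.  Averaging scores within and between the seven
canonical networks (hemispheres merged) yields 28 network-pair stability
scores per subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community_detection import Partition
from .data_io import NodeLabeling, NETWORKS_7
from .errors import DataValidationError, InsufficientDataError

logger = logging.getLogger(__name__)

#: Fixed output order of the 28 unordered network pairs: the 7 within-network
#: pairs first, then the 21 between-network pairs in row-major upper-triangle
#: order of (VIS, SMN, DAN, VAN, LIM, CON, DMN).
NETWORK_PAIRS: tuple[tuple[str, str], ...] = tuple(
    [(n, n) for n in NETWORKS_7]
    + [(NETWORKS_7[i], NETWORKS_7[j])
       for i in range(7) for j in range(i + 1, 7)]
)


@dataclass
class CoclassificationMatrix:
    """Node x node proportions of shared module assignment, diagonal 1."""

    values: np.ndarray
    n_windows: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise DataValidationError("coclassification matrix must be square")
        if np.abs(self.values - self.values.T).max() > 1e-12:
            raise DataValidationError("coclassification matrix must be symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise DataValidationError("coclassification values must lie in [0, 1]")
        if self.n_windows < 1:
            raise DataValidationError("n_windows must be >= 1")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def window_coclassification(partition: Partition) -> np.ndarray:
    """Binary matrix: entry (i, j) = 1 iff nodes i and j share a module."""
    a = partition.assignment
    return (a[:, None] == a[None, :]).astype(float)


def stability_matrix(partitions) -> CoclassificationMatrix:
    """Time-averaged coclassification over a subject's window partitions."""
    parts = list(partitions)
    if not parts:
        raise InsufficientDataError("need >= 1 window partition")
    n = parts[0].n_nodes
    if any(p.n_nodes != n for p in parts):
        raise DataValidationError("window partitions cover inconsistent node sets")
    acc = np.zeros((n, n))
    for p in parts:
        acc += window_coclassification(p)
    return CoclassificationMatrix(values=acc / len(parts), n_windows=len(parts))


def network_stability(matrix: CoclassificationMatrix, labeling: NodeLabeling,
                      include_diagonal: bool = False) -> pd.Series:
    """The 28 network-pair mean coclassification scores for one subject.

    Within-network blocks exclude the self-pair diagonal by default (a
    node is trivially coclassified with itself, which would inflate
    within-network scores); hemispheres are merged.  Output is a Series
    indexed by "A-B" pair names in the fixed NETWORK_PAIRS order.
    """
    if matrix.n_nodes != labeling.n_nodes:
        raise DataValidationError("labeling does not cover the matrix nodes")
    idx = labeling.network_7_indices()
    for net in NETWORKS_7:
        if idx[net].size < 1:
            raise DataValidationError(f"network {net} has no nodes")
    scores = {}
    for net_a, net_b in NETWORK_PAIRS:
        ia, ib = idx[net_a], idx[net_b]
        block = matrix.values[np.ix_(ia, ib)]
        if net_a == net_b and not include_diagonal:
            if ia.size < 2:
                raise DataValidationError(
                    f"network {net_a} needs >= 2 nodes to score without the diagonal"
                )
            mask = ~np.eye(ia.size, dtype=bool)
            scores[f"{net_a}-{net_b}"] = float(block[mask].mean())
        else:
            scores[f"{net_a}-{net_b}"] = float(block.mean())
    return pd.Series(scores, name="stability")
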