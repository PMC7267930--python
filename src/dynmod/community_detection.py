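"""Modularity maximization for signed weighted networks.

Quality function
----------------
For a non-negative weighted adjacency matrix W the quality of a partition
is Newman-Girvan weighted modularity with a resolution parameter:

    Q = (1/2m) * sum_ij [ W_ij - gamma * k_i k_j / (2m) ] * delta(c_i, c_j)

with node strengths k and total weight 2m (sums run over all ordered
pairs including i = j, so the self null terms are part of Q).

Fisher-z functional connectivity contains negative edges.  The default
treatment is the signed *asymmetric* variant: split W into its positive
and negative parts, compute the Newman term on each, and down-weight the
negative contribution by its share of the total weight,

    Q* = Q+ - ( v- / (v+ + v-) ) * Q-,

so that positive within-module weight dominates while negative
within-module weight is penalized only softly.  Alternatives
(``positive-only``: drop negative edges; ``plain``: apply the Newman
formula to the raw signed matrix) are selectable and recorded in output
metadata.

Optimization is multi-restart Louvain: greedy local node moves on the
(signed) modularity matrix followed by graph aggregation, repeated until
no move improves quality, with the node sweep order shuffled per restart
seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataValidationError, DegenerateInputError

logger = logging.getLogger(__name__)

#: Minimal quality gain for a local move to be accepted.
GAIN_TOL = 1e-10

#: Hard cap on aggregation passes (reached only on pathological inputs).
MAX_PASSES = 100

QUALITY_VARIANTS = ("signed-asymmetric", "positive-only", "plain")


@dataclass
class Partition:
    """A node -> module assignment with its quality value.

    Module ids are contiguous integers from 0, canonicalized by first
    appearance in node order.
    """

    assignment: np.ndarray
    gamma: float
    q: float
    run_seed: int | None = None

    def __post_init__(self) -> None:
        self.assignment = canonicalize(np.asarray(self.assignment, dtype=int))
        if not np.isfinite(self.q):
            raise DataValidationError("partition quality must be finite")

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max()) + 1 if self.assignment.size else 0

    @property
    def n_nodes(self) -> int:
        return self.assignment.size


def canonicalize(assignment: np.ndarray) -> np.ndarray:
    """Relabel modules as contiguous ids ordered by first appearance."""
    _, first = np.unique(assignment, return_index=True)
    order = assignment[np.sort(first)]
    lut = {old: new for new, old in enumerate(order)}
    return np.array([lut[a] for a in assignment], dtype=int)


def _as_matrix(matrix) -> np.ndarray:
    values = getattr(matrix, "values", matrix)
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if values.ndim != 2 or values.shape != (n, n):
        raise DataValidationError("adjacency must be a square matrix")
    if not np.isfinite(values).all():
        raise DataValidationError("adjacency has non-finite entries")
    if np.abs(values - values.T).max() > 1e-10:
        raise DataValidationError("adjacency must be symmetric")
    return values


def modularity_matrix(matrix, gamma: float,
                      variant: str = "signed-asymmetric") -> np.ndarray:
    """Full modularity matrix B such that Q = sum_ij B_ij delta(c_i, c_j).

    For the signed-asymmetric variant,
    B = (W+ - gamma k+ k+^T / v+) / v+  -  (W- - gamma k- k-^T / v-) / (v+ + v-)
    with v+- the total positive/negative weight (2m of each part); a part
    with zero total weight contributes nothing.
    """
    if gamma <= 0:
        raise DataValidationError("gamma must be positive")
    if variant not in QUALITY_VARIANTS:
        raise DataValidationError(f"unknown quality variant: {variant!r}")
    w = _as_matrix(matrix)
    if variant == "plain":
        pos, neg = w, np.zeros_like(w)
    else:
        pos = np.where(w > 0, w, 0.0)
        neg = -np.where(w < 0, w, 0.0)
        if variant == "positive-only":
            neg = np.zeros_like(w)
    v_pos = pos.sum()
    v_neg = neg.sum()
    if variant == "plain":
        if v_pos == 0:
            raise DegenerateInputError("modularity undefined: total weight is zero")
        k = pos.sum(axis=1)
        return (pos - gamma * np.outer(k, k) / v_pos) / v_pos
    if v_pos == 0 and v_neg == 0:
        raise DegenerateInputError("modularity undefined on an all-zero matrix")
    b = np.zeros_like(w)
    if v_pos > 0:
        k_pos = pos.sum(axis=1)
        b += (pos - gamma * np.outer(k_pos, k_pos) / v_pos) / v_pos
    if v_neg > 0:
        k_neg = neg.sum(axis=1)
        b -= (neg - gamma * np.outer(k_neg, k_neg) / v_neg) / (v_pos + v_neg)
    return b


def modularity_q(matrix, assignment: np.ndarray, gamma: float = 1.0,
                 variant: str = "signed-asymmetric") -> float:
    """Quality of a given partition (see module docstring for the form)."""
    w = _as_matrix(matrix)
    assignment = np.asarray(assignment, dtype=int)
    if assignment.shape != (w.shape[0],):
        raise DataValidationError("assignment must cover every node exactly once")
    b = modularity_matrix(w, gamma, variant)
    same = assignment[:, None] == assignment[None, :]
    return float(b[same].sum())


def _louvain_phase1(b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Greedy local moves on modularity matrix b until no gain > GAIN_TOL.

    Moving node i from its module to module c changes Q by
    2 * (sum_{j in c} B_ij - sum_{j in c_i, j != i} B_ij); the diagonal
    entry B_ii travels with the node and cancels.
    """
    n = b.shape[0]
    comm = np.arange(n)
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            row = b[i]
            links = np.bincount(comm, weights=row, minlength=n)
            own = comm[i]
            links[own] -= row[i]  # exclude self-loop from the stay/leave balance
            best = int(np.argmax(links))
            if links[best] - links[own] > GAIN_TOL and best != own:
                comm[i] = best
                improved = True
    return canonicalize(comm)


def louvain_once(matrix, gamma: float = 1.0, seed: int = 0,
                 variant: str = "signed-asymmetric") -> Partition:
    """One Louvain run: local moves + aggregation until stable.

    Deterministic given (matrix, gamma, seed): the seed drives the node
    sweep order in every phase-1 pass at every aggregation level.
    """
    b = modularity_matrix(matrix, gamma, variant)
    n = b.shape[0]
    rng = np.random.default_rng(seed)
    assignment = np.arange(n)
    level_b = b
    for _ in range(MAX_PASSES):
        comm = _louvain_phase1(level_b, rng)
        n_comm = comm.max() + 1
        if n_comm == level_b.shape[0]:
            break
        # aggregate: B' = P^T B P with P the community indicator matrix
        p = np.zeros((level_b.shape[0], n_comm))
        p[np.arange(level_b.shape[0]), comm] = 1.0
        level_b = p.T @ level_b @ p
        assignment = comm[assignment]
    assignment = canonicalize(assignment)
    q = float(b[assignment[:, None] == assignment[None, :]].sum())
    return Partition(assignment=assignment, gamma=gamma, q=q, run_seed=seed)


def best_partition(matrix, gamma: float = 1.0, n_runs: int = 100,
                   base_seed: int = 0,
                   variant: str = "signed-asymmetric") -> Partition:
    """Best of ``n_runs`` Louvain restarts (seeds base_seed..base_seed+n-1).

    Returns the maximum-quality partition; ties go to the lowest run seed.
    """
    if n_runs < 1:
        raise DataValidationError("n_runs must be >= 1")
    best: Partition | None = None
    for offset in range(n_runs):
        cand = louvain_once(matrix, gamma, seed=base_seed + offset, variant=variant)
        if best is None or cand.q > best.q:
            best = cand
    assert best is not None
    return best
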