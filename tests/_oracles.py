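"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: modularity is
evaluated straight from its defining sum, partitions are enumerated
exhaustively, and mutual information is computed from a hand-built
contingency table.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def set_partitions(n: int):
    """Yield every partition of range(n) as an assignment array.

    Uses restricted-growth strings: assignment[i] <= 1 + max(assignment[:i]).
    """
    assignment = np.zeros(n, dtype=int)

    def rec(i: int, max_label: int):
        if i == n:
            yield assignment.copy()
            return
        for label in range(max_label + 2):
            assignment[i] = label
            yield from rec(i + 1, max(max_label, label))

    yield from rec(1, 0) if n > 0 else iter(())


def newman_q(w: np.ndarray, assignment: np.ndarray, gamma: float) -> float:
    """Plain Newman-Girvan modularity from its defining double sum."""
    w = np.asarray(w, dtype=float)
    two_m = w.sum()
    k = w.sum(axis=1)
    q = 0.0
    n = w.shape[0]
    for i in range(n):
        for j in range(n):
            if assignment[i] == assignment[j]:
                q += w[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m


def signed_q(w: np.ndarray, assignment: np.ndarray, gamma: float) -> float:
    """Signed asymmetric modularity Q+ - (v-/(v+ + v-)) Q-, by direct sums."""
    w = np.asarray(w, dtype=float)
    pos = np.where(w > 0, w, 0.0)
    neg = -np.where(w < 0, w, 0.0)
    v_pos, v_neg = pos.sum(), neg.sum()
    same = np.equal.outer(assignment, assignment)

    def part_q(mat, v):
        if v == 0:
            return 0.0
        k = mat.sum(axis=1)
        return ((mat - gamma * np.outer(k, k) / v) * same).sum() / v

    q_pos = part_q(pos, v_pos)
    if v_neg == 0:
        return q_pos
    k = neg.sum(axis=1)
    q_neg_raw = ((neg - gamma * np.outer(k, k) / v_neg) * same).sum()
    return q_pos - q_neg_raw / (v_pos + v_neg)


def exhaustive_best_q(w: np.ndarray, gamma: float, quality=signed_q):
    """Globally optimal quality and partition by enumerating all partitions."""
    best_q, best_a = -np.inf, None
    for assignment in set_partitions(w.shape[0]):
        q = quality(w, assignment, gamma)
        if q > best_q:
            best_q, best_a = q, assignment
    return best_q, best_a


def contingency_mi(a, b) -> float:
    """Mutual information (nats) from an explicitly built contingency table."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = a.size
    mi = 0.0
    for la in np.unique(a):
        for lb in np.unique(b):
            p_ab = np.sum((a == la) & (b == lb)) / n
            if p_ab == 0:
                continue
            p_a = np.sum(a == la) / n
            p_b = np.sum(b == lb) / n
            mi += p_ab * math.log(p_ab / (p_a * p_b))
    return mi


def label_entropy(a) -> float:
    a = np.asarray(a)
    n = a.size
    h = 0.0
    for la in np.unique(a):
        p = np.sum(a == la) / n
        h -= p * math.log(p)
    return h


def planted_block_matrix(rng: np.random.Generator, n_nodes: int,
                         n_blocks: int, within: float = 1.0,
                         between: float = 0.1, noise: float = 0.05) -> np.ndarray:
    """Random symmetric non-negative matrix with planted block structure."""
    labels = rng.integers(0, n_blocks, size=n_nodes)
    # ensure every block occupied
    labels[:n_blocks] = np.arange(n_blocks)
    base = np.where(np.equal.outer(labels, labels), within, between)
    jitter = rng.uniform(0, noise, size=(n_nodes, n_nodes))
    w = base + (jitter + jitter.T) / 2
    np.fill_diagonal(w, 0.0)
    return (w + w.T) / 2
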