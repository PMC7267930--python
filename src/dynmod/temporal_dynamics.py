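"""Per-subject modularity dynamics: traces, stability, extreme states.

The temporal-stability statistic is SD(Q): the sample standard deviation
of window-wise modularity Q at the subject's resolution level (lower =
more stable).  Extreme-modularity states are windows whose Q lies beyond
mean +/- fraction * mean, with the mean taken either per subject
(individual convention) or as a supplied group mean (group convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community_detection import Partition, best_partition
from .data_io import NodeLabeling, NETWORKS_7
from .errors import DataValidationError, DegenerateInputError, InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass
class ModularityTrace:
    """Window-wise modularity values and module counts for one subject."""

    q_values: np.ndarray
    n_modules_values: np.ndarray
    gamma: float
    subject_id: str = ""
    partitions: list[Partition] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.q_values = np.asarray(self.q_values, dtype=float)
        self.n_modules_values = np.asarray(self.n_modules_values, dtype=int)
        if self.q_values.ndim != 1 or self.q_values.size == 0:
            raise DataValidationError("trace must hold >= 1 window value")
        if self.n_modules_values.shape != self.q_values.shape:
            raise DataValidationError("q and module-count series must align")
        if not np.isfinite(self.q_values).all():
            raise DataValidationError("trace contains non-finite Q values")

    @property
    def n_windows(self) -> int:
        return self.q_values.size

    @property
    def mean_q(self) -> float:
        """Time-averaged Q (the dynamic mean, distinct from static Q)."""
        return float(self.q_values.mean())


@dataclass
class StateReport:
    """Counts and window indices of high/low extreme-modularity states."""

    convention: str
    fraction: float
    reference_mean: float
    high_threshold: float
    low_threshold: float
    high_window_indices: np.ndarray
    low_window_indices: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.high_threshold < self.low_threshold:
            raise DataValidationError("thresholds out of order")
        self.high_window_indices = np.asarray(self.high_window_indices, dtype=int)
        self.low_window_indices = np.asarray(self.low_window_indices, dtype=int)

    @property
    def n_high(self) -> int:
        return self.high_window_indices.size

    @property
    def n_low(self) -> int:
        return self.low_window_indices.size


def q_trace(window_matrices, gamma: float, n_runs: int = 100, base_seed: int = 0,
            variant: str = "signed-asymmetric", subject_id: str = "") -> ModularityTrace:
    """Best-partition modularity for every window matrix at one gamma.

    Each window gets its own multi-restart Louvain optimization; the seeds
    are fanned out per window so restarts never share streams.
    """
    matrices = list(window_matrices)
    if not matrices:
        raise InsufficientDataError("no window matrices supplied")
    parts = []
    for w_idx, mat in enumerate(matrices):
        parts.append(best_partition(mat, gamma=gamma, n_runs=n_runs,
                                    base_seed=base_seed + w_idx * n_runs,
                                    variant=variant))
    if len(parts) == 1:
        logger.warning("single window: SD over time is 0 by convention")
    return ModularityTrace(
        q_values=np.array([p.q for p in parts]),
        n_modules_values=np.array([p.n_modules for p in parts]),
        gamma=gamma,
        subject_id=subject_id,
        partitions=parts,
    )


def sd_q(trace: ModularityTrace) -> float:
    """Sample SD (n-1 denominator) of the window-wise modularity values."""
    if trace.n_windows < 2:
        raise DegenerateInputError("SD(Q) needs >= 2 windows")
    return float(np.std(trace.q_values, ddof=1))


def detect_states(trace: ModularityTrace, convention: str = "individual",
                  reference_mean: float | None = None,
                  fraction: float = 0.5) -> StateReport:
    """Find windows with Q beyond mean * (1 +/- fraction), strict inequality.

    ``individual``: the reference mean is the subject's own trace mean.
    ``group``: the caller supplies the group mean (time-and-subject
    averaged Q) as ``reference_mean``.
    """
    if convention not in ("individual", "group"):
        raise DataValidationError(f"unknown state convention: {convention!r}")
    if convention == "group":
        if reference_mean is None:
            raise DataValidationError("group convention requires reference_mean")
        m = float(reference_mean)
    else:
        m = trace.mean_q
    if m <= 0:
        raise DegenerateInputError(
            f"non-positive reference mean ({m:.4f}): state thresholds undefined"
        )
    high_thr = m * (1.0 + fraction)
    low_thr = m * (1.0 - fraction)
    q = trace.q_values
    return StateReport(
        convention=convention,
        fraction=fraction,
        reference_mean=m,
        high_threshold=high_thr,
        low_threshold=low_thr,
        high_window_indices=np.flatnonzero(q > high_thr),
        low_window_indices=np.flatnonzero(q < low_thr),
        subject_id=trace.subject_id,
    )


def group_mean_q(traces) -> float:
    """Group reference mean: average Q across subjects first, then across windows.

    All traces must share a window count; the two-step order (subjects,
    then time) is preserved even though it equals the grand mean for
    equal-length traces.
    """
    qs = np.array([t.q_values for t in traces])
    if qs.ndim != 2:
        raise DataValidationError("traces must share a common window count")
    return float(qs.mean(axis=0).mean())


def threshold_sweep(traces, convention: str = "individual",
                    reference_mean: float | None = None,
                    fractions=()) -> pd.DataFrame:
    """State counts per subject at each threshold fraction (long format)."""
    rows = []
    for fraction in fractions:
        if not 0 < fraction < 1:
            raise DataValidationError("fractions must lie in (0, 1)")
        for trace in traces:
            rep = detect_states(trace, convention=convention,
                                reference_mean=reference_mean, fraction=fraction)
            rows.append({"subject_id": trace.subject_id, "fraction": fraction,
                         "n_high": rep.n_high, "n_low": rep.n_low})
    return pd.DataFrame(rows, columns=["subject_id", "fraction", "n_high", "n_low"])


def state_profiles(cohort_window_matrices, state_reports,
                   labeling: NodeLabeling):
    """Group-averaged connectivity in high vs low states and their difference.

    Pools windows across subjects: element-wise mean connectivity over all
    high-state windows, ditto low-state, difference = high - low, plus the
    7x7 network-aggregated difference (28 unordered network-pair blocks,
    hemispheres merged, diagonal cells excluded from block means).

    Parameters
    ----------
    cohort_window_matrices
        Per subject, the list of window ConnectivityMatrix objects (same
        order as the subject's StateReport window indices).
    state_reports
        Per subject, a StateReport aligned with the window list.
    labeling
        Node labeling providing the 7-network scheme.
    """
    highs, lows = [], []
    for mats, rep in zip(cohort_window_matrices, state_reports):
        stack = [m.values for m in mats]
        for idx in rep.high_window_indices:
            highs.append(stack[idx])
        for idx in rep.low_window_indices:
            lows.append(stack[idx])
    if not highs or not lows:
        raise InsufficientDataError(
            f"state profiles need >= 1 high and >= 1 low window across the cohort "
            f"(got {len(highs)} high, {len(lows)} low)"
        )
    high_mean = np.mean(highs, axis=0)
    low_mean = np.mean(lows, axis=0)
    diff = high_mean - low_mean
    return high_mean, low_mean, diff, aggregate_by_network(diff, labeling)


def aggregate_by_network(matrix: np.ndarray, labeling: NodeLabeling) -> pd.DataFrame:
    """Average a node x node matrix within the 28 network-pair blocks.

    Returns a 7x7 symmetric DataFrame indexed by network name; diagonal
    node pairs (i == i) are excluded from the block means.
    """
    matrix = np.asarray(matrix, dtype=float)
    idx = labeling.network_7_indices()
    out = pd.DataFrame(np.zeros((7, 7)), index=NETWORKS_7, columns=NETWORKS_7)
    for a, net_a in enumerate(NETWORKS_7):
        for net_b in NETWORKS_7[a:]:
            ia, ib = idx[net_a], idx[net_b]
            if ia.size == 0 or ib.size == 0:
                raise DataValidationError(f"network without nodes: {net_a} or {net_b}")
            block = matrix[np.ix_(ia, ib)]
            if net_a == net_b:
                if ia.size < 2:
                    raise DataValidationError(f"network {net_a} needs >= 2 nodes")
                mask = ~np.eye(ia.size, dtype=bool)
                value = block[mask].mean()
            else:
                value = block.mean()
            out.loc[net_a, net_b] = value
            out.loc[net_b, net_a] = value
    return out
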