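"""Static and tapered sliding-window weighted connectivity.

Edges are Fisher z-transformed Pearson correlations between node time
courses, computed either over the full scan (static network) or inside
tapered sliding windows (dynamic networks).  Matrices are weighted,
signed and unthresholded; negative correlations are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .data_io import ParcellatedTimeSeries
from .errors import DataValidationError, InsufficientDataError

logger = logging.getLogger(__name__)

#: Correlations are clipped to +/- (1 - FISHER_CLIP) before arctanh.
FISHER_CLIP = 1e-7


def make_taper(length: int, kind: str = "gaussian", sigma: float = 3.0) -> np.ndarray:
    """Build a max-normalized taper of the given window length.

    ``gaussian`` convolves a rectangular window with a Gaussian kernel
    (sigma in time points) and truncates to the window, de-emphasizing
    the window edges; ``uniform`` returns all-ones (plain Pearson).
    """
    if length < 2:
        raise DataValidationError("taper length must be >= 2")
    if kind == "uniform":
        return np.ones(length)
    if kind == "gaussian":
        rect = np.ones(length)
        taper = gaussian_filter1d(rect, sigma=sigma, mode="constant", cval=0.0)
        return taper / taper.max()
    raise DataValidationError(f"unknown taper kind: {kind!r}")


@dataclass
class WindowSpec:
    """Sliding-window geometry: length and step in time points, plus taper.

    Defaults follow a ~100 s window at TR = 0.645 s (156 points) shifted
    by 10 points.
    """

    length: int = 156
    step: int = 10
    taper: np.ndarray | None = None
    taper_kind: str = "gaussian"
    taper_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.length < 2:
            raise DataValidationError("window length must be >= 2")
        if self.step < 1:
            raise DataValidationError("window step must be >= 1")
        if self.taper is None:
            self.taper = make_taper(self.length, self.taper_kind, self.taper_sigma)
        self.taper = np.asarray(self.taper, dtype=float)
        if self.taper.shape != (self.length,):
            raise DataValidationError(
                f"taper length {self.taper.shape} does not match window length {self.length}"
            )
        if (self.taper < 0).any() or not (self.taper > 0).any():
            raise DataValidationError("taper must be non-negative and positive somewhere")

    def describe(self) -> dict:
        return {"length": self.length, "step": self.step,
                "taper_kind": self.taper_kind, "taper_sigma": self.taper_sigma}


@dataclass
class ConnectivityMatrix:
    """Node x node symmetric matrix of Fisher-z edge weights, zero diagonal."""

    values: np.ndarray
    window_index: int | str = "static"
    node_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise DataValidationError("connectivity matrix must be square")
        if not np.isfinite(self.values).all():
            raise DataValidationError("connectivity matrix has non-finite entries")
        if np.abs(self.values - self.values.T).max() > 1e-12:
            raise DataValidationError("connectivity matrix is not symmetric")
        np.fill_diagonal(self.values, 0.0)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def plan_windows(n_timepoints: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Enumerate 0-based half-open window index ranges [start, start+L).

    Returns floor((T - L)/s) + 1 contiguous ranges; windows that would run
    past the end of the series are not emitted.
    """
    if n_timepoints < spec.length:
        raise InsufficientDataError(
            f"series of {n_timepoints} points shorter than window length {spec.length}"
        )
    n_windows = (n_timepoints - spec.length) // spec.step + 1
    return [(i * spec.step, i * spec.step + spec.length) for i in range(n_windows)]


def weighted_correlation(x: np.ndarray, y: np.ndarray, taper: np.ndarray) -> float:
    """Weighted Pearson correlation with the taper as observation weights.

    Uses weighted means, covariance and variances.  A zero weighted
    variance on either side yields 0.0 with a logged warning (flagged
    pair convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(taper, dtype=float)
    if x.shape != y.shape or x.shape != w.shape:
        raise DataValidationError("x, y and taper must have equal lengths")
    wsum = w.sum()
    if wsum <= 0:
        raise DataValidationError("taper weights must sum to a positive value")
    w = w / wsum
    xc = x - w @ x
    yc = y - w @ y
    vx = w @ (xc * xc)
    vy = w @ (yc * yc)
    # relative zero test: centering leaves O(eps) residue on constant series
    tol_x = 1e-13 * max(1.0, float(w @ (x * x)))
    tol_y = 1e-13 * max(1.0, float(w @ (y * y)))
    if vx <= tol_x or vy <= tol_y:
        logger.warning("zero weighted variance; correlation set to 0")
        return 0.0
    return float((w @ (xc * yc)) / np.sqrt(vx * vy))


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing Fisher transform z = arctanh(r).

    Correlations within FISHER_CLIP of +/-1 are clipped before the
    transform (and the clip logged) so edges stay finite.
    """
    r = np.asarray(r, dtype=float)
    limit = 1.0 - FISHER_CLIP
    if (np.abs(r) >= limit).any():
        logger.warning("clipping %d near-unit correlations before Fisher transform",
                       int((np.abs(r) >= limit).sum()))
    z = np.arctanh(np.clip(r, -limit, limit))
    return float(z) if z.ndim == 0 else z


def _weighted_corr_matrix(window: np.ndarray, taper: np.ndarray) -> np.ndarray:
    """All-pairs weighted Pearson correlation of a (L x N) slice."""
    w = taper / taper.sum()
    xc = window - w @ window
    cov = (xc * w[:, None]).T @ xc
    var = np.diag(cov).copy()
    bad = var <= 0
    if bad.any():
        logger.warning("%d constant node(s) under taper; their edges set to 0",
                       int(bad.sum()))
        var[bad] = 1.0
    denom = np.sqrt(np.outer(var, var))
    corr = cov / denom
    corr[bad, :] = 0.0
    corr[:, bad] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def connectivity_stack(series: ParcellatedTimeSeries,
                       spec: WindowSpec) -> list[ConnectivityMatrix]:
    """One Fisher-z connectivity matrix per planned sliding window."""
    windows = plan_windows(series.n_timepoints, spec)
    out = []
    for idx, (start, stop) in enumerate(windows):
        corr = _weighted_corr_matrix(series.data[start:stop], spec.taper)
        np.fill_diagonal(corr, 0.0)  # diagonal is zeroed, keep it out of the clip log
        z = fisher_z(corr)
        np.fill_diagonal(z, 0.0)
        z = (z + z.T) / 2.0
        out.append(ConnectivityMatrix(values=z, window_index=idx,
                                      node_ids=series.node_ids))
    return out


def static_connectivity(series: ParcellatedTimeSeries) -> ConnectivityMatrix:
    """Full-scan connectivity: a single uniform window covering the series."""
    if series.n_timepoints < 3:
        raise InsufficientDataError(
            "need >= 3 time points for a static correlation estimate"
        )
    spec = WindowSpec(length=series.n_timepoints, step=1, taper_kind="uniform")
    (matrix,) = connectivity_stack(series, spec)
    return ConnectivityMatrix(values=matrix.values, window_index="static",
                              node_ids=series.node_ids)
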