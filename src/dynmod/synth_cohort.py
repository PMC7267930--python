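"""Synthetic cohorts with planted time-varying modular structure.

The generator emulates parcellated fast-TR resting-state BOLD: for each
subject, node signals follow a latent block-factor model

    x_i(t) = sqrt(b(t)) * g(t) + sqrt(w - b(t)) * f_m(i)(t) + sqrt(1 - w) * e_i(t)

with a global factor g, one factor f_m per planted module, and node
noise e, all unit-variance white Gaussian.  Nodes in the same module
correlate at w (``base_within_cov``); nodes in different modules
correlate at the time-varying coupling level b(t).  b(t) is a slow
sinusoid around ``base_between_cov`` whose amplitude is the subject's
planted stability amplitude: larger amplitude means larger fluctuation
of window-wise modularity downstream (high coupling = integrated, low
modularity; low coupling = segregated, high modularity).  An AR(1)
filter (variance-preserving, coefficient 0.3) mimics BOLD temporal
autocorrelation, and white observation noise of SD ``noise_sd`` is
added on top.

The phenotype is scored on the IQ convention (mean 100, SD 15, clipped
to [55, 145]) as a linear function of the planted amplitude plus
Gaussian noise, so that the planted amplitude-phenotype Spearman
correlation is approximately slope / sqrt(slope^2 + noise_sd^2).
Covariates (age, sex, handedness, mean FD) are generated independently
of the phenotype unless an FD-phenotype confound level is requested.

Everything is deterministic given (config.seed, subject_index): each
random draw uses its own numpy SeedSequence keyed by
(seed, subject_index, stream), so subjects can be generated
independently and in any order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_io import (
    NodeLabeling,
    ParcellatedTimeSeries,
    PhenotypeTable,
    NETWORKS_7,
    NETWORK_17_TO_7,
)
from .errors import ConfigError

logger = logging.getLogger(__name__)

#: AR(1) coefficient applied to the latent signal (BOLD-like smoothness).
AR1_COEFF = 0.3

#: 17-network children of each 7-network parent, in canonical order.
_CHILDREN_17 = {
    "VIS": ("VisCent", "VisPeri"),
    "SMN": ("SomMotA", "SomMotB"),
    "DAN": ("DorsAttnA", "DorsAttnB"),
    "VAN": ("SalVentAttnA", "SalVentAttnB"),
    "LIM": ("LimbicA", "LimbicB"),
    "CON": ("ContA", "ContB", "ContC"),
    "DMN": ("DefaultA", "DefaultB", "DefaultC", "TempPar"),
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults emulate the study conditions: 114 nodes, 884 usable time
    points at TR = 0.645 s, 7 planted modules matching the canonical
    networks, and a slow (200-point) coupling modulation that a 156-point
    window can resolve.
    """

    n_subjects: int
    n_nodes: int = 114
    n_timepoints: int = 884
    tr: float = 0.645
    n_modules: int = 7
    base_within_cov: float = 0.6
    base_between_cov: float = 0.15
    stability_range: tuple[float, float] = (0.0, 0.15)
    phenotype_slope: float = -1.0
    noise_sd: float = 0.5
    seed: int = 0
    modulation_period: float = 200.0
    fd_phenotype_r: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_nodes < 2 or self.n_timepoints < 2:
            raise ConfigError("n_subjects, n_nodes and n_timepoints must be positive "
                              "(>= 1 subject, >= 2 nodes, >= 2 time points)")
        if self.tr <= 0:
            raise ConfigError("tr must be positive")
        if self.n_modules < 1 or self.n_modules > self.n_nodes:
            raise ConfigError("n_modules must be in 1..n_nodes")
        if not 0 < self.base_within_cov < 1:
            raise ConfigError("base_within_cov must lie in (0, 1)")
        if not 0 <= self.base_between_cov < self.base_within_cov:
            raise ConfigError("base_between_cov must lie in [0, base_within_cov)")
        lo, hi = self.stability_range
        if lo < 0 or hi < lo:
            raise ConfigError("stability_range must be 0 <= lo <= hi")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.modulation_period <= 0:
            raise ConfigError("modulation_period must be positive")
        if not -1.0 <= self.fd_phenotype_r <= 1.0:
            raise ConfigError("fd_phenotype_r must lie in [-1, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stability_range"] = list(self.stability_range)
        return d


@dataclass
class GroundTruth:
    """Planted quantities for one cohort (one row set per subject)."""

    module_labels: list[np.ndarray]
    amplitudes: np.ndarray
    phenotype: np.ndarray
    coupling_trajectories: list[np.ndarray] = field(repr=False, default_factory=list)

    def to_dict(self) -> dict:
        return {
            "module_labels": [m.tolist() for m in self.module_labels],
            "amplitudes": self.amplitudes.tolist(),
            "phenotype": self.phenotype.tolist(),
            "coupling_trajectories": [c.tolist() for c in self.coupling_trajectories],
        }


def _rng(config: SimulationConfig, subject_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((config.seed, subject_index, stream))
    )


def planted_modules(config: SimulationConfig) -> np.ndarray:
    """Node -> module map: contiguous, near-equal blocks."""
    return (np.arange(config.n_nodes) * config.n_modules // config.n_nodes).astype(int)


def make_labeling(config: SimulationConfig) -> NodeLabeling:
    """Reference labeling aligned with the planted modules.

    Planted module m maps to 7-network NETWORKS_7[m mod 7]; each module's
    node block is split evenly over that network's 17-network children,
    and each child block is split LH/RH.  With the default n_modules = 7
    the planted modules coincide with the seven canonical networks.
    """
    modules = planted_modules(config)
    node_ids = tuple(f"node{i:03d}" for i in range(config.n_nodes))
    network_7 = [NETWORKS_7[m % 7] for m in modules]
    network_17 = [""] * config.n_nodes
    hemisphere = [""] * config.n_nodes
    for m in range(config.n_modules):
        block = np.flatnonzero(modules == m)
        children = _CHILDREN_17[NETWORKS_7[m % 7]]
        for rank, i in enumerate(block):
            network_17[i] = children[rank * len(children) // block.size]
            hemisphere[i] = "LH" if rank < (block.size + 1) // 2 else "RH"
    return NodeLabeling(node_ids=node_ids, network_7=tuple(network_7),
                        network_17=tuple(network_17), hemisphere=tuple(hemisphere))


def subject_amplitude(config: SimulationConfig, subject_index: int) -> float:
    """The subject's planted modularity-fluctuation amplitude."""
    lo, hi = config.stability_range
    if hi == lo:
        return float(lo)
    return float(_rng(config, subject_index, 0).uniform(lo, hi))


def coupling_trajectory(config: SimulationConfig, subject_index: int) -> np.ndarray:
    """Between-module correlation b(t): base + amp * sin, clipped to [0, w)."""
    amp = subject_amplitude(config, subject_index)
    phase = float(_rng(config, subject_index, 1).uniform(0, 2 * np.pi))
    t = np.arange(config.n_timepoints)
    b = config.base_between_cov + amp * np.sin(
        2 * np.pi * t / config.modulation_period + phase
    )
    return np.clip(b, 0.0, config.base_within_cov - 1e-3)


def generate_subject_timeseries(
    config: SimulationConfig, subject_index: int
) -> tuple[ParcellatedTimeSeries, dict]:
    """One subject's time x node matrix plus its ground-truth entry."""
    if not 0 <= subject_index < config.n_subjects:
        raise ConfigError(f"subject_index {subject_index} out of range")
    n, t = config.n_nodes, config.n_timepoints
    w = config.base_within_cov
    modules = planted_modules(config)
    b = coupling_trajectory(config, subject_index)

    rng = _rng(config, subject_index, 2)
    g = rng.standard_normal(t)                        # global factor
    f = rng.standard_normal((t, config.n_modules))    # per-module factors
    e = rng.standard_normal((t, n))                   # node noise

    sqrt_b = np.sqrt(b)[:, None]
    sqrt_wb = np.sqrt(w - b)[:, None]
    x = sqrt_b * g[:, None] + sqrt_wb * f[:, modules] + np.sqrt(1.0 - w) * e

    # variance-preserving AR(1) smoothing (BOLD-like autocorrelation)
    rho = AR1_COEFF
    y = np.empty_like(x)
    y[0] = x[0]
    for ti in range(1, t):
        y[ti] = rho * y[ti - 1] + np.sqrt(1.0 - rho ** 2) * x[ti]

    if config.noise_sd > 0:
        y = y + config.noise_sd * _rng(config, subject_index, 3).standard_normal((t, n))

    ts = ParcellatedTimeSeries(
        subject_id=f"sub{subject_index:04d}",
        data=y,
        tr=config.tr,
        node_ids=tuple(f"node{i:03d}" for i in range(n)),
    )
    truth = {"module_labels": modules,
             "amplitude": subject_amplitude(config, subject_index),
             "coupling_trajectory": b}
    return ts, truth


def _phenotype_scores(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """(amplitudes, fsiq) for the whole cohort."""
    amps = np.array([subject_amplitude(config, i) for i in range(config.n_subjects)])
    lo, hi = config.stability_range
    spread = (hi - lo) / np.sqrt(12.0)  # SD of the uniform amplitude draw
    z_amp = (amps - (lo + hi) / 2.0) / spread if spread > 0 else np.zeros_like(amps)
    noise = np.array([
        float(_rng(config, i, 4).standard_normal()) for i in range(config.n_subjects)
    ])
    scale = np.hypot(config.phenotype_slope, config.noise_sd)
    if scale == 0:
        fsiq = np.full(config.n_subjects, 100.0)
    else:
        fsiq = 100.0 + 15.0 * (config.phenotype_slope * z_amp
                               + config.noise_sd * noise) / scale
    return amps, np.clip(fsiq, 55.0, 145.0)


def generate_phenotype(config: SimulationConfig) -> tuple[PhenotypeTable, np.ndarray]:
    """Phenotype table (fsiq + covariates) and the planted amplitudes.

    Age, sex and handedness are independent of the phenotype.  Mean FD is
    independent too unless ``fd_phenotype_r`` is nonzero, in which case FD
    is constructed to correlate with the phenotype at that level (useful
    for confound testing).
    """
    amps, fsiq = _phenotype_scores(config)
    n = config.n_subjects
    rows = []
    z_fsiq = (fsiq - fsiq.mean()) / (fsiq.std() if fsiq.std() > 0 else 1.0)
    for i in range(n):
        rng = _rng(config, i, 5)
        age = float(np.clip(rng.normal(47.0, 15.0), 18.0, 85.0))
        sex = int(rng.random() < 0.35)
        handedness = int(rng.random() < 0.875)
        r = config.fd_phenotype_r
        fd_z = r * z_fsiq[i] + np.sqrt(max(0.0, 1.0 - r ** 2)) * rng.standard_normal()
        mean_fd = float(np.clip(0.10 + 0.04 * fd_z, 0.02, 0.20))
        rows.append({"subject_id": f"sub{i:04d}", "fsiq": fsiq[i], "age": age,
                     "sex": sex, "handedness": handedness, "mean_fd": mean_fd})
    return PhenotypeTable(pd.DataFrame(rows)), amps


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[ParcellatedTimeSeries], PhenotypeTable, NodeLabeling, GroundTruth]:
    """Full cohort: series, phenotype, reference labeling, ground truth."""
    if config.n_subjects < 3:
        raise ConfigError("a cohort needs >= 3 subjects")
    series = []
    labels = []
    trajectories = []
    for i in range(config.n_subjects):
        ts, truth = generate_subject_timeseries(config, i)
        series.append(ts)
        labels.append(truth["module_labels"])
        trajectories.append(truth["coupling_trajectory"])
    phenotype, amps = generate_phenotype(config)
    truth = GroundTruth(module_labels=labels, amplitudes=amps,
                        phenotype=phenotype.fsiq(),
                        coupling_trajectories=trajectories)
    return series, phenotype, make_labeling(config), truth
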