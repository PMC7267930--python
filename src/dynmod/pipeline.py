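"""End-to-end orchestration: simulate -> connectivity -> gamma -> dynamics
-> coclassification -> statistics.

`analyze_cohort` is the in-memory engine; `run_pipeline` wraps it with
file I/O, logging and a reproducibility manifest.  The master seed fans
out deterministically: every randomized stage for subject i draws its
seed from SeedSequence((master_seed, i, stage_tag)), so results do not
depend on subject processing order.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io
from .coclassification import network_stability, stability_matrix, NETWORK_PAIRS
from .community_detection import best_partition
from .data_io import Cohort, align_cohort, write_json
from .errors import ConfigError
from .group_stats import run_association_suite
from .resolution_selection import gamma_grid, select_gamma
from .synth_cohort import SimulationConfig, generate_cohort
from .temporal_dynamics import (
    detect_states,
    group_mean_q,
    q_trace,
    sd_q,
    threshold_sweep,
)
from .windowed_connectivity import WindowSpec, connectivity_stack, static_connectivity

logger = logging.getLogger(__name__)

#: Stage tags for the seed fan-out (subject-level streams).
SEED_STAGE_GAMMA = 10
SEED_STAGE_TRACE = 11
SEED_STAGE_STATIC = 12


def subject_seed(master_seed: int, subject_index: int, stage: int) -> int:
    """31-bit deterministic seed for (master, subject, stage)."""
    ss = np.random.SeedSequence((master_seed, subject_index, stage))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """Single config for a full run; serialized verbatim into the manifest."""

    seed: int = 0
    # simulation (used when no input directory is given)
    simulation: SimulationConfig | None = None
    # windowing
    window_length: int = 156
    window_step: int = 10
    taper_kind: str = "gaussian"
    taper_sigma: float = 3.0
    # community detection
    n_runs: int = 100
    quality_variant: str = "signed-asymmetric"
    # resolution selection: None -> select per subject on the grid
    gamma: float | None = None
    gamma_start: float = 0.1
    gamma_stop: float = 6.0
    gamma_step: float = 0.1
    gamma_n_runs: int | None = None
    normalized_mi: bool = True
    # states
    state_fraction: float = 0.5
    sweep_fractions: tuple = ()
    # statistics
    covariates: tuple = ("age", "sex", "handedness", "mean_fd")
    alpha: float = 0.05

    def window_spec(self) -> WindowSpec:
        return WindowSpec(length=self.window_length, step=self.window_step,
                          taper_kind=self.taper_kind, taper_sigma=self.taper_sigma)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        d["sweep_fractions"] = list(self.sweep_fractions)
        d["covariates"] = list(self.covariates)
        return d


@dataclass
class CohortAnalysis:
    """Everything `analyze_cohort` computes, kept in memory."""

    measures: pd.DataFrame
    traces: list
    coclassification: list
    window_stacks: list = field(repr=False, default_factory=list)
    gamma_per_subject: dict = field(default_factory=dict)
    group_mean: float = float("nan")
    report: dict | None = None
    sweep: pd.DataFrame | None = None


def analyze_cohort(cohort: Cohort, config: PipelineConfig,
                   keep_window_stacks: bool = False) -> CohortAnalysis:
    """Run the analysis stages on an aligned cohort.

    Per subject: sliding-window Fisher-z connectivity, gamma (fixed or
    selected against the 17-network reference on the static network),
    window-wise best partitions, SD(Q), time-averaged Q, static Q,
    extreme-state counts under both conventions, and the 28 network-pair
    coclassification stability scores.  If a phenotype is attached, the
    partial-Spearman association battery is run as well.
    """
    spec = config.window_spec()
    grid = gamma_grid(config.gamma_start, config.gamma_stop, config.gamma_step)
    gamma_runs = config.gamma_n_runs or config.n_runs
    rows = []
    traces, coclass_mats, stacks = [], [], []
    gamma_used: dict[str, float] = {}
    for i, ts in enumerate(cohort.series):
        stack = connectivity_stack(ts, spec)
        static = static_connectivity(ts)
        if config.gamma is not None:
            gamma = float(config.gamma)
        else:
            gamma, _, _ = select_gamma(
                static, grid, cohort.labeling.assignment_17(),
                n_runs=gamma_runs,
                base_seed=subject_seed(config.seed, i, SEED_STAGE_GAMMA),
                normalized=config.normalized_mi,
                variant=config.quality_variant,
            )
        gamma_used[ts.subject_id] = gamma
        static_part = best_partition(
            static, gamma=gamma, n_runs=gamma_runs,
            base_seed=subject_seed(config.seed, i, SEED_STAGE_STATIC),
            variant=config.quality_variant,
        )
        trace = q_trace(stack, gamma=gamma, n_runs=config.n_runs,
                        base_seed=subject_seed(config.seed, i, SEED_STAGE_TRACE),
                        variant=config.quality_variant, subject_id=ts.subject_id)
        traces.append(trace)
        ind = detect_states(trace, "individual", fraction=config.state_fraction)
        comat = stability_matrix(trace.partitions)
        coclass_mats.append(comat)
        row = {
            "subject_id": ts.subject_id,
            "gamma": gamma,
            "sd_q": sd_q(trace) if trace.n_windows > 1 else 0.0,
            "mean_q": trace.mean_q,
            "sd_num": float(np.std(trace.n_modules_values, ddof=1))
            if trace.n_windows > 1 else 0.0,
            "static_q": static_part.q,
            "n_high_individual": ind.n_high,
            "n_low_individual": ind.n_low,
        }
        row.update(network_stability(comat, cohort.labeling).to_dict())
        rows.append(row)
        if keep_window_stacks:
            stacks.append(stack)
        logger.debug("subject %s done (gamma=%.2f)", ts.subject_id, gamma)

    measures = pd.DataFrame(rows).set_index("subject_id")
    group_mean = group_mean_q(traces)
    n_high_g, n_low_g = [], []
    for trace in traces:
        rep = detect_states(trace, "group", reference_mean=group_mean,
                            fraction=config.state_fraction)
        n_high_g.append(rep.n_high)
        n_low_g.append(rep.n_low)
    measures["n_high_group"] = n_high_g
    measures["n_low_group"] = n_low_g

    sweep = None
    if config.sweep_fractions:
        sweep = threshold_sweep(traces, "individual",
                                fractions=config.sweep_fractions)

    report = None
    if cohort.phenotype is not None:
        net_cols = [f"{a}-{b}" for a, b in NETWORK_PAIRS]
        report = run_association_suite(
            measures, cohort.phenotype,
            covariate_names=config.covariates,
            network_columns=net_cols, alpha=config.alpha,
        )
    return CohortAnalysis(measures=measures, traces=traces,
                          coclassification=coclass_mats,
                          window_stacks=stacks, gamma_per_subject=gamma_used,
                          group_mean=group_mean, report=report, sweep=sweep)


def _load_cohort(in_dir: Path, tr: float) -> Cohort:
    labeling = data_io.read_labeling(in_dir / "labeling.tsv")
    phen_path = in_dir / "phenotype.csv"
    phenotype = data_io.read_phenotype(phen_path) if phen_path.exists() else None
    series = [data_io.read_timeseries(p, tr=tr)
              for p in sorted(in_dir.glob("sub*.tsv"))]
    return align_cohort(series, labeling, phenotype)


def simulate_to_dir(sim: SimulationConfig, out_dir: str | Path) -> Cohort:
    """Generate a cohort and write it as TSV/CSV/JSON under out_dir."""
    out_dir = Path(out_dir)
    series, phenotype, labeling, truth = generate_cohort(sim)
    for ts in series:
        data_io.write_timeseries(ts, out_dir / f"{ts.subject_id}.tsv")
    data_io.write_phenotype(phenotype, out_dir / "phenotype.csv")
    data_io.write_labeling(labeling, out_dir / "labeling.tsv")
    write_json({"config": sim.to_dict(), **truth.to_dict()},
               out_dir / "ground_truth.json")
    return align_cohort(series, labeling, phenotype)


def _report_to_json(report: dict | None) -> dict | None:
    if report is None:
        return None
    out: dict = {"n": report["n"], "alpha": report["alpha"], "correlations": {}}
    for name, res in report["correlations"].items():
        out["correlations"][name] = {"rho": res.rho, "p": res.p_value,
                                     "r_squared": res.r_squared}
    if "network_stability" in report:
        out["network_stability"] = {
            name: {"rho": entry["result"].rho, "p": entry["result"].p_value,
                   "survives_bonferroni": entry["survives_bonferroni"]}
            for name, entry in report["network_stability"].items()
        }
        out["bonferroni"] = report["bonferroni"]
    out["state_contrasts"] = report.get("state_contrasts", {})
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 in_dir: str | Path | None = None) -> Path:
    """Full disk-based run; returns the output directory.

    Inputs come either from ``in_dir`` (time series TSVs + labeling +
    optional phenotype) or, if absent, from the simulation config.  A
    manifest with the verbatim config, per-stage runtimes and package
    version is written alongside the outputs; re-running with the same
    config and seed reproduces every output.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    runtimes: dict[str, float] = {}

    t0 = time.perf_counter()
    if in_dir is not None:
        tr = config.simulation.tr if config.simulation else 0.645
        cohort = _load_cohort(Path(in_dir), tr)
        source = str(in_dir)
    else:
        if config.simulation is None:
            raise ConfigError("run_pipeline needs either in_dir or a simulation config")
        cohort = simulate_to_dir(config.simulation, out_dir / "cohort")
        source = "simulated"
    runtimes["inputs"] = time.perf_counter() - t0

    if cohort.phenotype is None:
        logger.warning("no phenotype table: association stage will be skipped")

    t0 = time.perf_counter()
    analysis = analyze_cohort(cohort, config)
    runtimes["analysis"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    analysis.measures.to_csv(out_dir / "measures.tsv", sep="\t",
                             float_format=data_io.FLOAT_FORMAT)
    for ts, comat in zip(cohort.series, analysis.coclassification):
        data_io.write_matrix(comat.values, cohort.labeling.node_ids,
                             out_dir / "coclassification" / f"{ts.subject_id}.tsv")
    if analysis.sweep is not None:
        analysis.sweep.to_csv(out_dir / "threshold_sweep.tsv", sep="\t", index=False)
    if analysis.report is not None:
        write_json(_report_to_json(analysis.report), out_dir / "associations.json")
    runtimes["outputs"] = time.perf_counter() - t0

    from . import __version__
    write_json({
        "config": config.to_dict(),
        "source": source,
        "version": __version__,
        "group_mean_q": analysis.group_mean,
        "runtimes_s": {k: round(v, 3) for k, v in runtimes.items()},
    }, out_dir / "manifest.json")
    logger.info("pipeline finished: %s", out_dir)
    return out_dir
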