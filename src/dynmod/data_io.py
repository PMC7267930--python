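"""Readers, writers and validation for the pipeline's tabular artifacts.

Everything on disk is plain text: time series and matrices as TSV, the
phenotype table as CSV, configs/manifests as JSON.  Matrices are written
with a fixed 9-significant-digit format so outputs diff cleanly and
round-trip bit-stably.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataValidationError

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.9g"

#: Canonical 7-network vocabulary (Yeo resting-state systems).
NETWORKS_7 = ("VIS", "SMN", "DAN", "VAN", "LIM", "CON", "DMN")

#: Canonical 17-network vocabulary (Yeo 17-system names).
NETWORKS_17 = (
    "VisCent", "VisPeri",
    "SomMotA", "SomMotB",
    "DorsAttnA", "DorsAttnB",
    "SalVentAttnA", "SalVentAttnB",
    "LimbicA", "LimbicB",
    "ContA", "ContB", "ContC",
    "DefaultA", "DefaultB", "DefaultC",
    "TempPar",
)

#: Mapping of each 17-network name onto its parent 7-network system.
#: TempPar is folded into the default-mode system, the usual convention.
NETWORK_17_TO_7 = {
    "VisCent": "VIS", "VisPeri": "VIS",
    "SomMotA": "SMN", "SomMotB": "SMN",
    "DorsAttnA": "DAN", "DorsAttnB": "DAN",
    "SalVentAttnA": "VAN", "SalVentAttnB": "VAN",
    "LimbicA": "LIM", "LimbicB": "LIM",
    "ContA": "CON", "ContB": "CON", "ContC": "CON",
    "DefaultA": "DMN", "DefaultB": "DMN", "DefaultC": "DMN",
    "TempPar": "DMN",
}

HEMISPHERES = ("LH", "RH")


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ParcellatedTimeSeries:
    """One subject's parcellated BOLD signal: a time x node matrix.

    Parameters
    ----------
    subject_id
        Unique subject identifier.
    data
        Array of shape (n_timepoints, n_nodes); no missing values.
    tr
        Sampling interval (repetition time) in seconds.
    node_ids
        Column labels, unique, aligned with ``data`` columns.
    """

    subject_id: str
    data: np.ndarray
    tr: float
    node_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.node_ids = tuple(str(n) for n in self.node_ids)
        if self.data.ndim != 2:
            raise DataValidationError(
                f"{self.subject_id}: time series must be 2-D, got {self.data.ndim}-D"
            )
        t, n = self.data.shape
        if t < 2 or n < 2:
            raise DataValidationError(
                f"{self.subject_id}: need >= 2 time points and >= 2 nodes, got {t} x {n}"
            )
        if n != len(self.node_ids):
            raise DataValidationError(
                f"{self.subject_id}: {n} columns but {len(self.node_ids)} node ids"
            )
        if len(set(self.node_ids)) != len(self.node_ids):
            raise DataValidationError(f"{self.subject_id}: duplicate node ids")
        if not np.isfinite(self.data).all():
            t_bad, n_bad = np.argwhere(~np.isfinite(self.data))[0]
            raise DataValidationError(
                f"{self.subject_id}: non-finite value at row {t_bad}, "
                f"column {n_bad} ({self.node_ids[n_bad]})"
            )
        if self.tr <= 0:
            raise DataValidationError(f"{self.subject_id}: tr must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass
class NodeLabeling:
    """Node-to-network reference labels in the 7- and 17-system schemes."""

    node_ids: tuple[str, ...]
    network_7: tuple[str, ...]
    network_17: tuple[str, ...]
    hemisphere: tuple[str, ...]

    def __post_init__(self) -> None:
        self.node_ids = tuple(str(n) for n in self.node_ids)
        self.network_7 = tuple(self.network_7)
        self.network_17 = tuple(self.network_17)
        self.hemisphere = tuple(self.hemisphere)
        n = len(self.node_ids)
        for name, seq in (
            ("network_7", self.network_7),
            ("network_17", self.network_17),
            ("hemisphere", self.hemisphere),
        ):
            if len(seq) != n:
                raise DataValidationError(f"{name} has {len(seq)} entries for {n} nodes")
        bad7 = set(self.network_7) - set(NETWORKS_7)
        if bad7:
            raise DataValidationError(f"unknown 7-network labels: {sorted(bad7)}")
        bad17 = set(self.network_17) - set(NETWORKS_17)
        if bad17:
            raise DataValidationError(f"unknown 17-network labels: {sorted(bad17)}")
        badh = set(self.hemisphere) - set(HEMISPHERES)
        if badh:
            raise DataValidationError(f"unknown hemisphere codes: {sorted(badh)}")
        if len(set(self.node_ids)) != n:
            raise DataValidationError("duplicate node ids in labeling")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def network_7_indices(self) -> dict[str, np.ndarray]:
        """Node index arrays per 7-network label, hemispheres merged."""
        arr = np.asarray(self.network_7)
        return {net: np.flatnonzero(arr == net) for net in NETWORKS_7}

    def assignment_17(self) -> np.ndarray:
        """17-network labels as integer codes (order of NETWORKS_17)."""
        lut = {name: i for i, name in enumerate(NETWORKS_17)}
        return np.array([lut[x] for x in self.network_17], dtype=int)


@dataclass
class PhenotypeTable:
    """Per-subject phenotype and nuisance covariates.

    Columns: subject_id, fsiq, age (years), sex (0/1), handedness (0/1),
    mean_fd (mm).  Sex and handedness are numeric codes so they can enter
    regressions directly.
    """

    table: pd.DataFrame

    REQUIRED = ("subject_id", "fsiq", "age", "sex", "handedness", "mean_fd")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DataValidationError(f"phenotype table missing columns: {missing}")
        self.table = self.table.copy()
        self.table["subject_id"] = self.table["subject_id"].astype(str)
        if self.table["subject_id"].duplicated().any():
            dupes = self.table.loc[self.table["subject_id"].duplicated(), "subject_id"]
            raise DataValidationError(f"duplicate subject ids: {sorted(set(dupes))}")
        numeric = list(self.REQUIRED[1:])
        if self.table[numeric].isna().any().any():
            bad = self.table[numeric].isna().any()
            raise DataValidationError(
                f"missing covariate values in columns {list(bad[bad].index)}"
            )
        for col in ("fsiq", "age", "mean_fd"):
            self.table[col] = self.table[col].astype(float)
        for col in ("sex", "handedness"):
            self.table[col] = self.table[col].astype(int)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.table["subject_id"])

    def covariate_matrix(self, names: Sequence[str] = ("age", "sex", "handedness", "mean_fd")) -> np.ndarray:
        return self.table[list(names)].to_numpy(dtype=float)

    def fsiq(self) -> np.ndarray:
        return self.table["fsiq"].to_numpy(dtype=float)


@dataclass
class Cohort:
    """Validated, aligned bundle of series, labeling and phenotype."""

    series: list[ParcellatedTimeSeries]
    labeling: NodeLabeling
    phenotype: PhenotypeTable | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.series)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.series]


# ---------------------------------------------------------------------------
# Time series I/O
# ---------------------------------------------------------------------------

def read_timeseries(path: str | Path, subject_id: str | None = None,
                    tr: float = 0.645) -> ParcellatedTimeSeries:
    """Read a TSV time series (header row = node ids, one row per time point).

    Raises :class:`DataValidationError` naming the offending row/column on
    ragged rows, non-numeric cells or NaN.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataValidationError(f"{path}: cannot parse TSV ({exc})") from exc
    if df.shape[1] < 2:
        raise DataValidationError(f"{path}: need >= 2 node columns, got {df.shape[1]}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(converted.isna().to_numpy())
        if bad.size:
            raise DataValidationError(
                f"{path}: non-numeric or missing value at row {bad[0]}, column '{col}'"
            )
        values[:, j] = converted.to_numpy()
    return ParcellatedTimeSeries(
        subject_id=subject_id or path.stem,
        data=values,
        tr=tr,
        node_ids=tuple(df.columns),
    )


def write_timeseries(ts: ParcellatedTimeSeries, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(ts.data, columns=list(ts.node_ids)).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


# ---------------------------------------------------------------------------
# Matrix I/O (square node x node tables)
# ---------------------------------------------------------------------------

def write_matrix(matrix: np.ndarray, node_ids: Sequence[str], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(np.asarray(matrix, dtype=float),
                 index=list(node_ids), columns=list(node_ids)).to_csv(
        path, sep="\t", float_format=FLOAT_FORMAT
    )


def read_matrix(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1] or list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise DataValidationError(f"{path}: not a square labeled matrix")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise DataValidationError(f"{path}: non-finite matrix entries")
    return values, tuple(str(c) for c in df.columns)


# ---------------------------------------------------------------------------
# Labeling I/O
# ---------------------------------------------------------------------------

def read_labeling(path: str | Path) -> NodeLabeling:
    """Read node labels: TSV with columns node_id, network_7, network_17, hemisphere."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["node_id", "network_7", "network_17", "hemisphere"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: labeling missing columns {missing}")
    return NodeLabeling(
        node_ids=tuple(df["node_id"]),
        network_7=tuple(df["network_7"]),
        network_17=tuple(df["network_17"]),
        hemisphere=tuple(df["hemisphere"]),
    )


def write_labeling(labeling: NodeLabeling, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "node_id": labeling.node_ids,
        "network_7": labeling.network_7,
        "network_17": labeling.network_17,
        "hemisphere": labeling.hemisphere,
    }).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phenotype I/O
# ---------------------------------------------------------------------------

PHENOTYPE_HEADER_COMMENT = "# sex: 0=female,1=male; handedness: 0=left,1=right\n"


def read_phenotype(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, comment="#")
    return PhenotypeTable(df)


def write_phenotype(phenotype: PhenotypeTable, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(PHENOTYPE_HEADER_COMMENT)
        phenotype.table.to_csv(fh, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Partition I/O
# ---------------------------------------------------------------------------

def write_partition(node_ids: Sequence[str], assignment: np.ndarray,
                    path: str | Path, metadata: dict | None = None) -> None:
    """Two-column TSV (node_id, module_id) plus optional JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"node_id": list(node_ids),
                  "module_id": np.asarray(assignment, dtype=int)}).to_csv(
        path, sep="\t", index=False
    )
    if metadata is not None:
        write_json(metadata, path.with_suffix(".json"))


def read_partition(path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["node_id", "module_id"]:
        raise DataValidationError(f"{path}: expected columns node_id, module_id")
    return tuple(df["node_id"].astype(str)), df["module_id"].to_numpy(dtype=int)


def write_json(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Cohort alignment
# ---------------------------------------------------------------------------

def align_cohort(series: Sequence[ParcellatedTimeSeries],
                 labeling: NodeLabeling,
                 phenotype: PhenotypeTable | None = None) -> Cohort:
    """Check that all subjects share node ids/order and phenotype coverage.

    Extra phenotype rows are dropped with a warning; a missing phenotype row
    for any subject, a node-order mismatch, or an empty cohort is an
    :class:`AlignmentError`.
    """
    series = list(series)
    if not series:
        raise AlignmentError("empty cohort: no time series provided")
    ref = labeling.node_ids
    for ts in series:
        if ts.node_ids != ref:
            raise AlignmentError(
                f"subject {ts.subject_id}: node ids/order do not match the labeling"
            )
    warnings: list[str] = []
    aligned_phenotype = phenotype
    if phenotype is not None:
        ids = [ts.subject_id for ts in series]
        have = set(phenotype.subject_ids)
        missing = [s for s in ids if s not in have]
        if missing:
            raise AlignmentError(f"phenotype missing subjects: {missing}")
        extra = [s for s in phenotype.subject_ids if s not in set(ids)]
        if extra:
            msg = f"dropping {len(extra)} unmatched phenotype rows: {extra[:5]}"
            warnings.append(msg)
            logger.warning(msg)
        tab = phenotype.table.set_index("subject_id").loc[ids].reset_index()
        aligned_phenotype = PhenotypeTable(tab)
    return Cohort(series=series, labeling=labeling,
                  phenotype=aligned_phenotype, warnings=warnings)
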