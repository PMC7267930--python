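"""Phenotype association statistics.

Associations between network measures and the phenotype are partial
Spearman correlations controlling for nuisance covariates (age, sex,
handedness, mean framewise displacement): both variables are
residualized on the covariates by OLS, the residuals are ranked
(average ranks on ties), and rho is the Pearson correlation of the
ranks.  Two-sided p-values use the t approximation with
df = n - 2 - n_covariates.  Multiple comparisons over the 28
network-pair stability scores are Bonferroni corrected.  Group
contrasts (subjects with vs without extreme states) are Mann-Whitney
U tests reported as z-statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataValidationError, DegenerateInputError, InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass
class PartialCorrResult:
    """Partial rank correlation with its two-sided p-value."""

    rho: float
    p_value: float
    n: int
    n_covariates: int

    @property
    def r_squared(self) -> float:
        return self.rho ** 2


def residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Standardized OLS residuals of y on covariates plus intercept.

    With no covariates this is plain centering and scaling to unit
    variance.  Rank-deficient designs raise, naming the offending
    column count.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        x = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariates.shape[0] != n:
            raise DataValidationError("covariate rows must match y length")
        x = np.column_stack([np.ones(n), covariates])
    if n <= x.shape[1]:
        raise InsufficientDataError(
            f"need n > {x.shape[1]} observations to residualize, got {n}"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise DataValidationError(
            f"covariate design is rank deficient ({rank} < {x.shape[1]}): "
            "collinear columns present"
        )
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    sd = resid.std(ddof=1)
    if sd <= 1e-10 * max(1.0, float(np.abs(y).max())):
        return resid  # all ~0: y exactly linear in covariates, leave unscaled
    return resid / sd


def partial_spearman(x: np.ndarray, y: np.ndarray,
                     covariates: np.ndarray | None = None,
                     rank_first: bool = False) -> PartialCorrResult:
    """Partial Spearman correlation of x and y given covariates.

    Default is residualize-then-rank; ``rank_first`` ranks the raw
    variables before residualizing instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataValidationError("x and y must be equal-length vectors")
    n = x.size
    k = 0
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.size:
            if covariates.ndim == 1:
                covariates = covariates[:, None]
            k = covariates.shape[1]
    if n < k + 4:
        raise InsufficientDataError(f"need n >= {k + 4} subjects, got {n}")
    if rank_first:
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    rx = residualize(x, covariates)
    ry = residualize(y, covariates)
    rrx = stats.rankdata(rx)
    rry = stats.rankdata(ry)
    if np.ptp(rrx) == 0 or np.ptp(rry) == 0:
        raise DegenerateInputError("constant residuals: correlation undefined")
    rho = float(np.corrcoef(rrx, rry)[0, 1])
    df = n - 2 - k
    if df <= 0:
        raise InsufficientDataError("non-positive degrees of freedom")
    rho_c = min(max(rho, -1.0 + 1e-15), 1.0 - 1e-15)
    t = rho_c * np.sqrt(df / (1.0 - rho_c ** 2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrResult(rho=rho, p_value=p, n=n, n_covariates=k)


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> tuple[float, float]:
    """Corrected per-test alpha: returns (full precision, rounded to 4 dp)."""
    if m < 1:
        raise DataValidationError("number of comparisons must be >= 1")
    if not 0 < alpha < 1:
        raise DataValidationError("alpha must lie in (0, 1)")
    corrected = alpha / m
    return corrected, round(corrected, 4)


def mann_whitney(group_a, group_b) -> tuple[float, float, float]:
    """Mann-Whitney U contrast, returning (U, z, two-sided p).

    U is the rank-sum statistic of group_a over group_b; z is the normal
    approximation with tie correction and no continuity correction.  The
    p-value comes from exact enumeration when n_a * n_b <= 400 and there
    are no ties, otherwise from the normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataValidationError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    mu = n_a * n_b / 2.0
    # tie-corrected variance of U
    _, counts = np.unique(pooled, return_counts=True)
    n = n_a + n_b
    tie_term = (counts ** 3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        raise DegenerateInputError("all pooled values identical: U variance is zero")
    z = (u_a - mu) / np.sqrt(sigma2)
    has_ties = counts.size < n
    if n_a * n_b <= 400 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        p = float(res.pvalue)
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return float(u_a), float(z), p


def run_association_suite(measures: pd.DataFrame, phenotype,
                          covariate_names=("age", "sex", "handedness", "mean_fd"),
                          network_columns=(), alpha: float = 0.05) -> dict:
    """The full phenotype association battery on an aligned cohort.

    Parameters
    ----------
    measures
        Per-subject DataFrame indexed like the phenotype table order, with
        at least ``sd_q``; optionally ``mean_q``, ``static_q``,
        ``n_high_individual``/``n_low_individual``,
        ``n_high_group``/``n_low_group`` and the 28 network-pair
        stability columns named in ``network_columns``.
    phenotype
        A PhenotypeTable aligned to the same subjects.

    Returns a report dict: one PartialCorrResult per measure, the
    Bonferroni threshold over the network scores, survival flags, and
    Mann-Whitney contrasts of FSIQ and mean FD between subjects with and
    without extreme states.
    """
    n = len(measures)
    if n < len(covariate_names) + 4:
        raise InsufficientDataError(
            f"association suite needs >= {len(covariate_names) + 4} subjects, got {n}"
        )
    if list(phenotype.table["subject_id"]) != list(measures.index.astype(str)):
        raise DataValidationError("measures and phenotype subjects are not aligned")
    fsiq = phenotype.fsiq()
    cov = phenotype.covariate_matrix(covariate_names)
    keep = cov.std(axis=0) > 0
    if not keep.all():
        dropped = [name for name, k in zip(covariate_names, keep) if not k]
        logger.warning("dropping constant covariate(s): %s", dropped)
        covariate_names = [n_ for n_, k in zip(covariate_names, keep) if k]
        cov = cov[:, keep]
    report: dict = {"n": n, "alpha": alpha, "correlations": {},
                    "covariates": list(covariate_names)}

    scalar_cols = [c for c in ("sd_q", "mean_q", "static_q",
                               "n_high_individual", "n_low_individual",
                               "n_high_group", "n_low_group")
                   if c in measures.columns]
    for col in scalar_cols:
        try:
            report["correlations"][col] = partial_spearman(
                measures[col].to_numpy(dtype=float), fsiq, cov
            )
        except DegenerateInputError:
            logger.warning("measure %s is constant across subjects; skipped", col)

    network_columns = [c for c in network_columns if c in measures.columns]
    if network_columns:
        full, rounded = bonferroni_threshold(alpha, len(network_columns))
        net = {}
        for col in network_columns:
            try:
                res = partial_spearman(measures[col].to_numpy(dtype=float), fsiq, cov)
            except DegenerateInputError:
                logger.warning("network score %s is constant; skipped", col)
                continue
            net[col] = {"result": res, "survives_bonferroni": res.p_value < full}
        report["network_stability"] = net
        report["bonferroni"] = {"m": len(network_columns),
                                "threshold": full, "threshold_rounded": rounded}

    contrasts = {}
    for col in ("n_high_individual", "n_low_individual"):
        if col not in measures.columns:
            continue
        has_state = measures[col].to_numpy(dtype=float) > 0
        if has_state.all() or not has_state.any():
            logger.warning("no contrast groups for %s (all-or-none states)", col)
            continue
        for var_name, values in (("fsiq", fsiq),
                                 ("mean_fd", phenotype.table["mean_fd"].to_numpy(float))):
            u, z, p = mann_whitney(values[has_state], values[~has_state])
            contrasts[f"{col}_vs_{var_name}"] = {"u": u, "z": z, "p": p,
                                                 "n_with": int(has_state.sum()),
                                                 "n_without": int((~has_state).sum())}
    report["state_contrasts"] = contrasts
    return report
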