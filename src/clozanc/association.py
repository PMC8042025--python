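"""Single-variant logistic association, ANC-threshold sweeps and OR trends.

The association model is an additive logistic regression of case status on
the risk-allele count (0/1/2), optionally adjusted for covariates (by
default principal components PC1-PC7; the "global and local ancestry" model
additionally includes the windowed AFR and EAS local-ancestry dosages as two
linear covariates).  Fitting is maximum likelihood via Newton iteration
(iteratively reweighted least squares) with Wald standard errors from the
observed information.

The threshold sweep refits the model over a range of ANC case thresholds
(500-1500 cells/mm^3 in steps of 100) under explicit case-inclusion modes,
and a weighted least-squares line (weights = reciprocal standard errors of
the OR) summarises the trend of the odds ratio across thresholds.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cohort_io import CohortValidationError, NoCasesError, PC_COLUMNS, PhenotypeClass

logger = logging.getLogger("clozanc")

Z_95 = 1.96  # Wald interval multiplier
SEPARATION_BETA = 12.0  # |log-OR| beyond which a non-converged fit is treated as separated


class SingularDesignError(CohortValidationError):
    """Design matrix is rank deficient (constant or collinear columns)."""


@dataclass
class AssociationResult:
    """Additive-model logistic fit for one phenotype definition.

    ``beta`` is the log-OR per risk allele; ``ci95`` uses exp(beta +- 1.96 se);
    ``p`` is the two-sided Wald p-value.  ``separation`` flags (quasi-)
    perfectly separated fits, for which beta is reported as +-inf and se/p as
    NaN rather than a silently divergent estimate.
    """

    beta: float
    se: float
    or_: float
    ci95: tuple[float, float]
    p: float
    n_cases: int
    n_controls: int
    freq_cases: float
    freq_controls: float
    covariate_names: tuple[str, ...] = ()
    n_excluded: int = 0
    separation: bool = False


def _as_design(
    dose: np.ndarray, covariates: Optional[np.ndarray], covariate_names: Optional[Sequence[str]]
) -> tuple[np.ndarray, list[str]]:
    dose = np.asarray(dose, dtype=float).reshape(-1, 1)
    if covariates is None:
        cov = np.empty((dose.shape[0], 0))
        names: list[str] = []
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov.reshape(-1, 1)
        names = list(covariate_names or (f"cov{i + 1}" for i in range(cov.shape[1])))
        if len(names) != cov.shape[1]:
            raise CohortValidationError("covariate_names length does not match covariates")
    return np.hstack([dose, cov]), names


def logistic_fit(
    status: np.ndarray,
    dose: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    covariate_names: Optional[Sequence[str]] = None,
) -> AssociationResult:
    """Covariate-adjusted logistic regression of case status on allele dose.

    Rows with a missing status, dose or covariate are excluded (and counted
    in ``n_excluded``).  Requires at least one case and one control after
    exclusion; constant or collinear design columns raise
    :class:`SingularDesignError` naming the offending columns.
    """
    status = np.asarray(status, dtype=float)
    X_raw, names = _as_design(dose, covariates, covariate_names)
    if status.size != X_raw.shape[0]:
        raise CohortValidationError("status and design rows must align")
    keep = np.isfinite(status) & np.all(np.isfinite(X_raw), axis=1)
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("logistic_fit: excluded %d subject(s) with missing data", n_excluded)
    y = status[keep]
    X_raw = X_raw[keep]
    if not np.isin(y, (0.0, 1.0)).all():
        raise CohortValidationError("status must be 0/1")
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())
    if n_cases == 0 or n_controls == 0:
        raise NoCasesError(
            f"logistic fit needs cases and controls (got {n_cases} cases, {n_controls} controls)"
        )
    all_names = ["dose"] + names
    constant = [all_names[j] for j in range(X_raw.shape[1]) if np.ptp(X_raw[:, j]) == 0]
    if constant:
        raise SingularDesignError(f"constant design column(s): {constant}")
    X = sm.add_constant(X_raw, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the columns whose removal restores full rank
        collinear = []
        for j in range(1, X.shape[1]):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(X):
                collinear.append(all_names[j - 1])
        raise SingularDesignError(f"collinear design column(s): {collinear}")

    dose_kept = X_raw[:, 0]
    freq_cases = float(dose_kept[y == 1].sum() / (2 * n_cases))
    freq_controls = float(dose_kept[y == 0].sum() / (2 * n_controls))

    separation = False
    beta = se = p = np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-10, disp=0)
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        p = float(fit.pvalues[1])
        converged = bool(fit.mle_retvals.get("converged", True))
        if (not converged and abs(beta) > SEPARATION_BETA) or not np.isfinite(se):
            separation = True
    except (PerfectSeparationError, np.linalg.LinAlgError):
        separation = True
        # sign of the divergent estimate from the raw 2x2 orientation
        beta = np.inf if freq_cases >= freq_controls else -np.inf

    if separation:
        logger.warning("logistic_fit: (quasi-)separation detected; estimate flagged")
        beta = np.inf if beta > 0 else -np.inf
        se = np.nan
        p = np.nan
    or_ = float(np.exp(beta))
    ci = (float(np.exp(beta - Z_95 * se)), float(np.exp(beta + Z_95 * se)))
    return AssociationResult(
        beta=beta,
        se=se,
        or_=or_,
        ci95=ci,
        p=p,
        n_cases=n_cases,
        n_controls=n_controls,
        freq_cases=freq_cases,
        freq_controls=freq_controls,
        covariate_names=tuple(names),
        n_excluded=n_excluded,
        separation=separation,
    )


# ---------------------------------------------------------------------------
# phenotype-definition table (main fits)


def association_table(
    data: pd.DataFrame,
    *,
    dose_col: str = "hard_call",
    class_col: str = "phenotype_class",
    pc_cols: Sequence[str] = PC_COLUMNS,
    local_cols: Sequence[str] = ("dos_afr", "dos_eas"),
) -> pd.DataFrame:
    """Fit neutropenia and agranulocytosis against controls, two models each.

    Neutropenia cases are all subjects with ANC <= 1500 (agranulocytosis
    included); the agranulocytosis analysis keeps only ANC <= 500 cases and
    drops the remaining neutropenia cases entirely.  The "global" model
    adjusts for principal components, the "global_local" model additionally
    for the windowed AFR and EAS local-ancestry dosages.
    """
    rows = []
    classes = data[class_col]
    for phenotype in ("neutropenia", "agranulocytosis"):
        if phenotype == "neutropenia":
            sub = data
            status = classes.map(lambda c: float(c.is_neutropenia))
        else:
            keep = classes != PhenotypeClass.NEUTROPENIA_ONLY
            sub = data[keep]
            status = classes[keep].map(lambda c: float(c is PhenotypeClass.AGRANULOCYTOSIS))
        for model, cov_cols in (("global", list(pc_cols)), ("global_local", list(pc_cols) + list(local_cols))):
            record = {"phenotype": phenotype, "model": model}
            try:
                result = logistic_fit(
                    status.to_numpy(),
                    sub[dose_col].to_numpy(dtype=float),
                    sub[cov_cols].to_numpy(dtype=float),
                    cov_cols,
                )
                record.update(
                    n_cases=result.n_cases,
                    n_controls=result.n_controls,
                    freq_cases=result.freq_cases,
                    freq_controls=result.freq_controls,
                    or_=result.or_,
                    ci_low=result.ci95[0],
                    ci_high=result.ci95[1],
                    p=result.p,
                    n_excluded=result.n_excluded,
                    separation=result.separation,
                    note="",
                )
            except (NoCasesError, SingularDesignError) as err:
                record.update(
                    n_cases=np.nan, n_controls=np.nan, freq_cases=np.nan,
                    freq_controls=np.nan, or_=np.nan, ci_low=np.nan, ci_high=np.nan,
                    p=np.nan, n_excluded=np.nan, separation=False, note=str(err),
                )
            rows.append(record)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANC-threshold sweep


class SweepMode(enum.Enum):
    """Case-inclusion rule of the ANC-threshold sweep.

    ``CUMULATIVE``: cases are all subjects with ANC <= T.
    ``EXCLUDE_AGRANULOCYTOSIS``: agranulocytosis subjects (ANC <= 500) are
    dropped entirely and cases are 500 < ANC <= T, isolating the
    neutropenia-only signal.
    ``EXCLUDE_NEUTROPENIA_BAND``: cases are ANC <= T and the remaining
    neutropenia-band subjects (T < ANC <= 1500) are dropped (they are never
    used as controls).  Controls are always ANC > 1500, so this coincides
    numerically with ``CUMULATIVE``; both names are kept to make the
    exclusion direction explicit at call sites.
    """

    CUMULATIVE = "cumulative"
    EXCLUDE_AGRANULOCYTOSIS = "exclude_agranulocytosis"
    EXCLUDE_NEUTROPENIA_BAND = "exclude_neutropenia_band"


@dataclass
class SweepPoint:
    threshold: float
    result: Optional[AssociationResult]
    skipped_reason: str = ""


@dataclass
class SweepResult:
    mode: SweepMode
    points: list[SweepPoint] = field(default_factory=list)
    trend: Optional[tuple[float, float]] = None  # (slope, intercept) of OR on T

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pt in self.points:
            row = {"threshold": pt.threshold, "mode": self.mode.value}
            if pt.result is None:
                row.update(
                    or_=np.nan, se_beta=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                    n_cases=np.nan, n_controls=np.nan, skipped=pt.skipped_reason,
                )
            else:
                r = pt.result
                row.update(
                    or_=r.or_, se_beta=r.se, ci_low=r.ci95[0], ci_high=r.ci95[1], p=r.p,
                    n_cases=r.n_cases, n_controls=r.n_controls, skipped="",
                )
            rows.append(row)
        return pd.DataFrame(rows)


def anc_threshold_sweep(
    anc: np.ndarray,
    dose: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    *,
    covariate_names: Optional[Sequence[str]] = None,
    thresholds: Optional[Sequence[float]] = None,
    mode: SweepMode = SweepMode.EXCLUDE_AGRANULOCYTOSIS,
    neut_threshold: float = 1500.0,
    agran_threshold: float = 500.0,
) -> SweepResult:
    """Refit the association across a range of ANC case thresholds.

    Controls are always subjects with ANC > ``neut_threshold``.  Subjects
    with missing ANC cannot be thresholded and are excluded.  A threshold
    that yields no cases is skipped with a logged reason rather than
    failing the sweep; the OR-vs-threshold trend is fitted by weighted
    least squares over the remaining points.
    """
    anc = np.asarray(anc, dtype=float)
    dose = np.asarray(dose, dtype=float)
    if thresholds is None:
        thresholds = np.arange(500.0, 1501.0, 100.0)
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise CohortValidationError("sweep thresholds must be strictly increasing")
    if np.any(thresholds < agran_threshold) or np.any(thresholds > neut_threshold):
        raise CohortValidationError(
            f"thresholds must lie within [{agran_threshold}, {neut_threshold}]"
        )
    usable = np.isfinite(anc)
    controls = usable & (anc > neut_threshold)
    result = SweepResult(mode=mode)
    for T in thresholds:
        if mode is SweepMode.EXCLUDE_AGRANULOCYTOSIS:
            cases = usable & (anc > agran_threshold) & (anc <= T)
        else:  # CUMULATIVE and EXCLUDE_NEUTROPENIA_BAND coincide (see SweepMode)
            cases = usable & (anc <= T)
        keep = cases | controls
        if cases.sum() == 0:
            reason = f"no cases at threshold {T:.0f} in mode {mode.value}"
            logger.info("sweep: %s; fit skipped", reason)
            result.points.append(SweepPoint(float(T), None, reason))
            continue
        try:
            fit = logistic_fit(
                cases[keep].astype(float),
                dose[keep],
                None if covariates is None else np.asarray(covariates, dtype=float)[keep],
                covariate_names,
            )
            result.points.append(SweepPoint(float(T), fit))
        except (NoCasesError, SingularDesignError) as err:
            logger.info("sweep: threshold %.0f skipped (%s)", T, err)
            result.points.append(SweepPoint(float(T), None, str(err)))
    ok = [
        pt
        for pt in result.points
        if pt.result is not None and not pt.result.separation and np.isfinite(pt.result.se)
    ]
    if len(ok) >= 2 and len({pt.threshold for pt in ok}) >= 2:
        T_ok = np.array([pt.threshold for pt in ok])
        or_ok = np.array([pt.result.or_ for pt in ok])
        se_or = np.array([pt.result.or_ * pt.result.se for pt in ok])  # delta method
        result.trend = wls_trend(T_ok, or_ok, se_or)
    return result


def wls_trend(
    thresholds: np.ndarray, or_values: np.ndarray, se_or: np.ndarray
) -> tuple[float, float]:
    """Weighted least-squares line of OR on threshold.

    Minimises sum_i w_i (or_i - a - b T_i)^2 with w_i = 1 / se_i (reciprocal
    standard errors of the OR, untransformed).  Returns ``(slope, intercept)``.
    """
    T = np.asarray(thresholds, dtype=float)
    y = np.asarray(or_values, dtype=float)
    se = np.asarray(se_or, dtype=float)
    if T.size != y.size or T.size != se.size or T.size < 2:
        raise CohortValidationError("wls_trend needs >= 2 aligned points")
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise CohortValidationError("standard errors must be positive and finite")
    if np.ptp(T) == 0:
        raise CohortValidationError("thresholds must not all be equal")
    X = sm.add_constant(T)
    fit = sm.WLS(y, X, weights=1.0 / se).fit()
    return float(fit.params[1]), float(fit.params[0])
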