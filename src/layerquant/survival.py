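"""Expression cutpoint scanning for survival: Youden's index + adjusted Cox fits.

Given a cohort table with continuous expression, follow-up time, vital
status, and the adjustment covariates (age, sex, smoking, alcohol), the scan
dichotomizes expression at every admissible candidate cutoff (midpoints
between sorted unique values), computes Youden's index
J = sensitivity + specificity - 1 of the high/low split against the binary
outcome, and selects the cutoff maximizing J (ties broken toward the smaller
cutoff).  A covariate-adjusted Cox proportional-hazards model supplies the
group log-hazard-ratio and Wald p-value at the selected cutoff.  Kaplan-Meier
curves and the two-sample log-rank test compare the resulting groups.

The default binary outcome for J is vital status at last follow-up; a
censoring-aware variant (status at a fixed horizon, censored-early subjects
excluded) is available via ``horizon``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .errors import ConfigurationError

REQUIRED_COLUMNS = ("expression", "time", "event", "age", "sex", "smoking", "alcohol")
DEFAULT_COVARIATES = ("age", "sex", "smoking", "alcohol")
MIN_GROUP_FRAC = 0.1


def load_survival_table(path) -> pd.DataFrame:
    """Load a cohort CSV, dropping incomplete rows.

    Requires columns ``expression,time,event,age,sex,smoking,alcohol``.  Rows
    with any blank field are dropped; the dropped count is recorded in
    ``df.attrs['n_dropped']`` (cohort cleaning of this kind is routine, e.g.
    185 -> 161 usable subjects in public registry tables).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"survival table missing columns: {missing}")
    n0 = len(df)
    df = df.dropna(subset=list(REQUIRED_COLUMNS)).reset_index(drop=True)
    validate_survival_table(df)
    df.attrs["n_dropped"] = n0 - len(df)
    return df


def validate_survival_table(df: pd.DataFrame) -> None:
    if (df["time"] <= 0).any():
        raise ConfigurationError("all follow-up times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ConfigurationError("event must be binary 0/1")


@dataclass(frozen=True)
class YoudenResult:
    """Youden's J with its 2x2 classification table."""

    j: float
    sensitivity: float
    specificity: float
    tp: int
    fn: int
    fp: int
    tn: int


def youden_index(high: np.ndarray, outcome: np.ndarray) -> YoudenResult:
    """Youden's index J = sensitivity + specificity - 1.

    ``high`` flags subjects above the cutoff, ``outcome`` the binary event.
    Sensitivity is P(high | outcome=1), specificity P(low | outcome=0).
    """
    high = np.asarray(high, dtype=bool)
    outcome = np.asarray(outcome, dtype=bool)
    if high.shape != outcome.shape:
        raise ConfigurationError("high and outcome must have equal length")
    n_pos = int(outcome.sum())
    n_neg = outcome.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ConfigurationError("outcome must contain both classes")
    tp = int((high & outcome).sum())
    fn = n_pos - tp
    fp = int((high & ~outcome).sum())
    tn = n_neg - fp
    sens = tp / n_pos
    spec = tn / n_neg
    return YoudenResult(sens + spec - 1.0, sens, spec, tp, fn, fp, tn)


@dataclass(frozen=True)
class PHFit:
    """Group term of a covariate-adjusted proportional-hazards fit."""

    coef: float
    se: float
    p: float
    hazard_ratio: float
    converged: bool
    ties: str = "efron"


def fit_adjusted_ph(
    table: pd.DataFrame,
    group: np.ndarray,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> PHFit:
    """Fit a Cox model for time/event on the group indicator plus covariates.

    Maximizes the standard partial likelihood with Efron tie handling and
    returns the group log-hazard-ratio with its Wald standard error and
    p-value.  Non-convergence or separation is reported via
    ``converged=False`` (NaN estimates) instead of raising, so scan rows can
    be flagged and excluded.
    """
    group = np.asarray(group, dtype=int)
    for g in (0, 1):
        sub = table.loc[group == g, "event"]
        if len(sub) == 0 or sub.sum() < 1:
            raise ConfigurationError("each group needs >= 1 subject with >= 1 event")
    df = table[["time", "event", *covariates]].copy()
    df["group"] = group
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return PHFit(np.nan, np.nan, np.nan, np.nan, converged=False)
    coef = float(fitter.params_["group"])
    se = float(fitter.standard_errors_["group"])
    p = float(fitter.summary.loc["group", "p"])
    return PHFit(coef, se, p, float(np.exp(coef)), converged=True)


@dataclass(frozen=True)
class CutoffScanResult:
    """Per-cutoff Youden/fit rows plus the selected optimum.

    ``table`` has one row per admissible candidate cutoff with columns
    ``cutoff,n_high,n_low,j,sensitivity,specificity`` (and
    ``coef,se,p,converged`` where a fit was run).  ``fit`` is the adjusted
    PH fit at the selected cutoff.
    """

    table: pd.DataFrame
    selected_cutoff: float
    j_max: float
    fit: PHFit


def _binary_outcome(table: pd.DataFrame, horizon: float | None) -> tuple[pd.DataFrame, np.ndarray]:
    if horizon is None:
        return table, table["event"].to_numpy(dtype=bool)
    known = (table["event"] == 1) & (table["time"] <= horizon) | (table["time"] > horizon)
    sub = table.loc[known].reset_index(drop=True)
    outcome = ((sub["event"] == 1) & (sub["time"] <= horizon)).to_numpy()
    return sub, outcome


def scan_cutoffs(
    table: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    min_group_frac: float = MIN_GROUP_FRAC,
    fit_all: bool = False,
    horizon: float | None = None,
) -> CutoffScanResult:
    """Scan expression cutoffs and select the one maximizing Youden's J.

    Candidate cutoffs are the midpoints between neighboring sorted unique
    expression values; candidates leaving either group below
    ``min_group_frac * n`` subjects are inadmissible.  With ``fit_all`` the
    adjusted Cox model is fitted at every admissible cutoff (non-converging
    rows are flagged and excluded from selection); otherwise only at the
    selected cutoff.  ``horizon`` switches J to the censoring-aware outcome
    (death by the horizon, subjects censored earlier excluded from J).
    """
    n = len(table)
    if n < 20:
        raise ConfigurationError("need n >= 20 subjects")
    validate_survival_table(table)
    j_table, outcome = _binary_outcome(table, horizon)
    expr = table["expression"].to_numpy(dtype=float)
    uniq = np.unique(expr)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    min_group = min_group_frac * n

    rows = []
    for c in candidates:
        high = expr > c
        n_high, n_low = int(high.sum()), int((~high).sum())
        if n_high < min_group or n_low < min_group:
            continue
        yr = youden_index(j_table["expression"].to_numpy() > c, outcome)
        rows.append(
            {
                "cutoff": float(c),
                "n_high": n_high,
                "n_low": n_low,
                "j": yr.j,
                "sensitivity": yr.sensitivity,
                "specificity": yr.specificity,
            }
        )
    if not rows:
        raise ConfigurationError("no admissible cutoff (expression nearly constant?)")
    scan = pd.DataFrame(rows)

    if fit_all:
        fits = [fit_adjusted_ph(table, expr > row.cutoff, covariates) for row in scan.itertuples()]
        scan["coef"] = [f.coef for f in fits]
        scan["se"] = [f.se for f in fits]
        scan["p"] = [f.p for f in fits]
        scan["converged"] = [f.converged for f in fits]
        admissible = scan[scan["converged"]]
        if admissible.empty:
            raise ConfigurationError("no converging admissible cutoff")
    else:
        admissible = scan

    # max J; ties broken toward the smaller cutoff (stable order of candidates)
    best = admissible.loc[admissible["j"].idxmax()]
    fit = fit_adjusted_ph(table, expr > best["cutoff"], covariates)
    return CutoffScanResult(
        table=scan, selected_cutoff=float(best["cutoff"]), j_max=float(best["j"]), fit=fit
    )


@dataclass(frozen=True)
class KMResult:
    """Kaplan-Meier curves per group and the two-sample log-rank test."""

    curves: dict[str, pd.DataFrame]
    statistic: float
    p: float


def km_logrank(table: pd.DataFrame, group: np.ndarray) -> KMResult:
    """Product-limit survival estimates per group plus the log-rank test."""
    group = np.asarray(group, dtype=int)
    if (group == 1).sum() == 0 or (group == 0).sum() == 0:
        raise ConfigurationError("both groups must be nonempty")
    curves = {}
    for g, label in ((0, "low"), (1, "high")):
        mask = group == g
        kmf = KaplanMeierFitter()
        kmf.fit(table.loc[mask, "time"], table.loc[mask, "event"], label=label)
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf[label].to_numpy()}
        )
    res = logrank_test(
        table.loc[group == 0, "time"],
        table.loc[group == 1, "time"],
        event_observed_A=table.loc[group == 0, "event"],
        event_observed_B=table.loc[group == 1, "event"],
    )
    return KMResult(curves=curves, statistic=float(res.test_statistic), p=float(res.p_value))


def km_median(times: np.ndarray, events: np.ndarray) -> float:
    """Kaplan-Meier median survival time of one group."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    return float(kmf.median_survival_time_)
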