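"""Kaplan-Meier curves, log-rank tests, Cox proportional hazards and
forward covariate selection.

The product-limit estimator, log-rank statistic and Efron-tie Cox partial
likelihood are provided by lifelines behind this module's surface; the
forward-selection procedure (candidate entry by Wald p below a cut-off,
default 0.1, with KRAS status always reported in the final model) is
implemented here.  Records flagged ``excluded_from_os`` (e.g. patients
enrolled on interventional trials) are dropped by a generic boolean
filter, and rows with missing covariates are dropped with a log entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .stats import TestResult

logger = logging.getLogger(__name__)

TIME_COL = "os_months"
EVENT_COL = "os_event"


def prepare_records(clinical: pd.DataFrame,
                    exclude_col: str = "excluded_from_os") -> pd.DataFrame:
    """Apply the generic exclusion filter and basic validity checks."""
    df = clinical.copy()
    if exclude_col in df.columns:
        n0 = len(df)
        df = df[~df[exclude_col].astype(bool)]
        if len(df) < n0:
            logger.info("excluded %d records via %s", n0 - len(df), exclude_col)
    if (df[TIME_COL] <= 0).any():
        raise ValueError("survival times must be > 0")
    return df


def km_curve(records: pd.DataFrame, group_col: str) -> pd.DataFrame:
    """Product-limit survival per group: step function plus median
    survival.  Long format with columns group, time, survival, median."""
    rows = []
    for value, sub in records.groupby(group_col):
        if len(sub) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub[TIME_COL], event_observed=sub[EVENT_COL].astype(bool))
        sf = kmf.survival_function_
        median = float(kmf.median_survival_time_)
        for t, s in zip(sf.index, sf.iloc[:, 0]):
            rows.append({"group": value, "time": float(t),
                         "survival": float(s), "median_survival": median})
    return pd.DataFrame(rows)


def logrank(records: pd.DataFrame, group_col: str) -> TestResult:
    """Log-rank test across groups (observed minus expected chi-square
    with hypergeometric variance at each event time)."""
    groups = records[group_col]
    if groups.nunique() < 2:
        raise ValueError("need >= 2 groups")
    if records.groupby(group_col)[EVENT_COL].sum().eq(0).all():
        logger.warning("no events in any group; log-rank is degenerate")
    res = multivariate_logrank_test(records[TIME_COL], groups,
                                    records[EVENT_COL].astype(bool))
    return TestResult(statistic=float(res.test_statistic),
                      p_value=float(res.p_value), method="logrank")


@dataclass
class CoxResult:
    table: pd.DataFrame  # per covariate: beta, hr, se, wald_p, ci95 low/high
    log_likelihood: float
    n: int
    n_events: int
    converged: bool = True
    note: str = ""


def cox_fit(records: pd.DataFrame, covariates: list[str]) -> CoxResult:
    """Cox proportional hazards with Efron tie handling; Wald p per
    coefficient.  Rows with missing covariates are dropped with a log
    entry; monotone-likelihood failures return a flagged result."""
    cols = [TIME_COL, EVENT_COL, *covariates]
    df = records[cols].copy()
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.info("dropped %d records with missing covariates", n0 - len(df))
    n_events = int(df[EVENT_COL].sum())
    if n_events < len(covariates) + 1:
        raise ValueError(f"{n_events} events cannot support "
                         f"{len(covariates)} covariates")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=TIME_COL, event_col=EVENT_COL)
    except ConvergenceError as exc:
        return CoxResult(table=pd.DataFrame(), log_likelihood=np.nan,
                         n=len(df), n_events=n_events, converged=False,
                         note=f"non-convergence (possible complete "
                              f"separation); consider penalization: {exc}")
    summ = cph.summary
    table = pd.DataFrame({
        "covariate": summ.index,
        "beta": summ["coef"].to_numpy(),
        "hr": summ["exp(coef)"].to_numpy(),
        "se": summ["se(coef)"].to_numpy(),
        "wald_p": summ["p"].to_numpy(),
        "ci95_low": np.exp(summ["coef"] - 1.96 * summ["se(coef)"]).to_numpy(),
        "ci95_high": np.exp(summ["coef"] + 1.96 * summ["se(coef)"]).to_numpy(),
    }).reset_index(drop=True)
    return CoxResult(table=table, log_likelihood=float(cph.log_likelihood_),
                     n=len(df), n_events=n_events)


def forward_select(records: pd.DataFrame, candidates: list[str],
                   entry_p: float = 0.1,
                   always_report: str | None = "kras_wildtype"
                   ) -> tuple[list[str], CoxResult]:
    """Forward covariate selection by Wald p of the entering coefficient.

    At each step the candidate with the smallest Wald p (when added to
    the model so far) enters if that p is strictly below ``entry_p``.
    The final model always reports ``always_report`` (the exposure of
    interest) alongside whatever was selected.
    """
    if not candidates:
        raise ValueError("no candidates")
    selected: list[str] = []
    remaining = [c for c in candidates]
    while remaining:
        best_c, best_p = None, np.inf
        for c in remaining:
            try:
                res = cox_fit(records, selected + [c])
            except (ValueError, ConvergenceError):
                continue
            if not res.converged or res.table.empty:
                continue
            p = float(res.table.set_index("covariate").loc[c, "wald_p"])
            if p < best_p:
                best_c, best_p = c, p
        if best_c is None or not (best_p < entry_p):
            break
        selected.append(best_c)
        remaining.remove(best_c)
    final_covs = list(selected)
    if always_report and always_report not in final_covs \
            and always_report in records.columns:
        final_covs.append(always_report)
    if not final_covs:
        return [], CoxResult(table=pd.DataFrame(), log_likelihood=np.nan,
                             n=len(records), n_events=int(records[EVENT_COL].sum()),
                             note="no covariate selected")
    return selected, cox_fit(records, final_covs)
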