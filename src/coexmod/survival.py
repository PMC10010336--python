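"""Survival estimation and testing: Kaplan-Meier, log-rank, Cox regression.

Overall survival (OS) is the time from surgery to death from any cause;
censored observations carry event = 0.  The Kaplan-Meier product-limit
estimator and Cox proportional-hazards fits are delegated to lifelines; the
k-group log-rank test is a direct vectorized implementation of the standard
observed-vs-expected chi-square with hypergeometric variance, which keeps
large calibration simulations cheap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats as sps

from .datatypes import InputContractError
from .stats import TestResult

__all__ = [
    "KMCurve",
    "km_estimate",
    "logrank_test",
    "CoxFit",
    "cox_fit",
    "univariate_then_multivariate_cox",
]

log = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate with its event table."""

    table: pd.DataFrame  # index: time; columns: at_risk, deaths, censored, survival
    median: float | None  # smallest t with S(t) <= 0.5; None if never reached

    def survival_at(self, t: float) -> float:
        s = self.table["survival"]
        past = s[s.index <= t]
        return float(past.iloc[-1]) if len(past) else 1.0


def _check_surv(os_months, os_event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(os_months, dtype=float)
    e = np.asarray(os_event)
    if (t < 0).any():
        raise InputContractError("negative survival times")
    if not np.isin(e, [0, 1]).all():
        raise InputContractError("os_event must be 0 (censored) or 1 (death)")
    return t, e.astype(int)


def km_estimate(os_months, os_event) -> KMCurve:
    """Product-limit survival estimate S(t) = prod_{t_i<=t} (1 - d_i/n_i)."""
    t, e = _check_surv(os_months, os_event)
    if t.size == 0:
        raise InputContractError("need at least one observation")
    kmf = KaplanMeierFitter().fit(t, e)
    surv = kmf.survival_function_["KM_estimate"]
    table = pd.DataFrame({
        "at_risk": kmf.event_table["at_risk"],
        "deaths": kmf.event_table["observed"],
        "censored": kmf.event_table["censored"],
        "survival": surv,
    })
    # keep only actual observation times (drop lifelines' synthetic t=0 row)
    table = table[(table["deaths"] + table["censored"]) > 0]
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KMCurve(table=table, median=median)


def logrank_test(os_months, os_event, groups) -> TestResult:
    """k-group log-rank chi-square test (df = k - 1).

    At each distinct event time the observed deaths per group are compared
    with the expectation under a common hazard; the variance is the
    multivariate hypergeometric one.  Groups with no subjects are rejected.
    """
    t, e = _check_surv(os_months, os_event)
    groups = np.asarray(groups)
    names = pd.unique(groups)
    k = len(names)
    if k < 2:
        raise InputContractError("need >= 2 groups")
    if e.sum() == 0:
        log.warning("logrank_test: no events; statistic 0")
        return TestResult(0.0, 1.0, "logrank", {"df": k - 1})
    gidx = np.array([np.where(names == g)[0][0] for g in groups])
    event_times = np.unique(t[e == 1])
    o_minus_e = np.zeros(k)
    v = np.zeros((k, k))
    for tt in event_times:
        at_risk = t >= tt
        n = at_risk.sum()
        if n < 2:
            continue
        d = int(((t == tt) & (e == 1)).sum())
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gidx[(t == tt) & (e == 1)], minlength=k).astype(float)
        frac = n_g / n
        o_minus_e += d_g - d * frac
        coef = d * (n - d) / (n - 1)
        v += coef * (np.diag(frac) - np.outer(frac, frac))
    sub = slice(0, k - 1)
    vi = np.linalg.pinv(v[sub, sub])
    chi2 = float(o_minus_e[sub] @ vi @ o_minus_e[sub])
    p = float(sps.chi2.sf(chi2, df=k - 1))
    return TestResult(chi2, p, "logrank", {"df": k - 1, "observed_minus_expected":
                                           dict(zip(map(str, names), o_minus_e))})


@dataclass
class CoxFit:
    """Cox proportional-hazards fit (log hazard ratios per covariate)."""

    coefficients: pd.Series
    standard_errors: pd.Series
    p_values: pd.Series
    converged: bool
    extras: dict = field(default_factory=dict)

    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coefficients)


def cox_fit(os_months, os_event, covariates: pd.DataFrame) -> CoxFit:
    """Cox partial-likelihood fit with Efron tie handling.

    ``covariates`` is a samples x q frame of numeric covariates.  Returns
    coefficients, standard errors from the inverse information, Wald
    p-values, and a convergence flag (monotone likelihood / separation is
    reported as non-converged with the last iterate's coefficients).
    """
    t, e = _check_surv(os_months, os_event)
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    if cov.shape[1] < 1:
        raise InputContractError("need at least one covariate")
    if (cov.nunique() <= 1).any():
        bad = list(cov.columns[cov.nunique() <= 1])
        raise InputContractError(f"constant covariates: {bad}")
    df = cov.copy()
    df["os_months"], df["os_event"] = t, e
    fitter = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fitter.fit(df, duration_col="os_months", event_col="os_event")
        except ConvergenceError:
            converged = False
            log.warning("cox_fit: Newton-Raphson failed to converge; refitting with ridge")
            fitter = CoxPHFitter(penalizer=1e-6)
            fitter.fit(df, duration_col="os_months", event_col="os_event")
    s = fitter.summary
    return CoxFit(
        coefficients=s["coef"].rename(None),
        standard_errors=s["se(coef)"].rename(None),
        p_values=s["p"].rename(None),
        converged=converged,
        extras={"log_likelihood": float(fitter.log_likelihood_)},
    )


def univariate_then_multivariate_cox(
    os_months, os_event, covariates: pd.DataFrame, screen_p: float = 0.1
) -> tuple[pd.DataFrame, CoxFit | None]:
    """Univariate Cox screen, then a multivariate model of the survivors.

    Each covariate is fit alone; covariates with univariate Wald p below
    ``screen_p`` enter a joint multivariate fit (None if fewer than one
    survives).  Returns (univariate table, multivariate fit).
    """
    rows = []
    for col in covariates.columns:
        fit = cox_fit(os_months, os_event, covariates[[col]])
        rows.append({"covariate": col, "coef": fit.coefficients.iloc[0],
                     "hr": float(np.exp(fit.coefficients.iloc[0])),
                     "se": fit.standard_errors.iloc[0], "p": fit.p_values.iloc[0]})
    uni = pd.DataFrame(rows).set_index("covariate")
    keep = uni.index[uni["p"] < screen_p]
    multi = cox_fit(os_months, os_event, covariates[list(keep)]) if len(keep) >= 1 else None
    return uni, multi
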