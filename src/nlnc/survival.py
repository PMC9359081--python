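"""Survival evaluation of risk scores: Kaplan–Meier curves, log-rank tests,
multivariable Cox independence, time-dependent IPCW AUC and Harrell's C."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index as _ll_cindex
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .io import validate_clinical

logger = logging.getLogger("nlnc")

__all__ = [
    "km_estimate",
    "logrank_test",
    "multivariable_cox",
    "time_dependent_auc",
    "concordance_index",
    "evaluate_risk",
]


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.size == 0:
        raise ValueError("empty survival input")
    if np.any(t <= 0):
        raise ValueError("survival times must be > 0")
    if not np.isin(e, [0.0, 1.0]).all():
        raise ValueError("event indicator must be 0 or 1")
    return t, e.astype(int)


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct event time with the number at risk, the
    number of events and the survival estimate just after that time.
    Censoring at a tied time is handled events-first (the censored subject
    counts as at risk for the tied event).
    """
    t, e = _as_arrays(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    tab = kmf.event_table
    tab = tab[tab["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"].reindex(tab.index)
    return pd.DataFrame({
        "event_time": tab.index.to_numpy(dtype=float),
        "at_risk": tab["at_risk"].to_numpy(dtype=int),
        "n_events": tab["observed"].to_numpy(dtype=int),
        "survival": surv.to_numpy(dtype=float),
    }).reset_index(drop=True)


def logrank_test(group_a, group_b) -> tuple[float, float]:
    """Two-group Mantel–Haenszel log-rank test; returns (chi-square, p)."""
    ta, ea = _as_arrays(*group_a)
    tb, eb = _as_arrays(*group_b)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def multivariable_cox(
    clinical: pd.DataFrame,
    scores: pd.Series,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Cox model of the risk score adjusted for clinical covariates.

    Categorical covariates are one-hot encoded against a reference level;
    rows with missing covariates are list-wise deleted (count logged).
    Returns a per-term summary (beta, SE, HR, CI95, Wald p); the score's row
    answers whether the signature is prognostic independently of the
    covariates.  A covariate-free call reduces to univariate Cox on the
    score.
    """
    clinical = validate_clinical(clinical.loc[scores.index])
    df = clinical[["time", "event"]].copy()
    df["score"] = scores
    if covariates:
        cov = clinical[covariates]
        cov = pd.get_dummies(cov, drop_first=True, dtype=float)
        df = pd.concat([df, cov], axis=1)
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.info("multivariable Cox dropped %d row(s) with missing covariates", n0 - len(df))
    X = df.drop(columns=["time", "event"]).to_numpy()
    cond = np.linalg.cond(X - X.mean(axis=0))
    if cond > 1e8:
        raise ValueError(f"collinear design (condition number {cond:.2e})")
    cph = CoxPHFitter()
    try:
        cph.fit(df, "time", "event")
    except Exception as exc:
        raise ValueError(f"Cox model failed to converge: {exc}") from exc
    s = cph.summary
    return pd.DataFrame({
        "beta": s["coef"],
        "se": s["se(coef)"],
        "hr": np.exp(s["coef"]),
        "ci_low": np.exp(s["coef"] - 1.96 * s["se(coef)"]),
        "ci_high": np.exp(s["coef"] + 1.96 * s["se(coef)"]),
        "p": s["p"],
    })


def time_dependent_auc(
    scores: pd.Series,
    clinical: pd.DataFrame,
    horizons=(1.0, 3.0, 5.0),
) -> pd.Series:
    """Cumulative/dynamic AUC at fixed horizons with IPCW weights from the
    Kaplan–Meier censoring distribution.

    At horizon t, cases are subjects with an observed event by t and controls
    are subjects event-free past t; score ties receive half credit.  A
    horizon with no cases or no controls is reported as NaN with a warning.
    With no censoring before t the weights are uniform and the estimate
    equals the plain empirical AUC of the binary outcome "event by t".
    """
    clinical = validate_clinical(clinical.loc[scores.index])
    t = clinical["time"].to_numpy()
    e = clinical["event"].to_numpy().astype(bool)
    y = Surv.from_arrays(e, t)
    out = {}
    for h in horizons:
        h = float(h)
        n_cases = int(np.sum(e & (t <= h)))
        n_controls = int(np.sum(t > h))
        if n_cases == 0 or n_controls == 0 or h >= t.max():
            warnings.warn(f"AUC undefined at horizon {h}: "
                          f"{n_cases} case(s), {n_controls} control(s)", stacklevel=2)
            out[h] = np.nan
            continue
        auc, _ = cumulative_dynamic_auc(y, y, scores.to_numpy(), [h])
        out[h] = float(auc[0])
    return pd.Series(out, name="auc")


def concordance_index(scores: pd.Series, clinical: pd.DataFrame) -> float:
    """Harrell's C for a risk score (higher score = higher risk).

    Usable pairs are those where the shorter observed time carries an event;
    score ties count 0.5.
    """
    clinical = validate_clinical(clinical.loc[scores.index])
    # lifelines' convention is concordance with predicted *survival*, so the
    # risk score is negated.
    return float(_ll_cindex(clinical["time"], -scores.to_numpy(), clinical["event"]))


def evaluate_risk(
    risk_table: pd.DataFrame,
    clinical: pd.DataFrame,
    horizons=(1.0, 3.0, 5.0),
    covariates: list[str] | None = None,
) -> dict:
    """One-call evaluation of a dichotomized risk table.

    Computes per-group KM curves, the high-vs-low log-rank test, the
    multivariable Cox independence check, time-dependent AUC at the given
    horizons, and Harrell's C.
    """
    clinical = validate_clinical(clinical.loc[risk_table.index])
    hi = risk_table["group"] == "high"
    km = {
        grp: km_estimate(clinical.loc[mask, "time"], clinical.loc[mask, "event"])
        for grp, mask in (("high", hi), ("low", ~hi))
        if mask.any()
    }
    if hi.any() and (~hi).any():
        chi2, p = logrank_test(
            (clinical.loc[hi, "time"], clinical.loc[hi, "event"]),
            (clinical.loc[~hi, "time"], clinical.loc[~hi, "event"]),
        )
    else:
        chi2, p = np.nan, np.nan
    scores = risk_table["score"]
    return {
        "km": km,
        "logrank_chi2": chi2,
        "logrank_p": p,
        "cox": multivariable_cox(clinical, scores, covariates),
        "auc": time_dependent_auc(scores, clinical, horizons),
        "c_index": concordance_index(scores, clinical),
    }
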