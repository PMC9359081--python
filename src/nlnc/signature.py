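"""Prognostic lncRNA signature: univariate Cox consistency screen across
cohorts, cross-validated LASSO-Cox, multivariable pruning, and linear risk
scoring with dichotomization.

The signature's risk score is a linear combination

    score(sample) = sum_i  z_i(sample) * coefficient_i

over the selected lncRNAs, where ``z_i`` is z-scored expression and the
coefficients are the L1-penalised Cox coefficients at the cross-validated
penalty (the multivariable refit only prunes non-significant features; the
retained features' coefficients are re-extracted from a restricted LASSO fit
at the same penalty).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .io import ExpressionMatrix, align_samples, validate_clinical

logger = logging.getLogger("nlnc")

__all__ = [
    "zscore_normalize",
    "breslow_partial_loglik",
    "univariate_cox_screen",
    "fit_lasso_cox_cv",
    "multivariate_cox_refit",
    "SignatureModel",
    "compute_risk_score",
    "dichotomize",
    "build_signature",
]


def zscore_normalize(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Per-gene z-score across samples; returns the matrix and a mean/SD
    record for applying the same transform to held-out samples.

    Constant genes become all-zero rows (SD recorded as 0) with a warning.
    """
    vals = matrix.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant feature(s) z-scored to zero",
                      stacklevel=2)
    safe_sd = sd.mask(constant, 1.0)
    z = vals.sub(mean, axis=0).div(safe_sd, axis=0)
    z[constant] = 0.0
    record = pd.DataFrame({"mean": mean, "sd": sd})
    return ExpressionMatrix(z, matrix.biotype), record


def apply_normalization(values: pd.DataFrame, record: pd.DataFrame) -> pd.DataFrame:
    """Apply a stored mean/SD record to a genes x samples frame."""
    rec = record.loc[values.index]
    sd = rec["sd"].mask(rec["sd"] == 0, 1.0)
    z = values.sub(rec["mean"], axis=0).div(sd, axis=0)
    z[rec["sd"] == 0] = 0.0
    return z


def breslow_partial_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Cox partial log-likelihood with Breslow handling of tied event times."""
    order = np.argsort(time, kind="stable")
    t, e, x = time[order], event[order], lp[order]
    # log-sum-exp over risk sets (suffixes); ties share the full risk set
    rev = np.logaddexp.accumulate(x[::-1])[::-1]
    first = np.searchsorted(t, t, side="left")
    return float(np.sum((x - rev[first])[e == 1]))


# ---------------------------------------------------------------------------
# Univariate consistency screen
# ---------------------------------------------------------------------------

def _fit_univariate(x: pd.Series, clinical: pd.DataFrame) -> tuple[float, float] | None:
    df = pd.DataFrame({"time": clinical["time"], "event": clinical["event"], "x": x})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, "time", "event")
    except Exception as exc:  # non-convergence: exclude with reason
        logger.warning("univariate Cox failed for %r: %s", x.name, exc)
        return None
    return float(cph.params_["x"]), float(cph.summary.loc["x", "p"])


def univariate_cox_screen(
    cohorts: list[tuple[ExpressionMatrix, pd.DataFrame]],
    features: list[str] | None = None,
    p_threshold: float = 0.15,
) -> tuple[list[str], pd.DataFrame]:
    """Single-covariate Cox fits per feature per cohort.

    A feature is a candidate iff its unadjusted p-value is below
    ``p_threshold`` in *every* cohort and its hazard-ratio direction is
    identical in every cohort.  The threshold is deliberately lenient and
    unadjusted — aggressive multiplicity correction at this stage would
    discard weak but consistent prognostic features before the penalised fit.

    Returns the candidate list and the full per-(feature, cohort) table.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    if features is None:
        features = list(cohorts[0][0].lncrna_ids)
    rows = []
    for c, (expr, clinical) in enumerate(cohorts):
        clinical = validate_clinical(clinical)
        expr, clinical = align_samples(expr, clinical, intersect=False)
        for fid in features:
            res = _fit_univariate(expr.values.loc[fid], clinical)
            if res is None:
                continue
            beta, p = res
            rows.append({"feature_id": fid, "cohort_id": c, "beta": beta,
                         "hr": float(np.exp(beta)), "p": p})
    table = pd.DataFrame(rows, columns=["feature_id", "cohort_id", "beta", "hr", "p"])
    n_cohorts = len(cohorts)
    candidates = []
    for fid, grp in table.groupby("feature_id", sort=False):
        if len(grp) < n_cohorts:
            continue  # failed to converge somewhere
        if (grp["p"] < p_threshold).all() and len(set(np.sign(grp["beta"]))) == 1:
            candidates.append(fid)
    candidates = [f for f in features if f in set(candidates)]  # stable order
    return candidates, table


# ---------------------------------------------------------------------------
# LASSO-Cox with cross-validated penalty
# ---------------------------------------------------------------------------

@dataclass
class SignatureModel:
    """Selected lncRNAs, their coefficients, the training penalty, and the
    per-feature normalization constants needed to score new samples."""

    feature_ids: list[str]
    coefficients: list[float]
    training_lambda: float
    normalization: pd.DataFrame = field(repr=False)  # index=feature, cols mean/sd

    def __post_init__(self) -> None:
        if len(self.feature_ids) != len(self.coefficients):
            raise ValueError("one coefficient per feature required")
        if any(c == 0 for c in self.coefficients):
            raise ValueError("signature coefficients must be non-zero")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_ids": self.feature_ids,
            "coefficients": list(map(float, self.coefficients)),
            "training_lambda": self.training_lambda,
            "normalization": {
                "mean": self.normalization["mean"].loc[self.feature_ids].tolist(),
                "sd": self.normalization["sd"].loc[self.feature_ids].tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        d = json.loads(Path(path).read_text())
        norm = pd.DataFrame(d["normalization"], index=d["feature_ids"])
        return cls(d["feature_ids"], d["coefficients"], d["training_lambda"], norm)


@dataclass
class LassoCoxCVResult:
    lambda_path: np.ndarray
    cv_deviance: np.ndarray  # mean deviance per lambda
    chosen_lambda: float
    model: SignatureModel | None
    coef_path: pd.DataFrame  # features x lambdas, full-data fit


def _surv_y(clinical: pd.DataFrame):
    return Surv.from_arrays(clinical["event"].astype(bool).to_numpy(),
                            clinical["time"].to_numpy())


def fit_lasso_cox_cv(
    X: pd.DataFrame,
    clinical: pd.DataFrame,
    n_folds: int = 10,
    seed: int | None = None,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
) -> LassoCoxCVResult:
    """L1-penalised Cox over a log-spaced penalty path with K-fold CV.

    ``X`` is samples x features (z-scored).  The path runs from the smallest
    penalty that zeroes every coefficient down to ``lambda_min_ratio`` times
    it.  Folds are stratified by event status; the chosen penalty minimises
    the mean cross-validated partial-likelihood deviance, computed by the
    subtraction method: for fold k with coefficients ``b_k``,
    ``dev_k = -2 * (loglik_all(b_k) - loglik_train(b_k))`` (Breslow ties).
    """
    clinical = validate_clinical(clinical.loc[X.index])
    events = clinical["event"].to_numpy()
    if events.sum() < n_folds:
        raise ValueError(f"need at least {n_folds} events for {n_folds}-fold CV")
    y = _surv_y(clinical)
    Xv = X.to_numpy()

    path = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_lambdas, alpha_min_ratio=lambda_min_ratio,
        max_iter=100000,
    )
    path.fit(Xv, y)
    lambdas = np.asarray(path.alphas_)
    coef_path = pd.DataFrame(path.coef_, index=X.columns, columns=lambdas)

    rng = np.random.default_rng(seed)
    t_arr = clinical["time"].to_numpy()
    for attempt in range(10):
        fold_seed = int(rng.integers(2**31))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
        folds = list(skf.split(Xv, events))
        if all(events[tr].sum() > 0 for tr, _ in folds):
            break
    else:
        raise ValueError("could not build folds with events in every training set")

    dev = np.full((n_folds, len(lambdas)), np.nan)
    for k, (tr, _te) in enumerate(folds):
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=lambdas, max_iter=100000)
        m.fit(Xv[tr], y[tr])
        betas = m.coef_  # features x (possibly truncated) lambdas
        lp_all = Xv @ betas
        for j in range(betas.shape[1]):  # fitted path is a prefix of `lambdas`
            ll_all = breslow_partial_loglik(lp_all[:, j], t_arr, events)
            ll_tr = breslow_partial_loglik(lp_all[tr, j], t_arr[tr], events[tr])
            dev[k, j] = -2.0 * (ll_all - ll_tr)
    valid = ~np.isnan(dev).any(axis=0)  # lambdas evaluated in every fold
    cv_dev = np.where(valid, np.nanmean(dev, axis=0), np.inf)
    best = int(np.argmin(cv_dev))
    chosen = float(lambdas[best])

    coefs = coef_path.iloc[:, best]
    nonzero = coefs[coefs != 0]
    model = None
    if len(nonzero):
        norm = pd.DataFrame({"mean": 0.0, "sd": 1.0}, index=nonzero.index)
        model = SignatureModel(list(nonzero.index), nonzero.tolist(), chosen, norm)
    else:
        logger.warning("chosen penalty leaves no non-zero coefficients")
    return LassoCoxCVResult(lambdas, cv_dev, chosen, model, coef_path)


def refit_lasso_at_lambda(
    X: pd.DataFrame, clinical: pd.DataFrame, features: list[str], lam: float
) -> pd.Series:
    """Coefficients of an L1 Cox fit restricted to ``features`` at penalty
    ``lam`` (used to re-extract scoring weights after multivariable pruning)."""
    clinical = validate_clinical(clinical.loc[X.index])
    m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[lam], max_iter=100000)
    m.fit(X[features].to_numpy(), _surv_y(clinical))
    return pd.Series(m.coef_[:, 0], index=features)


def multivariate_cox_refit(
    X: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Unpenalised multivariable Cox on the selected features.

    Returns the per-feature summary (beta, SE, HR, CI95, Wald p) and the
    features with Wald p below ``alpha``.
    """
    if X.shape[1] == 0:
        raise ValueError("no features to refit")
    cond = np.linalg.cond(X.to_numpy() - X.to_numpy().mean(axis=0))
    if cond > 1e8:
        raise ValueError(
            f"collinear features (condition number {cond:.2e}): {list(X.columns)}"
        )
    clinical = validate_clinical(clinical.loc[X.index])
    df = pd.concat([clinical[["time", "event"]], X], axis=1)
    cph = CoxPHFitter()
    cph.fit(df, "time", "event")
    summ = cph.summary
    out = pd.DataFrame({
        "beta": summ["coef"],
        "se": summ["se(coef)"],
        "hr": np.exp(summ["coef"]),
        "ci_low": np.exp(summ["coef"] - 1.96 * summ["se(coef)"]),
        "ci_high": np.exp(summ["coef"] + 1.96 * summ["se(coef)"]),
        "p": summ["p"],
    })
    retained = [f for f in X.columns if out.loc[f, "p"] < alpha]
    return out, retained


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def compute_risk_score(
    matrix: ExpressionMatrix,
    model: SignatureModel,
    renormalize: bool = False,
) -> pd.Series:
    """Linear risk score per sample: sum of z-scored expression times
    coefficient over the model's features.

    With ``renormalize=True`` z-scoring uses the scored cohort's own
    means/SDs (per-cohort z-scoring, the default behaviour of the pipeline);
    otherwise the model's stored training constants are applied.
    """
    missing = [f for f in model.feature_ids if f not in matrix.gene_ids]
    if missing:
        raise ValueError(f"expression matrix lacks model feature(s): {missing}")
    vals = matrix.values.loc[model.feature_ids]
    if renormalize:
        sd = vals.std(axis=1, ddof=0).mask(lambda s: s == 0, 1.0)
        z = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0)
    else:
        z = apply_normalization(vals, model.normalization)
    coef = pd.Series(model.coefficients, index=model.feature_ids)
    return z.mul(coef, axis=0).sum(axis=0).rename("risk_score")


def dichotomize(
    scores: pd.Series,
    clinical: pd.DataFrame | None = None,
    method: str = "median",
    min_group_fraction: float = 0.1,
) -> tuple[pd.DataFrame, float]:
    """Split samples into high/low risk at a cutoff.

    ``median`` uses the sample median; ``optimal_logrank`` scans candidate
    cutoffs (midpoints between adjacent distinct scores that leave at least
    ``min_group_fraction`` of samples in each group) and keeps the one
    maximising the two-group log-rank statistic.  Samples with score strictly
    above the cutoff are "high"; ties go to "low".
    """
    if len(scores) < 4:
        raise ValueError("need at least 4 samples to dichotomize")
    if scores.nunique() == 1:
        raise ValueError("all scores identical; no cutoff exists")
    if method == "median":
        cutoff = float(scores.median())
    elif method == "optimal_logrank":
        if clinical is None:
            raise ValueError("optimal_logrank requires a clinical table")
        from .survival import logrank_test
        clinical = validate_clinical(clinical.loc[scores.index])
        srt = np.sort(scores.unique())
        mids = (srt[:-1] + srt[1:]) / 2.0
        n = len(scores)
        best_stat, cutoff = -np.inf, None
        for c in mids:
            hi = scores > c
            n_hi = int(hi.sum())
            if min(n_hi, n - n_hi) < min_group_fraction * n:
                continue
            stat, _ = logrank_test(
                (clinical.loc[hi, "time"], clinical.loc[hi, "event"]),
                (clinical.loc[~hi, "time"], clinical.loc[~hi, "event"]),
            )
            if stat > best_stat:
                best_stat, cutoff = stat, float(c)
        if cutoff is None:
            raise ValueError("no cutoff satisfies the group-size constraint")
    else:
        raise ValueError(f"unknown method {method!r}")
    group = np.where(scores > cutoff, "high", "low")
    table = pd.DataFrame({"score": scores, "group": group})
    return table, cutoff


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def build_signature(
    cohorts: list[tuple[ExpressionMatrix, pd.DataFrame]],
    candidate_ids: list[str],
    train_cohort: int = 0,
    p_threshold: float = 0.15,
    n_folds: int = 10,
    mv_alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[SignatureModel, dict]:
    """Full signature construction from screened candidate lncRNAs.

    Steps: per-cohort z-scoring of the candidates; univariate Cox consistency
    screen across all cohorts (p < ``p_threshold`` everywhere, same HR
    direction); 10-fold cross-validated LASSO-Cox on the training cohort;
    multivariable Cox pruning at Wald p < ``mv_alpha``; re-extraction of
    LASSO coefficients restricted to the retained features at the chosen
    penalty.  Returns the model plus a diagnostics dict.
    """
    if not candidate_ids:
        raise ValueError("no candidate features to build a signature from")
    z_cohorts = []
    norms = []
    for expr, clinical in cohorts:
        sub = expr.subset_genes([g for g in candidate_ids if g in expr.gene_ids])
        z, rec = zscore_normalize(sub)
        z_cohorts.append((z, clinical))
        norms.append(rec)

    uni_candidates, uni_table = univariate_cox_screen(z_cohorts, candidate_ids, p_threshold)
    if not uni_candidates:
        raise ValueError("univariate consistency screen retained no feature")

    expr_tr, clin_tr = z_cohorts[train_cohort]
    expr_tr, clin_tr = align_samples(expr_tr, clin_tr)
    X = expr_tr.values.loc[uni_candidates].T
    cv = fit_lasso_cox_cv(X, clin_tr, n_folds=n_folds, seed=seed)
    if cv.model is None:
        raise ValueError("LASSO selected no features at the chosen penalty")
    selected = cv.model.feature_ids

    mv_table, retained = multivariate_cox_refit(X[selected], clin_tr, alpha=mv_alpha)
    if retained:
        coefs = refit_lasso_at_lambda(X, clin_tr, retained, cv.chosen_lambda)
        coefs = coefs[coefs != 0]
    else:
        coefs = pd.Series(dtype=float)
    if not len(coefs):
        logger.warning("multivariable pruning removed every feature; "
                       "keeping the unpruned LASSO model")
        coefs = pd.Series(cv.model.coefficients, index=selected)
        retained = selected

    norm = norms[train_cohort].loc[coefs.index]
    model = SignatureModel(list(coefs.index), coefs.tolist(), cv.chosen_lambda, norm)
    report = {
        "univariate_candidates": uni_candidates,
        "univariate_table": uni_table,
        "lasso_selected": selected,
        "cv": cv,
        "multivariate_table": mv_table,
        "retained": retained,
    }
    return model, report
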