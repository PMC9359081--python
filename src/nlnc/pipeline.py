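"""End-to-end orchestration: coverage filter -> driver screen per cohort ->
cross-cohort combination -> signature construction -> risk scoring and
survival evaluation."""

from __future__ import annotations

import logging

import pandas as pd

from .io import ExpressionMatrix, filter_low_coverage_lncrnas
from .screen import combine_driver_sets, screen_nlncers
from .signature import SignatureModel, build_signature, compute_risk_score, dichotomize
from .survival import evaluate_risk

logger = logging.getLogger("nlnc")


def run_pipeline(
    cohorts: list[tuple[ExpressionMatrix, pd.Series, pd.DataFrame]],
    notch_set: list[str],
    n_perm: int = 1000,
    fdr_threshold: float = 0.05,
    nes_threshold: float = 0.995,
    combine: str = "intersection",
    train_cohort: int = 0,
    p_uni: float = 0.15,
    n_folds: int = 10,
    mv_alpha: float = 0.05,
    cutoff_method: str = "median",
    horizons=(1.0, 3.0, 5.0),
    seed: int | None = None,
    heldout: tuple[ExpressionMatrix, pd.DataFrame] | None = None,
) -> dict:
    """Run the full screen-to-evaluation pipeline on one or more cohorts.

    ``cohorts`` are (expression, purity, clinical) triples; the driver screen
    runs per cohort and the per-cohort driver sets are combined by
    ``combine`` (intersection by default).  The signature is trained on
    ``cohorts[train_cohort]`` and every cohort — plus an optional held-out
    (expression, clinical) pair — is scored with per-cohort z-scoring and
    evaluated (KM/log-rank, Cox, time-dependent AUC, C-index).
    """
    screens = []
    filtered = []
    for expr, purity, clinical in cohorts:
        expr_f, _removed = filter_low_coverage_lncrnas(expr)
        filtered.append((expr_f, purity, clinical))
        screens.append(
            screen_nlncers(
                expr_f, purity, notch_set, n_perm=n_perm,
                fdr_threshold=fdr_threshold, nes_threshold=nes_threshold, seed=seed,
            )
        )
    drivers = combine_driver_sets(screens, how=combine)
    logger.info("combined driver set (%s): %d lncRNA(s)", combine, len(drivers))
    if not drivers:
        return {"screens": screens, "drivers": [], "model": None, "evaluations": {}}

    model, report = build_signature(
        [(expr, clin) for expr, _p, clin in filtered],
        drivers, train_cohort=train_cohort, p_threshold=p_uni,
        n_folds=n_folds, mv_alpha=mv_alpha, seed=seed,
    )

    evaluations = {}
    risk_tables = {}
    for c, (expr, _purity, clinical) in enumerate(filtered):
        scores = compute_risk_score(expr, model, renormalize=True)
        table, cutoff = dichotomize(scores, clinical, method=cutoff_method)
        risk_tables[c] = (table, cutoff)
        evaluations[c] = evaluate_risk(table, clinical, horizons=horizons)
    if heldout is not None:
        expr_h, clin_h = heldout
        scores = compute_risk_score(expr_h, model, renormalize=True)
        table, cutoff = dichotomize(scores, clin_h, method=cutoff_method)
        risk_tables["heldout"] = (table, cutoff)
        evaluations["heldout"] = evaluate_risk(table, clin_h, horizons=horizons)

    return {
        "screens": screens,
        "drivers": drivers,
        "model": model,
        "signature_report": report,
        "risk_tables": risk_tables,
        "evaluations": evaluations,
    }
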