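"""Purity-adjusted screening of pathway-derived lncRNA drivers.

Bulk co-expression between a lncRNA and an mRNA is confounded by tumour
purity: both track the malignant-cell fraction of the sample.  The screen
therefore ranks, for every lncRNA, all mRNAs by a signed index built from the
first-order partial correlation given purity,

    PCC = (R_lm - R_lp * R_mp) / sqrt((1 - R_lp^2) * (1 - R_mp^2))
    P   = 2 * Phi(-|PCC * sqrt(n - 3) / sqrt(1 - PCC^2)|)
    NI  = -ln(P) * sign(PCC)

and asks whether the pathway gene set concentrates at either extreme of that
ranking (weighted-KS enrichment with a gene-label permutation null).  Each
lncRNA's adjusted p-value and enrichment-score sign are folded into a bounded
normalised enrichment score

    NES = (1 - 2 * P_adj) * sign(ES)  in [-1, 1],

and drivers are the lncRNAs with ``P_adj < 0.05`` and ``|NES| > 0.995``
(both strict).  Note the algebra of the filter: ``|NES| > 0.995`` already
implies ``P_adj < 0.0025``.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import (
    bh_adjust,
    derive_rng,
    enrichment_score,
    make_ranked_list,
    permutation_null_es,
)
from .io import ExpressionMatrix, align_samples, validate_purity

logger = logging.getLogger("nlnc")

P_FLOOR = 1e-300  # keeps -ln(P) finite without perturbing any ranking
_CLAMP = 1.0 - 1e-12


def partial_correlation(lnc: np.ndarray, mrna: np.ndarray, purity: np.ndarray) -> float:
    """First-order partial correlation of two vectors given one control.

    Pairwise-complete observations are used.  Mathematically identical to the
    Pearson correlation of the residuals after regressing each variable on
    the control.  The result is clamped just inside (-1, 1) so the downstream
    z-transform stays finite.
    """
    lnc = np.asarray(lnc, dtype=float)
    mrna = np.asarray(mrna, dtype=float)
    purity = np.asarray(purity, dtype=float)
    if not (len(lnc) == len(mrna) == len(purity)):
        raise ValueError("vectors must have equal length")
    ok = ~(np.isnan(lnc) | np.isnan(mrna) | np.isnan(purity))
    lnc, mrna, purity = lnc[ok], mrna[ok], purity[ok]
    if len(lnc) < 4:
        raise ValueError("need at least 4 complete observations")
    for name, v in (("lnc", lnc), ("mrna", mrna), ("purity", purity)):
        if np.std(v) == 0:
            raise ValueError(f"{name} vector is constant")
    r_lm = np.corrcoef(lnc, mrna)[0, 1]
    r_lp = np.corrcoef(lnc, purity)[0, 1]
    r_mp = np.corrcoef(mrna, purity)[0, 1]
    if abs(r_lp) >= 1 - 1e-12 or abs(r_mp) >= 1 - 1e-12:
        raise ValueError("a variable is perfectly correlated with purity")
    pcc = (r_lm - r_lp * r_mp) / math.sqrt((1 - r_lp**2) * (1 - r_mp**2))
    return float(np.clip(pcc, -_CLAMP, _CLAMP))


def pcc_pvalue(pcc: float | np.ndarray, n: int | np.ndarray) -> float | np.ndarray:
    """Two-sided normal-approximation p-value for a first-order partial
    correlation with one control variable: z = pcc*sqrt(n-3)/sqrt(1-pcc^2).

    The p-value is floored at a tiny positive constant so that downstream
    log transforms remain finite.
    """
    pcc = np.asarray(pcc, dtype=float)
    n = np.asarray(n)
    if np.any(np.abs(pcc) >= 1):
        raise ValueError("|pcc| must be < 1")
    if np.any(n < 4):
        raise ValueError("n must be >= 4")
    z = pcc * np.sqrt(n - 3) / np.sqrt(1 - pcc**2)
    p = 2.0 * stats.norm.cdf(-np.abs(z))
    p = np.maximum(p, P_FLOOR)
    return float(p) if p.ndim == 0 else p


def notch_pair_index(pcc: float | np.ndarray, p: float | np.ndarray) -> float | np.ndarray:
    """Signed pair index ``-ln(p) * sign(pcc)`` (zero when pcc is zero)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p must lie in (0, 1] (floor it upstream)")
    ni = -np.log(p) * np.sign(pcc)
    return float(ni) if ni.ndim == 0 else ni


# ---------------------------------------------------------------------------
# Vectorised pair statistics
# ---------------------------------------------------------------------------

def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd, ok


def pairwise_partial_correlation(
    lnc_values: np.ndarray,
    mrna_values: np.ndarray,
    purity: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partial correlations of every (lncRNA, mRNA) pair given purity.

    Complete-data fast path: one matrix product yields all Pearson
    correlations, then the first-order formula is applied elementwise.
    Returns ``(pcc, lnc_ok, mrna_ok)`` where the ``ok`` masks flag rows that
    are non-constant and not perfectly purity-correlated; excluded rows carry
    NaN in ``pcc``.
    """
    n = lnc_values.shape[1]
    ls, l_ok = _standardize_rows(lnc_values)
    ms, m_ok = _standardize_rows(mrna_values)
    ps = (purity - purity.mean()) / purity.std()
    r_lm = ls @ ms.T / n
    r_lp = ls @ ps / n
    r_mp = ms @ ps / n
    l_ok &= np.abs(r_lp) < 1
    m_ok &= np.abs(r_mp) < 1
    denom = np.sqrt(np.clip((1 - r_lp**2)[:, None] * (1 - r_mp**2)[None, :], 1e-300, None))
    pcc = (r_lm - np.outer(r_lp, r_mp)) / denom
    pcc = np.clip(pcc, -_CLAMP, _CLAMP)
    pcc[~l_ok, :] = np.nan
    pcc[:, ~m_ok] = np.nan
    return pcc, l_ok, m_ok


def pair_records(
    matrix: ExpressionMatrix,
    lnc_id: str,
    purity: pd.Series,
) -> pd.DataFrame:
    """PCC / p / NI records of one lncRNA against every usable mRNA."""
    purity = validate_purity(purity)
    matrix, purity = align_samples(matrix, purity)
    mrna_ids = matrix.mrna_ids
    if len(mrna_ids) < 2:
        raise ValueError("need at least 2 mRNA rows")
    lnc = matrix.values.loc[lnc_id].to_numpy()
    rows = []
    has_nan = np.isnan(matrix.values.to_numpy()).any() or np.isnan(purity.to_numpy()).any()
    if has_nan:
        for mid in mrna_ids:
            m = matrix.values.loc[mid].to_numpy()
            try:
                pcc = partial_correlation(lnc, m, purity.to_numpy())
            except ValueError:
                continue
            n_used = int(np.sum(~(np.isnan(lnc) | np.isnan(m) | np.isnan(purity.to_numpy()))))
            p = pcc_pvalue(pcc, n_used)
            rows.append((mid, pcc, p, notch_pair_index(pcc, p), n_used))
    else:
        pcc, l_ok, m_ok = pairwise_partial_correlation(
            lnc[None, :], matrix.values.loc[mrna_ids].to_numpy(), purity.to_numpy()
        )
        if not l_ok[0]:
            raise ValueError(f"lncRNA {lnc_id!r} is degenerate (constant or purity-collinear)")
        n = matrix.n_samples
        for j, mid in enumerate(mrna_ids):
            if not m_ok[j]:
                continue
            p = pcc_pvalue(pcc[0, j], n)
            rows.append((mid, float(pcc[0, j]), p, notch_pair_index(pcc[0, j], p), n))
    if not rows:
        raise ValueError("every mRNA was excluded as degenerate")
    return pd.DataFrame(rows, columns=["mrna_id", "pcc", "p", "ni", "n_used"])


def build_ranked_list(
    matrix: ExpressionMatrix,
    lnc_id: str,
    purity: pd.Series,
) -> pd.Series:
    """Rank all mRNAs by the signed pair index NI, descending (ties by id)."""
    if matrix.biotype[lnc_id] != "lncRNA":
        raise ValueError(f"{lnc_id!r} is not a lncRNA row")
    rec = pair_records(matrix, lnc_id, purity)
    return make_ranked_list(pd.Series(rec["ni"].to_numpy(), index=rec["mrna_id"]))


def nes_from_enrichment(es: float, p_adjusted: float) -> float:
    """Bounded normalised enrichment score ``(1 - 2*p_adj) * sign(es)``."""
    if not -1 <= es <= 1:
        raise ValueError("es must lie in [-1, 1]")
    if not 0 <= p_adjusted <= 1:
        raise ValueError("p_adjusted must lie in [0, 1]")
    return float((1.0 - 2.0 * p_adjusted) * np.sign(es))


def screen_nlncers(
    matrix: ExpressionMatrix,
    purity: pd.Series,
    notch_set: list[str] | set[str],
    n_perm: int = 1000,
    fdr_threshold: float = 0.05,
    nes_threshold: float = 0.995,
    weight_exponent: float = 1.0,
    seed: int | None = None,
    intersect_samples: bool = False,
) -> pd.DataFrame:
    """Screen every lncRNA for purity-adjusted association with a pathway.

    For each lncRNA: build its NI ranking of all mRNAs, compute the
    weighted-KS enrichment score of ``notch_set`` and an add-one permutation
    p-value; then Benjamini–Hochberg adjust across *all* lncRNAs in one pass,
    form the bounded NES and apply the strict driver filter.  Per-lncRNA
    permutation streams are keyed on the lncRNA id, so reordering rows
    permutes the output without changing any value.

    Returns a DataFrame with columns ``lnc_id, es, p_nominal, p_adjusted,
    nes, is_driver, n_mrna_used`` sorted by ``|nes|`` descending.
    """
    purity = validate_purity(purity)
    matrix, purity = align_samples(matrix, purity, intersect=intersect_samples)
    lnc_ids = matrix.lncrna_ids
    mrna_ids = matrix.mrna_ids
    notch_in_matrix = [g for g in notch_set if g in set(mrna_ids)]
    if len(lnc_ids) < 1:
        raise ValueError("matrix contains no lncRNA rows")
    if len(mrna_ids) < len(notch_in_matrix) + 1:
        raise ValueError("matrix needs more mRNAs than the pathway set")
    if not notch_in_matrix:
        raise ValueError("pathway set is disjoint from the matrix mRNAs")

    vals = matrix.values
    has_nan = bool(np.isnan(vals.to_numpy()).any() or np.isnan(purity.to_numpy()).any())
    n = matrix.n_samples
    mrna_arr = mrna_ids.to_numpy()

    if not has_nan:
        pcc, l_ok, m_ok = pairwise_partial_correlation(
            vals.loc[lnc_ids].to_numpy(), vals.loc[mrna_ids].to_numpy(), purity.to_numpy()
        )

    rows = []
    skipped: list[str] = []
    for i, lid in enumerate(lnc_ids):
        if has_nan:
            try:
                rec = pair_records(matrix, lid, purity)
            except ValueError:
                skipped.append(lid)
                continue
            ranked = make_ranked_list(pd.Series(rec["ni"].to_numpy(), index=rec["mrna_id"]))
        else:
            if not l_ok[i]:
                skipped.append(lid)
                continue
            use = m_ok
            p = pcc_pvalue(pcc[i, use], n)
            ni = notch_pair_index(pcc[i, use], p)
            ranked = make_ranked_list(pd.Series(ni, index=mrna_arr[use]))
        try:
            es, _ = enrichment_score(ranked, notch_in_matrix, weight_exponent)
        except ValueError:
            skipped.append(lid)
            continue
        n_hit = int(ranked.index.isin(set(notch_in_matrix)).sum())
        rng = derive_rng(seed, str(lid))
        null = permutation_null_es(
            np.abs(ranked.to_numpy()) ** weight_exponent, n_hit, n_perm, rng
        )
        p_nom = (1.0 + np.sum(np.abs(null) >= abs(es))) / (1.0 + n_perm)
        rows.append({"lnc_id": lid, "es": es, "p_nominal": p_nom, "n_mrna_used": len(ranked)})

    if skipped:
        logger.warning("screen skipped %d degenerate lncRNA(s): %s",
                       len(skipped), skipped[:5])
    if not rows:
        raise ValueError("no lncRNA survived the screen preconditions")
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p_nominal"].to_numpy())
    out["nes"] = [
        nes_from_enrichment(e, q) for e, q in zip(out["es"], out["p_adjusted"])
    ]
    out["is_driver"] = (out["p_adjusted"] < fdr_threshold) & (out["nes"].abs() > nes_threshold)
    out = out.sort_values(
        ["nes", "lnc_id"], key=lambda s: -s.abs() if s.name == "nes" else s
    ).reset_index(drop=True)
    return out[["lnc_id", "es", "p_nominal", "p_adjusted", "nes", "is_driver", "n_mrna_used"]]


def combine_driver_sets(results: list[pd.DataFrame], how: str = "intersection") -> list[str]:
    """Combine per-cohort driver calls across cohorts.

    ``intersection`` (default) keeps lncRNAs flagged in every cohort —
    the natural reading of "common to all cohorts"; ``union`` keeps any.
    """
    sets = [set(df.loc[df["is_driver"], "lnc_id"]) for df in results]
    if not sets:
        return []
    if how == "intersection":
        combined = set.intersection(*sets)
    elif how == "union":
        combined = set.union(*sets)
    else:
        raise ValueError(f"unknown combination rule {how!r}")
    return sorted(combined)
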