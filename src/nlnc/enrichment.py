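"""Gene-set enrichment machinery: weighted-KS enrichment score with a
gene-label permutation null, Benjamini–Hochberg adjustment, per-sample
(ssGSEA-style) pathway scoring, and group-difference ranking.

The enrichment score is the classic weighted Kolmogorov–Smirnov statistic:
walking down a ranked list, in-set genes ("hits") increment a running sum in
proportion to ``|score|**weight_exponent`` (normalised over the hits) and
out-of-set genes decrement it by ``1/(N - n_hits)``; the score is the
running-sum value of maximum absolute magnitude, signed.  Because the
statistic here is computed per ranked list (one list per lncRNA), the only
valid permutation scheme is permutation of gene labels, which is equivalent
to placing the set on a uniformly random subset of positions.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("nlnc")

__all__ = [
    "make_ranked_list",
    "enrichment_score",
    "permutation_null_es",
    "preranked_gsea",
    "bh_adjust",
    "ssgsea_score",
    "rank_by_group_difference",
    "compare_index_by_group",
]


def derive_rng(seed: int | None, *labels: str) -> np.random.Generator:
    """Generator keyed by a master seed plus stable string labels.

    Keying on labels (e.g. a gene or set name) rather than iteration order
    makes results invariant to the order in which items are processed.
    """
    entropy = [zlib.crc32(lab.encode()) for lab in labels]
    if seed is None:
        ss = np.random.SeedSequence(entropy=entropy or None)
    else:
        ss = np.random.SeedSequence(entropy=[int(seed)] + entropy)
    return np.random.default_rng(ss)


def make_ranked_list(scores: Mapping[str, float] | pd.Series) -> pd.Series:
    """Sort scores descending with ties broken by gene id ascending.

    Returns a float Series indexed by gene id — the canonical ranked-list
    container used throughout this module.
    """
    s = pd.Series(scores, dtype=float)
    if s.index.duplicated().any():
        raise ValueError("duplicate gene ids in ranked list")
    order = np.lexsort((s.index.to_numpy(), -s.to_numpy()))
    return s.iloc[order]


def _hit_mask(ranked: pd.Series, gene_set: Iterable[str]) -> np.ndarray:
    genes = ranked.index
    hit = genes.isin(set(gene_set)).astype(bool)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    if n_hit == len(genes):
        raise ValueError("gene set covers the entire ranked list")
    return hit


def enrichment_score(
    ranked: pd.Series,
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted-KS enrichment score of ``gene_set`` in a ranked list.

    Hit increments are ``|score|**weight_exponent`` normalised by their sum
    (uniform ``1/n_hits`` when all hit weights are zero); miss decrements are
    ``1/(N - n_hits)``.  Returns ``(es, running_sum)`` where ``es`` is the
    running-sum value of maximum absolute magnitude.
    """
    hit = _hit_mask(ranked, gene_set)
    w = np.abs(ranked.to_numpy()) ** weight_exponent
    n = len(w)
    n_hit = int(hit.sum())
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total > 0:
        inc = hit_w / total
    else:
        inc = hit / n_hit
    dec = (~hit) / (n - n_hit)
    running = np.cumsum(inc - dec)
    # the walk lives in [-1, 1]; cumulative rounding can overshoot by ~1e-16
    es = float(np.clip(running[np.argmax(np.abs(running))], -1.0, 1.0))
    return es, running


def permutation_null_es(
    weights_abs: np.ndarray,
    n_hit: int,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 2000,
) -> np.ndarray:
    """Null enrichment scores under gene-label permutation.

    Permuting gene labels of a fixed ranking is equivalent to assigning the
    set to a uniformly random subset of ``n_hit`` positions, so the null is
    drawn by sampling position subsets and replaying the walk, vectorised
    across permutations.
    """
    n = len(weights_abs)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        r = rng.random((b, n))
        idx = np.argpartition(r, n_hit - 1, axis=1)[:, :n_hit]
        hit = np.zeros((b, n), dtype=bool)
        hit[np.arange(b)[:, None], idx] = True
        hit_w = np.where(hit, weights_abs, 0.0)
        total = hit_w.sum(axis=1, keepdims=True)
        safe = np.where(total > 0, total, 1.0)
        inc = np.where(total > 0, hit_w / safe, hit / n_hit)
        running = np.cumsum(inc - (~hit) / (n - n_hit), axis=1)
        peak = np.argmax(np.abs(running), axis=1)
        out[done:done + b] = running[np.arange(b), peak]
        done += b
    return out


def _leading_edge(ranked: pd.Series, hit: np.ndarray, running: np.ndarray) -> list[str]:
    peak = int(np.argmax(np.abs(running)))
    genes = ranked.index.to_numpy()
    if running[peak] >= 0:
        sel = hit & (np.arange(len(genes)) <= peak)
    else:
        sel = hit & (np.arange(len(genes)) >= peak)
    return list(genes[sel])


def preranked_gsea(
    ranked: pd.Series,
    sets: GeneSetCollection | Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Preranked enrichment of one or more gene sets with a permutation null.

    Nominal p-values use the add-one estimator
    ``(1 + #{|es_perm| >= |es_obs|}) / (1 + n_perm)`` (two-sided on |ES|),
    which cannot return zero; adjusted p-values are Benjamini–Hochberg across
    the sets tested in this call.  Sets violating the enrichment-score
    preconditions are skipped with a warning.  Fully deterministic given
    ``seed`` and independent of set iteration order.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable p-values", stacklevel=2)
    items = sets.items() if hasattr(sets, "items") else dict(sets).items()
    rows = []
    for name, members in items:
        try:
            hit = _hit_mask(ranked, members)
        except ValueError as exc:
            logger.warning("skipping set %r: %s", name, exc)
            continue
        es, running = enrichment_score(ranked, members, weight_exponent)
        rng = derive_rng(seed, name)
        null = permutation_null_es(
            np.abs(ranked.to_numpy()) ** weight_exponent, int(hit.sum()), n_perm, rng
        )
        p = (1.0 + np.sum(np.abs(null) >= abs(es))) / (1.0 + n_perm)
        rows.append({
            "set_name": name,
            "es": es,
            "p_nominal": p,
            "n_perm_used": n_perm,
            "leading_edge": _leading_edge(ranked, hit, running),
        })
    result = pd.DataFrame(rows, columns=["set_name", "es", "p_nominal", "n_perm_used", "leading_edge"])
    if len(result):
        result["p_adjusted"] = bh_adjust(result["p_nominal"].to_numpy())
    else:
        result["p_adjusted"] = pd.Series(dtype=float)
    return result[["set_name", "es", "p_nominal", "p_adjusted", "n_perm_used", "leading_edge"]]


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-aligned with input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def ssgsea_score(
    matrix: ExpressionMatrix,
    gene_set: Iterable[str],
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.Series:
    """Per-sample pathway activity by rank-weighted ECDF difference.

    For each sample, genes are ranked by expression (descending, ties broken
    by gene id so results are platform-independent); rank weights are
    ``rank**alpha`` with rank ``N`` for the top gene.  The score is the sum
    over list positions of the weighted in-set ECDF minus the out-of-set
    ECDF.  With ``normalize=True`` all samples' scores are divided by the
    max-minus-min across samples.  The score depends on each sample's
    expression vector only through its ranks, so it is invariant to strictly
    monotone per-sample transforms.
    """
    gene_set = set(gene_set)
    genes = matrix.gene_ids
    in_set = np.asarray(genes.isin(gene_set))
    n_in = int(in_set.sum())
    n = len(genes)
    if n_in == 0 or n_in == n:
        raise ValueError("gene set must be a proper non-empty subset of matrix genes")
    gene_arr = genes.to_numpy()
    scores = {}
    for sample in matrix.sample_ids:
        x = matrix.values[sample].to_numpy()
        if np.nanstd(x) == 0:
            logger.warning("sample %r has constant expression; ranking by gene id", sample)
        order = np.lexsort((gene_arr, -x))
        hit = in_set[order]
        rank_weight = (n - np.arange(n)).astype(float) ** alpha
        hit_w = np.where(hit, rank_weight, 0.0)
        ecdf_in = np.cumsum(hit_w) / hit_w.sum()
        ecdf_out = np.cumsum(~hit) / (n - n_in)
        scores[sample] = float(np.sum(ecdf_in - ecdf_out))
    out = pd.Series(scores, name="ssgsea")
    if normalize:
        spread = out.max() - out.min()
        if spread > 0:
            out = out / spread
    return out


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def rank_by_group_difference(
    matrix: ExpressionMatrix,
    group_labels: pd.Series,
    min_per_group: int = 3,
) -> pd.Series:
    """Rank genes by the Welch two-sample t statistic (group1 - group2).

    ``group_labels`` is a binary Series over samples; the two groups are the
    sorted unique labels, compared as first-minus-second.  Genes with fewer
    than ``min_per_group`` complete observations in either group are excluded
    (pairwise-complete handling of missing values).  Returns a descending
    ranked list.
    """
    group_labels = group_labels.loc[matrix.sample_ids]
    levels = sorted(pd.unique(group_labels.dropna()))
    if len(levels) != 2:
        raise ValueError("group_labels must define exactly two groups")
    a = matrix.values.loc[:, group_labels == levels[0]].to_numpy()
    b = matrix.values.loc[:, group_labels == levels[1]].to_numpy()
    if a.shape[1] < min_per_group or b.shape[1] < min_per_group:
        raise ValueError(f"each group needs >= {min_per_group} samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit").statistic
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    ok = (n_a >= min_per_group) & (n_b >= min_per_group) & np.isfinite(t)
    n_excluded = int(np.sum(~ok))
    if n_excluded:
        logger.info("group-difference ranking excluded %d gene(s)", n_excluded)
    return make_ranked_list(pd.Series(t[ok], index=matrix.gene_ids[ok]))


def compare_index_by_group(scores: pd.Series, labels: pd.Series) -> tuple[float, float]:
    """Test a per-sample index across groups.

    Two groups: Wilcoxon rank-sum, exact when both groups are small and
    tie-free, otherwise the normal approximation.  More than two groups:
    Kruskal–Wallis.  Returns ``(statistic, p)``.
    """
    labels = labels.loc[scores.index]
    groups = [scores[labels == lev].to_numpy() for lev in pd.unique(labels.dropna())]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every group needs at least two members")
    if len(groups) == 2:
        pooled = np.concatenate(groups)
        exact = max(len(g) for g in groups) <= 25 and len(np.unique(pooled)) == len(pooled)
        res = stats.mannwhitneyu(
            groups[0], groups[1], alternative="two-sided",
            method="exact" if exact else "asymptotic",
            use_continuity=False,
        )
        return float(res.statistic), float(res.pvalue)
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)
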