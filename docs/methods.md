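# Methods

## Screening model

For lncRNA *i*, mRNA *k* and tumour purity *p* over *n* samples, the screen
uses the first-order partial correlation

PCC = (R_lm − R_lp·R_mp) / √((1 − R_lp²)(1 − R_mp²)),

which is mathematically the Pearson correlation of the residuals of each
variable regressed on purity (the test suite holds the two routes to 1e-10).
Its two-sided p-value uses the normal approximation z = PCC·√(n−3)/√(1−PCC²)
with one control variable; *n* is the pairwise-complete sample count for that
pair, so missing entries are handled per pair. The signed pair index is
NI = −ln(P)·sign(PCC), with sign(0) = 0. The sign multiplies **outside** the
logarithm: placing it inside (−ln(P·sign(PCC))) is undefined for negative
correlations, so that reading is rejected. P is floored at 1e-300 before the
logarithm; the floor changes no ordering.

For each lncRNA, all mRNAs are ranked by NI descending (ties broken by gene
id ascending, so results are platform-independent) and the pathway set's
enrichment is the classic weighted Kolmogorov–Smirnov walk: hits increment
the running sum by |NI|^w normalised over the hits (w = 1 by default; uniform
increments if all hit weights are zero), misses decrement by 1/(N − n_hits);
ES is the running-sum value of largest magnitude, signed, clipped into
[−1, 1] against cumulative rounding.

**Permutation null.** Because the statistic is computed per ranked list, the
null permutes gene labels, which is equivalent to placing the set on a
uniformly random subset of positions; the walk is replayed vectorised across
permutations. The nominal p-value is the add-one estimator
(1 + #{|ES_perm| ≥ |ES_obs|}) / (1 + n_perm), two-sided on |ES|, which can
never be zero. Permutation streams are keyed on the lncRNA (or set) name
plus the master seed, so results are independent of row order and bit-for-bit
reproducible. We verified on identical rankings that the ES and p agree with
fgsea's simple preranked permutation test.

**Bounded NES and the driver filter.** Nominal p-values are
Benjamini–Hochberg adjusted in one pass across all lncRNAs; each lncRNA then
gets NES = (1 − 2·P_adj)·sign(ES) ∈ [−1, 1], and drivers must satisfy
P_adj < 0.05 **and** |NES| > 0.995, both strict. The second condition
algebraically implies P_adj < 0.0025. Per-cohort driver sets are combined by
intersection by default (union available).

**Resolution of the permutation estimator.** The add-one estimator floors
nominal p at 1/(n_perm + 1). If k true drivers tie at that floor among m
screened lncRNAs, their BH-adjusted p is m/(k·(n_perm + 1)); the strict
filter therefore needs roughly n_perm ≳ 400·m/k. The library default is
1,000 permutations — sufficient for the FDR < 0.05 condition but **not** for
|NES| > 0.995 at typical m/k; recovery tests and the acceptance script use
4,999–9,999 permutations where the strict filter must be attainable. An
analysis based on an estimator without this floor (such as fgsea's
multilevel algorithm, not implemented here) does not face the constraint.

**Known limitation: correlated gene sets.** Gene-label permutation assumes
the ranking scores are exchangeable. A co-expressed pathway module violates
this: a *null* lncRNA's correlations with the module's genes all share that
lncRNA's chance correlation with the module's latent factor, so the module
clusters in the ranking far more often than exchangeable permutations
predict, and nominal p-values for correlated sets are anti-conservative.
On a single synthetic cohort with module internal correlation 0.5 this
produces a large false-discovery proportion among flagged drivers even
though recall of true drivers is essentially 1. The operative control in
this pipeline is the **cross-cohort intersection**: a null lncRNA's chance
alignment with the module has an independent random sign and magnitude in
each cohort, so false drivers rarely replicate (empirically the 3-cohort
intersection FDP is below 0.1 at the default conditions), while true drivers
replicate by construction. Single-cohort driver lists from this method
should be treated as anti-conservative. This behaviour is shared by any
preranked gene-permutation GSEA, including the fgsea-based original of this
procedure.

## Signature construction

Driver lncRNA expression is z-scored per cohort (constant features map to
zero with a warning; training means/SDs are stored in the model so held-out
samples can be scored either with carried-over constants or re-z-scored per
cohort — the default, matching per-cohort standardisation at training).
Features must pass unadjusted univariate Cox p < 0.15 with the same
hazard-ratio direction in **every** cohort; the threshold is deliberately
lenient and unadjusted, because aggressive multiplicity correction before a
penalised fit discards weak but consistent prognostic features.

The LASSO-Cox path (glmnet-style coordinate descent via scikit-survival's
coxnet) runs over 100 log-spaced penalties from the smallest value that
zeroes every coefficient down to 1e-3 of it. Ten-fold cross-validation is
stratified by event status; the cross-validated partial-likelihood deviance
uses the subtraction method — for fold k with coefficients b_k,
dev_k = −2·(loglik_all(b_k) − loglik_train(b_k)) with a Breslow partial
log-likelihood — and the chosen penalty minimises the mean deviance over the
penalties evaluated in every fold. Features with non-zero coefficients are
then pruned by an unpenalised multivariable Cox fit (Wald p < 0.05 by
default; the threshold is this package's choice), and the scoring weights
are re-extracted by refitting the LASSO restricted to the retained features
at the same penalty — the risk score uses **LASSO** coefficients, the
multivariable fit only prunes. Risk is dichotomised at the sample median by
default; an optimal log-rank cutoff (scanning midpoints that leave at least
10% of samples per group) is available and reported alongside.

Tie handling: the unpenalised Cox fits (lifelines) use Efron's
approximation, the penalised path and the CV deviance use Breslow. On
continuous survival times — all this package generates — the two coincide;
with heavily tied data the univariate screen and the penalised fit would
differ slightly.

## Survival evaluation

Kaplan–Meier product-limit curves and Mantel–Haenszel log-rank tests
(lifelines); multivariable Cox with one-hot covariates, list-wise deletion
(counted) and a design condition-number guard at 1e8; cumulative/dynamic
time-dependent AUC with Kaplan–Meier IPCW weights (scikit-survival), with
horizons lacking cases or controls reported as NaN with a warning; Harrell's
C with 0.5 credit for score ties. Confidence intervals for hazard ratios use
the normal approximation on the log scale.

## Synthetic cohorts

The generator emulates a bulk tumour cohort:

- purity ~ Beta(5, 2) (mean 0.71, realistic bulk tumour purity) loads with
  weight `purity_loading` (default 3.0) on **every** gene, inflating naive
  correlations — the confounding the partial correlation exists to remove
  (a test asserts naive > partial under the null);
- a latent N(0, 1) module factor loads with weight 1 on the
  `notch_set_size` module mRNAs and with weight w on the driver lncRNAs,
  where w is calibrated analytically so the population partial correlation
  between a driver and a module mRNA given purity equals `driver_effect`
  (default 0.5): w = r·s·√(1+s²)/√(1−r²(1+s²)) with noise SD s (default 1),
  feasible iff |r| < 1/√(1+s²);
- all other variation is i.i.d. Gaussian noise on a continuous log-like
  scale (no count model: every downstream formula consumes continuous
  values);
- survival follows a proportional-hazards model with linear predictor
  Σ β_j·z_j over the standardized prognostic lncRNAs (β defaults to
  alternating ±0.8 per SD), a Weibull baseline (shape 1.5, scale set for a
  baseline median event time of 3 time units), and independent Uniform(0, c)
  censoring with c solved by bisection so the expected censoring fraction
  matches `censoring_rate` (default 0.3);
- multi-cohort draws share gene identities, use disjoint sample ids and
  per-cohort seeds derived from the master seed, keep planted coefficient
  signs identical across cohorts and jitter magnitudes multiplicatively.

What the generator does **not** emulate: count noise/library size, batch and
platform effects, probe-level artefacts, non-proportional hazards,
non-linear purity effects, and realistic pathway topology (the module is a
single factor). Recovery results on these cohorts therefore demonstrate
correctness of the computations and the qualitative behaviour of the
procedure, not its operating characteristics on real tumour data.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the package's
own defaults: null-calibration screens use 20 cohorts of 200 lncRNAs × 300
mRNAs (n = 200, 200 permutations); planted-driver recovery uses 30 drivers
among 300 lncRNAs (n = 300, 9,999 permutations, see the resolution analysis
above); LASSO recovery uses 6 prognostic of 24 features at n = 600 with 30%
censoring; the end-to-end run uses three cohorts plus a held-out one at
n = 450 (within the 382–585 range of typical public CRC cohorts) with 100
lncRNAs, 24 drivers, 6 prognostic and 1,999 permutations. At n = 300 the
univariate consistency screen intermittently loses planted features whose
marginal effects are attenuated by correlated opposing-sign drivers; n = 450
provides the power those cohort sizes imply.

Other numerical choices: correlations are clamped to ±(1 − 1e-12) before the
z-transform; degenerate rows (constant, or purity-collinear beyond 1e-12)
are excluded and counted; ssGSEA uses exponent α = 0.25 on within-sample
ranks (top gene gets rank N) with max-minus-min normalisation across
samples, making it invariant to strictly monotone per-sample transforms;
ranked-list ties always break by gene id ascending; "empty expression" in
the lncRNA coverage filter means missing **or** exactly zero by default
(configurable), and removal requires the empty fraction to strictly exceed
the threshold; group comparisons use the exact rank-sum distribution for
small tie-free groups and the normal approximation otherwise, and
Kruskal–Wallis for more than two groups.
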