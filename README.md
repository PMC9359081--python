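# nlnc

Screening pathway-derived lncRNA drivers in bulk tumour transcriptomes and
building a prognostic lncRNA risk signature from them.

## The problem

Bulk lncRNA–mRNA co-expression is confounded by tumour purity: the malignant
cell fraction drives expression of most genes, so naive correlations are
inflated. Given an expression matrix with lncRNA/mRNA biotype labels, a
pathway gene set (e.g. the Notch pathway), and per-sample purity estimates,
this package

1. **screens drivers**: for each lncRNA *i* and mRNA *k* it computes the
   first-order partial correlation given purity *p*,

   ```
   PCC_ik = (R_lm − R_lp·R_mp) / √((1 − R_lp²)(1 − R_mp²))
   P_ik   = 2·Φ(−|PCC_ik·√(n−3) / √(1 − PCC_ik²)|)
   NI_ik  = −ln(P_ik) · sign(PCC_ik)
   ```

   ranks all mRNAs by NI and asks — by a weighted Kolmogorov–Smirnov
   enrichment score with a gene-label permutation null — whether the pathway
   set concentrates at an extreme of the ranking. Each lncRNA's BH-adjusted
   p-value and enrichment-score sign give a bounded normalised enrichment
   score `NES = (1 − 2·P_adj)·sign(ES) ∈ [−1, 1]`; drivers satisfy
   `P_adj < 0.05` and `|NES| > 0.995`, intersected across cohorts;

2. **builds the signature**: z-scores driver expression per cohort, keeps
   features with univariate Cox `p < 0.15` and a consistent hazard-ratio
   direction in every cohort, fits 10-fold cross-validated LASSO-Cox at the
   penalty minimising partial-likelihood deviance, prunes by multivariable
   Cox, and scores samples as `risk = Σ_i z_i · coefficient_i` with a
   median (or optimal log-rank) high/low split;

3. **evaluates**: Kaplan–Meier curves and log-rank tests, multivariable Cox
   independence, IPCW time-dependent AUC at fixed horizons, Harrell's
   C-index;

4. **simulates**: synthetic cohorts with a purity confounder, a correlated
   pathway module, planted driver lncRNAs with a calibrated partial
   correlation, and Weibull proportional-hazards survival — with ground
   truth, so every stage is testable by recovery.

It is intended for computational oncology / transcriptomics researchers who
want a reproducible, testable implementation of this class of
purity-adjusted lncRNA screens rather than a one-off analysis script.

## Worked example

`examples/02_signature_and_evaluation.py` simulates three cohorts plus a
held-out one (450 samples each, 24 planted drivers among 100 lncRNAs, 6 of
them prognostic), screens, intersects, fits the signature and evaluates it:

```
drivers common to all cohorts: 27
signature lncRNAs and LASSO coefficients:
  L0001: +0.769  (planted +0.73)
  L0002: -0.807  (planted -0.85)
  L0003: +0.733  (planted +0.74)
  L0004: -0.837  (planted -0.85)
  L0005: +0.730  (planted +0.75)
  L0006: -0.928  (planted -0.84)

held-out cohort: log-rank p = 1e-49, C-index = 0.797
time-dependent AUC: {'t=1': 0.85, 't=3': 0.856, 't=5': 0.887}
```

All six planted prognostic lncRNAs are recovered with the correct
log-hazard signs, and the signature discriminates survival on a cohort it
never saw (AUC > 0.7 at every horizon). The other examples show the driver
screen alone (`01`) and per-sample pathway-index scoring (`03`).

The same workflow is available from the shell:

```
nlnc simulate --out-dir data/             # or bring your own TSV/GCT + GMT
nlnc screen --expr data/expression.tsv --biotype data/biotype.tsv \
            --purity data/purity.tsv --gmt data/notch.gmt --out screen.tsv
nlnc signature --cohort expr.tsv:clin.tsv ... --candidates screen.tsv \
               --biotype biotype.tsv --out model.json
nlnc score / nlnc evaluate / nlnc ssgsea / nlnc pipeline
```

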