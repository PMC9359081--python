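"""Build a prognostic lncRNA signature across cohorts and evaluate it.

Simulates three training cohorts plus one held-out cohort sharing the same
planted structure, screens drivers in each, intersects the per-cohort driver
sets, fits the cross-validated LASSO-Cox signature and reports held-out
discrimination.
"""

from nlnc import SimulationConfig, run_pipeline, simulate_multi_cohort

cfg = SimulationConfig(
    n_samples=450, n_mrna=250, n_lncrna=100, notch_set_size=30,
    n_driver_lnc=24, n_prognostic_lnc=6, driver_effect=0.5,
    censoring_rate=0.3, seed=5003,
)
cohorts = simulate_multi_cohort(cfg, 4, effect_jitter=0.1)
held = cohorts[3]

res = run_pipeline(
    [(c.expression, c.purity, c.clinical) for c in cohorts[:3]],
    cohorts[0].truth.notch_gene_ids,
    n_perm=1999, seed=42,
    heldout=(held.expression, held.clinical),
)

model = res["model"]
print("drivers common to all cohorts:", len(res["drivers"]))
print("signature lncRNAs and LASSO coefficients:")
for f, c in zip(model.feature_ids, model.coefficients):
    print(f"  {f}: {c:+.3f}  (planted {cohorts[0].truth.prognostic_betas.get(f, 0):+.2f})")

ev = res["evaluations"]["heldout"]
print(f"\nheld-out cohort: log-rank p = {ev['logrank_p']:.3g}, "
      f"C-index = {ev['c_index']:.3f}")
print("time-dependent AUC:", {f"t={k:g}": round(v, 3) for k, v in ev["auc"].items()})
# Recovered coefficients carry the planted log-hazard signs (shrunk toward
# zero by the L1 penalty); occasionally a correlated non-prognostic driver
# enters with a small weight.  C-index and horizon AUCs above 0.7 indicate
# the signature separates risk groups on data it never saw.
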