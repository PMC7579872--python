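"""Meta-regression of per-study effects on cohort-level covariates.

Regresses a gene's per-study LFCs on total sample size, geographic region
(Asia / Europe / North America, Europe as reference) and study age for the
default eleven-cohort catalogue.
"""

import lfcmeta as lm

cfg = lm.SyntheticConfig(n_genes=50, true_lfc={"SPP1": 2.64}, tau2=0.1, seed=5)
datasets = lm.generate_studies(cfg)
effects = lm.effects_table(datasets, genes=["SPP1"])

result = lm.regress_gene_effects(effects, lm.cohort_catalogue())
print(result.to_frame().to_string(index=False))
print(f"\nn = {result.n_obs} studies, residual df = {result.df_resid}, "
      f"R^2 = {result.r_squared:.2f}")
# Each coefficient is the change in the study-level LFC per unit covariate;
# with 11 studies the test is low-powered, so p-values are indicative only.
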