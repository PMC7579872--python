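"""Heterogeneity statistics and a forest table for one pooled gene.

Shows the Q / I^2 / p-Q arithmetic on a heterogeneous instance and prints
the per-study forest rows (effect, 95% CI, weight) with the pooled summary.
"""

import pandas as pd

import lfcmeta as lm

effects = pd.DataFrame(
    {
        "gene_id": "SPP1",
        "study_id": [f"Cohort{i}" for i in range(6)],
        "lfc": [2.1, 3.0, 2.4, 1.8, 3.3, 2.6],
        "variance": [0.10, 0.25, 0.08, 0.15, 0.30, 0.12],
    }
)

q, df = lm.cochran_q(effects["lfc"], effects["variance"])
print(f"Q = {q:.3f} on {df} df -> I^2 = {lm.isq(q, df):.1f}%, "
      f"p-Q = {lm.q_pvalue(q, df):.3f}, model = {lm.select_model(q, df)}")

result = lm.meta_analyze_gene(effects, min_fraction=0.1)
print(lm.forest_table(result, effects).to_string(index=False))
# Each study row shows its effect with a sampling-noise CI and its share of
# the pooled weight; the POOLED row is the model-selected combined estimate.
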