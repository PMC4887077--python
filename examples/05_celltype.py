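"""Interpret the delta profile against a blood cell-type expression panel.

Each panel probe is centered by its mean across the cell-type columns, then
every centered column is Spearman-correlated with the delta profile.  A
negative coefficient suggests the corresponding cell population decreases
with treatment response; here the panel is synthetic, so coefficients hover
near zero and the example simply demonstrates the machinery.
"""

import rxdeconv as rx

cohort = rx.generate_cohort(
    rx.GeneratorConfig(G=400, M=6, N=8, total_counts=50_000, n_de_genes=20, seed=42)
)
result = rx.fit_map(cohort.panel, cohort.counts, rx.FitConfig(n_restarts=2, seed=1))
state = result.best_state

delta = rx.compute_delta(state.response, state.hyper, cohort.panel)
table = rx.celltype_correlation(delta, cohort.celltypes)
table = table.sort_values("rho")
print("5 most negatively / positively correlated cell types:")
print(table.head(5).to_string(float_format=lambda x: f"{x:.3f}"))
print(table.tail(5).to_string(float_format=lambda x: f"{x:.3f}"))
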