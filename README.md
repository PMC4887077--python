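# rxdeconv

Treatment-response deconvolution of pre-/post-treatment gene expression
cohorts.

## The problem

In heterogeneous diseases such as juvenile idiopathic arthritis, patients
differ in subtype, medication, and baseline expression, so the transcriptional
effect of therapy is buried under strong patient-specific signatures.  Given
a panel of **M** pre-treatment expression profiles and **N** post-treatment
profiles (they need not be paired or equal in number), `rxdeconv` infers

* a single **treatment-response profile** `r` — a probability distribution
  over genes shared by the whole cohort — capturing the expression signal
  that no combination of pre-treatment profiles can explain, and
* a per-patient **% treatment response** — the convex weight each
  post-treatment profile places on `r`.

The per-patient weight can then be correlated with clinical outcomes, and the
**delta profile** `δ = log2(r) − log2(ωB)` (the response profile contrasted
with the fitted blend of references) ranks the genes most changed by
treatment.

## The model

Each pre-treatment profile (column of `B`) is normalized to sum to one.  Each
post-treatment profile `p_n` is a count vector, modeled as

```
p̂_n = [B r] θ_n                      θ_n ∈ Δ^{M+1}
p_n | B, r, θ_n ~ Multinomial(p̂_n)
θ_n ~ Dirichlet(v)                   r ~ Dirichlet(κ ωB)
```

`θ_n` holds the convex mixing weights of the M references plus `r`; its last
entry is the % treatment response.  The prior on `r` is centered on a convex
blend `ωB` of the references with strength `κ`.  All parameters
(`θ, r, v, ω, κ`) are fitted by MAP: blockwise Polak–Ribière conjugate
gradient ascent on the complete log likelihood, under softmax/log
reparameterizations that keep every block feasible, with random restarts and
a monotone-ascent guarantee on the likelihood trace.

## Worked example

```python
import rxdeconv as rx
from scipy.stats import spearmanr

cohort = rx.generate_cohort(
    rx.GeneratorConfig(G=400, M=6, N=8, total_counts=50_000, n_de_genes=20, seed=42))
result = rx.fit_map(cohort.panel, cohort.counts, rx.FitConfig(n_restarts=2, seed=1))
est = rx.extract_treatment_response(result)
print(spearmanr(est.to_numpy(), cohort.truth.response_weights).statistic)
```

Running `python examples/01_simulate_and_fit.py` (which does the above and
prints the per-patient table) ends with:

```
Spearman(fitted, planted) = 1.000  (1.0 = perfect rank recovery)
paired reference dominant for 100% of patients
```

meaning the fitted % treatment response ranks the patients almost exactly as
the planted weights do, and every patient's own paired reference receives the
highest mixture weight even though the model never sees the pairing.  Note
that the *absolute* fitted weights run higher than the planted ones (the
response component also absorbs sampling noise); the estimates are reliable
as a ranking, which is how they are used downstream.  The other scripts in
`examples/` demonstrate delta-profile gene ranking versus the per-gene
t-test, clinical correlation with Bonferroni correction, the gene-subset
sensitivity test, and the cell-type correlation analysis.  The same stages
are available from the shell via the `rxdeconv` CLI
(`simulate`, `fit`, `delta`, `sensitivity`, `celltype`, `clinical`, `all`).

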