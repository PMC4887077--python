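# Methods

## Model

`rxdeconv` decomposes post-treatment expression profiles into a
treatment-naïve part and a shared treatment-response part.  The inputs are a
gene × M reference panel `B` of pre-treatment profiles, each column scaled to
sum to one, and a gene × N matrix `P` of post-treatment count vectors
(real-valued intensities are rescaled to a common total and discretized by
largest-remainder rounding, default 10⁶ counts per sample, so every column
total is exact).

Each post-treatment sample n draws its counts from a multinomial whose cell
probabilities are the convex mixture `p̂_n = [B r] θ_n`, where `r` is the
hidden treatment-response distribution over genes, shared across the cohort,
and `θ_n` is a simplex vector of M+1 mixing weights.  The last entry of
`θ_n` is the per-patient % treatment response.  Priors:

* `θ_n ~ Dirichlet(v)` with `v ≥ 1` elementwise.  At initialization the
  first M entries are drawn `1 + U(0,1)` and the response entry `5 + U(0,1)`:
  a single response profile competes with M references, so its weight gets a
  larger prior concentration.
* `r ~ Dirichlet(κ·ωB)` — the prior mean of `r` is a convex blend of the
  references with weights `ω` (initialized uniform) and strength `κ`
  (initialized at 10,000).

The complete log likelihood is the sum of the `r` prior, the N `θ` priors,
and the N multinomial log masses.  The multinomial coefficient (a
count-dependent constant) is included, so reported likelihood values are
fully normalized and comparable across parameter settings; it does not
affect optimization.

## Estimation

All parameters are fitted by MAP.  Each outer iteration cycles the blocks in
the fixed order theta → response → v → omega → kappa; each block is
optimized by Polak–Ribière conjugate gradients (scipy's `CG`) in an
unconstrained space with analytic gradients:

* simplex blocks (`θ` rows, `r`, `ω`) through a softmax reparameterization,
* `v` through `log(v − 1)` (keeps `v > 1`),
* `κ` through `log(κ − κ_min)` (see below).

A block update is accepted only if the complete log likelihood does not
decrease (relative slack 1e-9); otherwise the input state is returned, so
the per-iteration likelihood trace is non-decreasing by construction.
Iteration stops when the relative change in log likelihood falls below
`rel_tol` (default 1e-7) or after `max_outer_iterations` (default 35).
Ten random restarts are run by default, restart k seeding its initialization
with `seed + k`; the restart with the highest final complete log likelihood
is kept.

### The κ floor

If any prior concentration `κ·(ωB)_g` falls below 1, the Dirichlet density
diverges on the simplex boundary and the posterior mode for `r` collapses
the affected genes to zero (fitted values around 1e-60 in practice, which
destroys the delta profile).  `rxdeconv` therefore constrains
`κ ≥ 1/min_g((ωB)_g)`, which keeps every concentration at least 1 and the
mode interior.  The floor is coupled into the `ω` objective (an `ω` move
that lowers `min(ωB)` implicitly raises `κ`), and binding floors are logged.
Entries of `ωB` that are exactly zero (genes absent from every reference)
are floored at 1e-12 before use as concentrations.

## Downstream analyses

* **Delta profile**: `δ_g = log2(max(r_g, ε)) − log2(max((ωB)_g, ε))` with
  `ε = 1e-12` (floor hits are counted and logged); computed against the
  *fitted* `ω`.  Genes are ranked by signed delta in each direction, ties
  broken lexicographically by gene id.
* **t-test comparator**: per-gene two-sided Welch (unequal-variance) t-test
  of post vs pre profiles, with a paired option; genes with an undefined
  statistic (both groups constant and equal) are flagged and ranked last.
  The Welch default is recorded in the output metadata.
* **Clinical correlation**: percent reductions `100·(x₀ − x₆)/x₀` of four
  disease-activity indicators (PGA, ESR, active joint count, LRM joint
  count) are correlated (Spearman and Pearson) with the % treatment
  response.  Patients with a zero baseline are excluded listwise from that
  indicator only, with the exclusion count logged.  P-values are
  Bonferroni-corrected with family size 4 — the four indicators tested per
  method — configurable.
* **Sensitivity test**: genes are partitioned round-robin by index (a
  seeded-random scheme is available) into 4 disjoint subsets; the model is
  refitted on each subset (reference columns renormalized).  The per-patient
  standard error is the SD of the subset estimates divided by √4, i.e. the
  standard error of the mean of the subset estimates.
* **Cell-type correlation**: panel probes are matched to the analysis genes
  by identifier (≥ 100 shared genes required), each probe centered by its
  mean across the panel's own cell-type columns, and each centered column
  Spearman-correlated with the delta profile.  Centering uses the panel
  columns as the sample set.

## Synthetic cohorts

The generator draws cohorts from the model's own likelihood so that every
pipeline stage can be validated against planted truth:

* **References**: a shared template (normalized log-normal, σ = 1) plus a
  flat background floor of 10% of mean intensity — emulating array
  background, so no gene is entirely unmeasured — perturbed per patient by a
  Dirichlet with concentration 5000 (roughly ±40% per-gene variation between
  patients).
* **Response profile**: the uniform blend `ωB` with `n_de_genes` (default
  50 of 1000) multiplied by `2^(±2)` (half up, half down) and renormalized.
  Planted genes are drawn from genes above the 40th expression percentile:
  a 4-fold change on an essentially unexpressed gene is not recoverable at
  finite counts and would not be called differentially expressed in
  practice.  The achieved (post-renormalization) per-gene log2 changes are
  recorded as the truth.
* **Mixture weights**: the response weight is uniform on [0.05, 0.5]; of the
  remaining mass, 60% goes to the sample's paired reference (emulating the
  observed dominance of each patient's own pre-treatment profile) and the
  rest is spread Dirichlet-uniformly.
* **Counts**: multinomial draws of 100,000 trials per sample, with an
  optional per-gene log-normal overdispersion multiplier (off by default)
  for misspecification checks.
* **Clinical table**: each indicator's reduction fraction is an affine
  monotone map of the true response weight onto [0.1, 0.9] plus N(0, 0.1)
  noise.  Joint counts are integers; at noise 0 a deterministic repair pass
  decrements follow-up counts until the achieved reductions are strictly
  increasing in the true weight, so integer rounding cannot break exact rank
  agreement.  PGA and ESR remain real-valued.
* **Cell-type panel**: 38 independent log-normal archetype columns — enough
  to exercise the correlation machinery, with no planted cell-type signal.

What passing these tests shows: the fitting machinery recovers the planted
structure when the data match the model.  What it does not show: robustness
to array-specific noise physics, batch effects, probe-to-gene mapping
artifacts, or biological deviations from the multinomial-mixture assumption;
those are outside the generator's scope.

## Validation sizes

The recovery benchmark uses G = 1000 genes, M = 10 references, N = 12 post
samples at 10⁵ counts and 2–3 restarts; the sensitivity benchmark uses
G = 600 with signal spread over 20% of genes.  These sizes give stable
recovery statistics (rank correlation of weights ≈ 0.99, log-scale profile
correlation ≈ 0.98, planted-gene recovery ≈ 98%) while keeping the full
validation suite fast.

## Known limitations

* The absolute % treatment-response estimates are biased upward (by roughly
  1.5× at the validation sizes): the response component absorbs multinomial
  sampling noise in addition to the planted signal.  Rank order — which is
  what the clinical correlation uses — is preserved almost exactly.
* With N = 1 post sample and M = 1 reference the model is weakly identified
  (`r` and `θ` trade off); such corner cases are exercised only with frozen
  blocks in the oracle tests.
* The optimizer guarantees monotone ascent, not a global optimum; restarts
  mitigate but do not eliminate local maxima.
* Whether post-treatment totals should be preserved per sample or equalized
  across samples before discretization is an open modeling choice; the
  discretizer equalizes them at `total_counts`, which makes the multinomial
  precision uniform across patients.
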