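"""Synthetic cohorts with planted ground truth.

The generator draws cohorts from the model's own likelihood: pre-treatment
reference profiles are Dirichlet perturbations of a shared template, the
hidden treatment-response profile is a perturbed convex blend of the
references with planted log2 fold changes on a subset of genes, and each
post-treatment profile is a multinomial draw from the convex mixture implied
by a known weight vector.  Clinical indicators are monotone transforms of the
true response weight plus configurable noise.  Because every latent quantity
is recorded, recovery of the % treatment response, the response profile, the
planted genes, and the clinical correlation can all be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .downstream_stats import CellTypePanel, ClinicalTable
from .model_core import (
    CountMatrix,
    MixtureWeights,
    ReferencePanel,
    ResponseProfile,
    floored_blend,
    mixture_profile,
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort dimensions and noise settings.

    Defaults match the recovery conditions the pipeline is validated under:
    a 1000-gene cohort with 10 references, 12 post-treatment samples at 1e5
    counts each, 50 planted genes at |log2FC| = 2, and response weights drawn
    uniformly on [0.05, 0.5].
    """

    G: int = 1000
    M: int = 10
    N: int = 12
    total_counts: int = 100_000
    n_de_genes: int = 50
    effect_size: float = 2.0           # |log2 fold change| of planted genes
    response_range: tuple = (0.05, 0.5)
    reference_concentration: float = 5000.0
    background_fraction: float = 0.1   # array-like background floor on the template
    paired_fraction: float = 0.6       # share of the naive mass on the paired reference
    clinical_noise: float = 0.1        # sd of additive noise on reduction fractions
    overdispersion_sigma: float = 0.0  # per-gene log-normal multiplier; 0 = off
    n_cell_types: int = 38
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.response_range
        if not (0 <= lo <= hi <= 1):
            raise InvalidInputError("response_range must satisfy 0 <= lo <= hi <= 1")
        if self.n_de_genes > self.G:
            raise InvalidInputError("n_de_genes cannot exceed G")
        if min(self.G, self.M, self.N) < 1:
            raise InvalidInputError("all dimensions must be >= 1")
        if self.clinical_noise < 0:
            raise InvalidInputError("clinical_noise must be >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything that was planted: weights, response, DE genes, pairings."""

    true_theta: MixtureWeights
    true_response: ResponseProfile
    planted_gene_ids: list
    planted_log2fc: pd.Series       # achieved per-gene log2 change, full G-vector
    paired_reference: np.ndarray    # index into the panel per post sample
    seed: int

    @property
    def response_weights(self) -> np.ndarray:
        return self.true_theta.response_weights


@dataclass(frozen=True)
class SyntheticCohort:
    """A complete generated fixture: inputs plus ground truth."""

    panel: ReferencePanel
    counts: CountMatrix
    clinical: ClinicalTable
    celltypes: CellTypePanel
    truth: SyntheticTruth
    config: GeneratorConfig = field(repr=False, default=None)


def _rng(config: GeneratorConfig, stage: int) -> np.random.Generator:
    """Stage-scoped generator derived from the top-level seed."""
    return np.random.default_rng([config.seed, stage])


def _gene_ids(G: int) -> list:
    return [f"g{i:05d}" for i in range(G)]


def gen_reference_panel(config: GeneratorConfig) -> ReferencePanel:
    """M pre-treatment profiles: Dirichlet draws around a shared template.

    The template is a normalized log-normal draw (heavy-tailed, as expression
    is) plus a flat background floor emulating array background intensity, so
    no gene is entirely unmeasured; the concentration controls inter-patient
    similarity — higher values give more mutually correlated reference columns.
    """
    rng = _rng(config, 0)
    template = rng.lognormal(mean=0.0, sigma=1.0, size=config.G)
    template += config.background_fraction * template.mean()
    template /= template.sum()
    alpha = config.reference_concentration * template
    cols = rng.dirichlet(alpha, size=config.M).T  # G x M
    return ReferencePanel(
        values=cols,
        gene_ids=_gene_ids(config.G),
        sample_ids=[f"pre{m:02d}" for m in range(config.M)],
    )


def gen_response_profile(
    panel: ReferencePanel, omega: np.ndarray, config: GeneratorConfig
):
    """Hidden treatment-response profile with planted fold changes.

    Starts from the blend omega.B, multiplies the planted genes by
    2^(+-effect_size) (half up, half down) and renormalizes.  Planted genes
    are drawn from genes above the 40th expression percentile of the blend —
    fold changes on essentially unexpressed genes are not meaningful signal.
    Returns ``(response, achieved_log2fc, planted_gene_ids)`` where the
    achieved changes are the exact per-gene log2 ratios after renormalization.
    """
    rng = _rng(config, 1)
    base = floored_blend(panel.values, np.asarray(omega, dtype=float))
    r = base.copy()
    planted_idx = np.array([], dtype=int)
    if config.n_de_genes > 0:
        cutoff = np.quantile(base, 0.4)
        candidates = np.nonzero(base >= cutoff)[0]
        if candidates.size < config.n_de_genes:
            candidates = np.arange(config.G)
        planted_idx = np.sort(
            rng.choice(candidates, size=config.n_de_genes, replace=False)
        )
        signs = np.ones(config.n_de_genes)
        signs[(config.n_de_genes + 1) // 2 :] = -1.0
        r[planted_idx] = r[planted_idx] * 2.0 ** (signs * config.effect_size)
    r = r / r.sum()
    achieved = np.log2(r) - np.log2(base)
    gene_ids = list(panel.gene_ids)
    response = ResponseProfile(values=r, gene_ids=gene_ids)
    achieved_series = pd.Series(achieved, index=gene_ids, name="true_log2fc")
    planted_ids = [gene_ids[i] for i in planted_idx]
    return response, achieved_series, planted_ids


def gen_mixture_weights(config: GeneratorConfig):
    """True theta rows: response weight U[lo, hi]; of the remaining mass,
    ``paired_fraction`` goes to the sample's paired reference and the rest is
    spread Dirichlet-uniformly over the other references.

    Returns ``(MixtureWeights, paired_reference_indices)``.
    """
    rng = _rng(config, 2)
    lo, hi = config.response_range
    w = rng.uniform(lo, hi, size=config.N)
    paired = np.arange(config.N) % config.M
    theta = np.zeros((config.N, config.M + 1))
    for n in range(config.N):
        naive = 1.0 - w[n]
        if config.M == 1:
            theta[n, 0] = naive
        else:
            others = rng.dirichlet(np.ones(config.M - 1))
            weights = np.empty(config.M)
            weights[paired[n]] = config.paired_fraction
            rest = np.delete(np.arange(config.M), paired[n])
            weights[rest] = (1.0 - config.paired_fraction) * others
            theta[n, : config.M] = naive * weights
        theta[n, config.M] = w[n]
    return MixtureWeights(theta), paired


def gen_post_counts(
    panel: ReferencePanel,
    response: ResponseProfile,
    truth: SyntheticTruth,
    config: GeneratorConfig,
) -> CountMatrix:
    """Multinomial draws of ``total_counts`` trials from each true mixture.

    With ``overdispersion_sigma > 0`` each sample's mixture probabilities are
    multiplied by per-gene log-normal factors and renormalized first, giving a
    misspecified (overdispersed) cohort for robustness checks.
    """
    rng = _rng(config, 3)
    vals = np.empty((config.G, config.N), dtype=np.int64)
    for n in range(config.N):
        p = mixture_profile(panel, response, truth.true_theta.values[n])
        if config.overdispersion_sigma > 0:
            p = p * rng.lognormal(0.0, config.overdispersion_sigma, size=config.G)
            p = p / p.sum()
        vals[:, n] = rng.multinomial(config.total_counts, p / p.sum())
    return CountMatrix(
        values=vals,
        gene_ids=list(panel.gene_ids),
        sample_ids=[f"post{n:02d}" for n in range(config.N)],
    )


def _repair_monotone(base: np.ndarray, follow: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Decrement integer follow-ups along ``order`` until achieved reductions
    are strictly increasing (used only at clinical noise 0, where integer
    rounding would otherwise break exact rank agreement)."""
    follow = follow.copy()
    prev = -np.inf
    for n in order:
        red = (base[n] - follow[n]) / base[n]
        while red <= prev and follow[n] > 0:
            follow[n] -= 1
            red = (base[n] - follow[n]) / base[n]
        prev = red
    return follow


def gen_clinical(truth: SyntheticTruth, config: GeneratorConfig) -> ClinicalTable:
    """Clinical indicators whose percent reductions track the true response.

    Each indicator's reduction fraction is an affine (monotone) transform of
    the true response weight mapping [lo, hi] onto [0.1, 0.9], plus N(0,
    clinical_noise) noise, clipped to [0, 0.95].  Joint counts are integers;
    PGA and ESR stay real-valued.  At noise 0 the integer follow-ups are
    repaired so the achieved reductions are exactly rank-identical to the
    true weights.
    """
    rng = _rng(config, 4)
    w = truth.response_weights
    lo, hi = config.response_range
    span = max(hi - lo, 1e-12)
    target = 0.1 + 0.8 * (w - lo) / span
    N = w.size

    ids = [f"post{n:02d}" for n in range(N)]
    data = {"patient_id": ids}
    baselines = {
        "pga": rng.uniform(3.0, 8.0, size=N),
        "esr": rng.uniform(10.0, 60.0, size=N),
        "active": rng.integers(20, 41, size=N).astype(float),
        "lrm": rng.integers(10, 31, size=N).astype(float),
    }
    order = np.argsort(w, kind="stable")
    for ind, base in baselines.items():
        t = np.clip(target + rng.normal(0.0, config.clinical_noise, size=N), 0.0, 0.95)
        follow = base * (1.0 - t)
        if ind in ("active", "lrm"):
            follow = np.rint(follow)
            if config.clinical_noise == 0:
                follow = _repair_monotone(base, follow, order)
            follow = np.clip(follow, 0, None)
        data[f"{ind}_0"] = base
        data[f"{ind}_6"] = follow
    return ClinicalTable(pd.DataFrame(data, columns=list(CLINICAL_TABLE_COLUMNS)))


CLINICAL_TABLE_COLUMNS = (
    "patient_id",
    "pga_0",
    "pga_6",
    "esr_0",
    "esr_6",
    "active_0",
    "active_6",
    "lrm_0",
    "lrm_6",
)


def gen_celltype_panel(config: GeneratorConfig) -> CellTypePanel:
    """Noisy cell-type archetypes: log-normal expression per gene per type."""
    rng = _rng(config, 5)
    vals = rng.lognormal(mean=2.0, sigma=1.0, size=(config.G, config.n_cell_types))
    labels = [f"celltype_{c:02d}" for c in range(config.n_cell_types)]
    return CellTypePanel(pd.DataFrame(vals, index=_gene_ids(config.G), columns=labels))


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Build a full cohort: panel, counts, clinical table, cell-type panel, truth."""
    panel = gen_reference_panel(config)
    omega = np.full(config.M, 1.0 / config.M)
    response, achieved, planted_ids = gen_response_profile(panel, omega, config)
    theta, paired = gen_mixture_weights(config)
    truth = SyntheticTruth(
        true_theta=theta,
        true_response=response,
        planted_gene_ids=planted_ids,
        planted_log2fc=achieved,
        paired_reference=paired,
        seed=config.seed,
    )
    counts = gen_post_counts(panel, response, truth, config)
    clinical = gen_clinical(truth, config)
    celltypes = gen_celltype_panel(config)
    return SyntheticCohort(
        panel=panel,
        counts=counts,
        clinical=clinical,
        celltypes=celltypes,
        truth=truth,
        config=config,
    )
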