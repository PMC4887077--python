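"""Domain types and probability computations for the treatment-response mixture model.

The model treats each post-treatment expression profile as a multinomial draw
from a convex mixture of (a) the cohort's pre-treatment reference profiles and
(b) a single hidden treatment-response profile shared by every patient.  This
module defines the validated containers (reference panel, count matrix, mixture
weights, response profile, hyperparameters, model state) and the elementary
density computations the fitting machinery is built from.

Conventions
-----------
* ``B`` is the G x M column-stochastic reference panel; ``P`` the G x N count
  matrix of post-treatment profiles; ``r`` the G-simplex response profile.
* ``theta`` is N x (M+1), one simplex row per post-treatment sample; its last
  column is the per-patient "% treatment response".
* The Dirichlet prior on ``r`` has concentration ``kappa * (B @ omega)``.
* All log densities are natural-log; the multinomial log-mass includes its
  count-dependent coefficient so reported likelihoods are fully normalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

from .errors import (
    AlignmentError,
    BoundaryError,
    DegenerateSampleError,
    InvalidInputError,
    InvalidWeightsError,
    NonFiniteLikelihoodError,
)

logger = logging.getLogger("rxdeconv")

#: Floor applied to omega.B entries before they are used as Dirichlet
#: concentrations or as the starting point of r (concentrations must be > 0).
PRIOR_FLOOR = 1e-12

_KAPPA_INIT = 10_000.0


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise InvalidInputError(f"{name} must be a 2-D matrix, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite entries")
    return arr


def _check_ids(ids, n: int, name: str) -> list:
    ids = list(ids)
    if len(ids) != n:
        raise InvalidInputError(f"{name}: expected {n} identifiers, got {len(ids)}")
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InvalidInputError(f"{name}: duplicate identifiers {dupes[:5]}")
    return ids


@dataclass(frozen=True)
class ReferencePanel:
    """Column-stochastic G x M matrix of pre-treatment profiles (``B``)."""

    values: np.ndarray
    gene_ids: list
    sample_ids: list

    def __post_init__(self):
        vals = _as_float_array(self.values, "ReferencePanel.values")
        if vals.shape[0] < 2 or vals.shape[1] < 1:
            raise InvalidInputError(
                f"ReferencePanel requires G >= 2 and M >= 1, got shape {vals.shape}"
            )
        if np.any(vals < 0):
            raise InvalidInputError("ReferencePanel entries must be non-negative")
        colsums = vals.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-10):
            worst = int(np.argmax(np.abs(colsums - 1.0)))
            raise InvalidInputError(
                f"ReferencePanel column {worst} sums to {colsums[worst]!r}, not 1"
            )
        object.__setattr__(self, "values", vals)
        object.__setattr__(
            self, "gene_ids", _check_ids(self.gene_ids, vals.shape[0], "gene_ids")
        )
        object.__setattr__(
            self, "sample_ids", _check_ids(self.sample_ids, vals.shape[1], "sample_ids")
        )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class CountMatrix:
    """G x N matrix of non-negative integer post-treatment counts (``P``)."""

    values: np.ndarray
    gene_ids: list
    sample_ids: list

    def __post_init__(self):
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise InvalidInputError("CountMatrix.values must be 2-D")
        if not np.all(np.isfinite(vals.astype(float))):
            raise InvalidInputError("CountMatrix contains non-finite entries")
        if np.any(vals < 0):
            raise InvalidInputError("CountMatrix entries must be non-negative")
        rounded = np.rint(vals).astype(np.int64)
        if np.any(np.abs(vals - rounded) > 1e-9):
            raise InvalidInputError("CountMatrix entries must be integers")
        object.__setattr__(self, "values", rounded)
        object.__setattr__(
            self, "gene_ids", _check_ids(self.gene_ids, rounded.shape[0], "gene_ids")
        )
        object.__setattr__(
            self,
            "sample_ids",
            _check_ids(self.sample_ids, rounded.shape[1], "sample_ids"),
        )

    @property
    def totals(self) -> np.ndarray:
        """Per-sample count sums."""
        return self.values.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class MixtureWeights:
    """N x (M+1) matrix; row n is theta_n, last column the % treatment response."""

    values: np.ndarray

    def __post_init__(self):
        vals = _as_float_array(self.values, "MixtureWeights.values")
        if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
            raise InvalidInputError("MixtureWeights entries must lie in [0, 1]")
        rowsums = vals.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-8):
            worst = int(np.argmax(np.abs(rowsums - 1.0)))
            raise InvalidInputError(
                f"MixtureWeights row {worst} sums to {rowsums[worst]!r}, not 1"
            )
        object.__setattr__(self, "values", np.clip(vals, 0.0, 1.0))

    @property
    def response_weights(self) -> np.ndarray:
        """The (M+1)-th column: per-patient % treatment response."""
        return self.values[:, -1]


@dataclass(frozen=True)
class ResponseProfile:
    """Strictly positive G-simplex treatment-response profile (``r``)."""

    values: np.ndarray
    gene_ids: list

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise InvalidInputError("ResponseProfile.values must be 1-D")
        if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
            raise InvalidInputError("ResponseProfile must be strictly positive")
        if abs(vals.sum() - 1.0) > 1e-8:
            raise InvalidInputError(f"ResponseProfile sums to {vals.sum()!r}, not 1")
        object.__setattr__(self, "values", vals)
        object.__setattr__(
            self, "gene_ids", _check_ids(self.gene_ids, vals.size, "gene_ids")
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.gene_ids, name="response")


@dataclass(frozen=True)
class HyperParams:
    """Dirichlet hyperparameters: v (theta prior), omega and kappa (r prior)."""

    v: np.ndarray
    omega: np.ndarray
    kappa: float

    def __post_init__(self):
        v = np.asarray(self.v, dtype=float)
        omega = np.asarray(self.omega, dtype=float)
        if np.any(v < 1.0):
            raise InvalidInputError("HyperParams.v entries must be >= 1")
        if np.any(omega < 0) or abs(omega.sum() - 1.0) > 1e-8:
            raise InvalidInputError("HyperParams.omega must be a simplex vector")
        if not self.kappa > 0:
            raise InvalidInputError("HyperParams.kappa must be positive")
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "kappa", float(self.kappa))


@dataclass(frozen=True)
class ModelState:
    """All fitted quantities plus the per-outer-iteration likelihood trace."""

    panel: ReferencePanel
    counts: CountMatrix
    theta: MixtureWeights
    response: ResponseProfile
    hyper: HyperParams
    loglik_trace: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        G, M = self.panel.values.shape
        N = self.counts.n_samples
        if self.counts.n_genes != G:
            raise AlignmentError(
                f"counts have {self.counts.n_genes} genes, panel has {G}"
            )
        if list(self.counts.gene_ids) != list(self.panel.gene_ids):
            raise AlignmentError("counts and panel gene identifiers differ")
        if self.theta.values.shape != (N, M + 1):
            raise InvalidInputError(
                f"theta shape {self.theta.values.shape} != ({N}, {M + 1})"
            )
        if self.response.values.size != G:
            raise InvalidInputError("response profile length != G")
        if self.hyper.v.size != M + 1 or self.hyper.omega.size != M:
            raise InvalidInputError("hyperparameter dimensions inconsistent with panel")

    def with_(self, **kwargs) -> "ModelState":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)

    @property
    def prior_mean_profile(self) -> np.ndarray:
        """omega . B, floored away from zero and renormalized (G-vector)."""
        return floored_blend(self.panel.values, self.hyper.omega)


def floored_blend(B: np.ndarray, omega: np.ndarray, floor: float = PRIOR_FLOOR) -> np.ndarray:
    """Convex blend ``B @ omega`` floored at ``floor`` and renormalized.

    The blend parameterizes the mean direction of r's Dirichlet prior; its
    entries must be strictly positive to be valid concentrations.
    """
    m = B @ omega
    m = np.maximum(m, floor)
    return m / m.sum()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def normalize_reference(raw) -> ReferencePanel:
    """Scale every column of a gene x sample matrix to sum to one.

    Parameters
    ----------
    raw : pandas.DataFrame
        Non-negative gene x sample matrix; index = gene ids, columns = sample
        ids.

    Returns
    -------
    ReferencePanel
        The column-stochastic panel, gene order preserved.
    """
    if not isinstance(raw, pd.DataFrame):
        raise InvalidInputError("normalize_reference expects a pandas DataFrame")
    vals = _as_float_array(raw.to_numpy(dtype=float), "reference matrix")
    if np.any(vals < 0):
        raise InvalidInputError("reference matrix contains negative entries")
    colsums = vals.sum(axis=0)
    zero = np.nonzero(colsums == 0)[0]
    if zero.size:
        raise DegenerateSampleError(
            f"reference column(s) {[raw.columns[i] for i in zero]} sum to zero"
        )
    return ReferencePanel(
        values=vals / colsums, gene_ids=list(raw.index), sample_ids=list(raw.columns)
    )


def _largest_remainder(col: np.ndarray, target_total: int) -> np.ndarray:
    """Round a non-negative column to integers summing exactly to target_total."""
    total = col.sum()
    scaled = col * (target_total / total)
    base = np.floor(scaled).astype(np.int64)
    shortfall = int(target_total - base.sum())
    if shortfall:
        remainders = scaled - base
        # stable argsort on negated remainders: ties go to the lowest index
        order = np.argsort(-remainders, kind="stable")
        base[order[:shortfall]] += 1
    return base


def discretize_counts(raw, target_total: int = 1_000_000) -> CountMatrix:
    """Rescale each column to ``target_total`` and round by largest remainder.

    Each integer column sums to ``target_total`` exactly, so the multinomial
    totals are equalized across samples at the requested precision.
    """
    if not isinstance(raw, pd.DataFrame):
        raise InvalidInputError("discretize_counts expects a pandas DataFrame")
    if target_total < 1:
        raise InvalidInputError("target_total must be a positive integer")
    vals = _as_float_array(raw.to_numpy(dtype=float), "count matrix")
    if np.any(vals < 0):
        raise InvalidInputError("count matrix contains negative entries")
    if target_total < vals.shape[0]:
        logger.warning(
            "discretize_counts: target_total %d < G=%d genes; resolution is coarse",
            target_total,
            vals.shape[0],
        )
    colsums = vals.sum(axis=0)
    zero = np.nonzero(colsums == 0)[0]
    if zero.size:
        raise DegenerateSampleError(
            f"count column(s) {[raw.columns[i] for i in zero]} sum to zero"
        )
    out = np.empty(vals.shape, dtype=np.int64)
    for j in range(vals.shape[1]):
        out[:, j] = _largest_remainder(vals[:, j], int(target_total))
    return CountMatrix(values=out, gene_ids=list(raw.index), sample_ids=list(raw.columns))


def mixture_profile(
    panel: ReferencePanel, response: ResponseProfile, theta_row: np.ndarray
) -> np.ndarray:
    """Return ``[B r] @ theta_row``: the mixture distribution for one sample."""
    theta_row = np.asarray(theta_row, dtype=float)
    M = panel.n_samples
    if theta_row.shape != (M + 1,):
        raise InvalidWeightsError(f"theta_row must have length {M + 1}")
    s = theta_row.sum()
    if np.any(theta_row < -1e-6) or abs(s - 1.0) > 1e-6:
        raise InvalidWeightsError(
            f"theta_row off the simplex (sum={s!r}, min={theta_row.min()!r})"
        )
    theta_row = np.clip(theta_row, 0.0, None) / np.clip(theta_row, 0.0, None).sum()
    return panel.values @ theta_row[:M] + theta_row[M] * response.values


def multinomial_loglik(counts_col: np.ndarray, probs: np.ndarray) -> float:
    """Full multinomial log-mass, including the log multinomial coefficient.

    Uses the convention 0*log(0)=0; if some category has positive count but
    zero probability the mass is zero and -inf is returned (with a warning).
    """
    counts_col = np.asarray(counts_col)
    probs = np.asarray(probs, dtype=float)
    if counts_col.shape != probs.shape:
        raise InvalidInputError("counts and probs must have the same length")
    if np.any(counts_col < 0):
        raise InvalidInputError("counts must be non-negative")
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-8:
        raise InvalidInputError("probs must be a simplex vector (tolerance 1e-8)")
    if np.any((counts_col > 0) & (probs == 0)):
        logger.warning("multinomial_loglik: positive count on zero-probability gene")
        return float("-inf")
    total = counts_col.sum()
    coeff = gammaln(total + 1.0) - gammaln(counts_col + 1.0).sum()
    return float(coeff + xlogy(counts_col, probs).sum())


def dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    """Log density of Dirichlet(alpha) at an interior simplex point x."""
    x = np.asarray(x, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if x.shape != alpha.shape:
        raise InvalidInputError("x and alpha must have the same length")
    if np.any(alpha <= 0):
        raise InvalidInputError("Dirichlet concentrations must be positive")
    if np.any(x <= 0):
        raise BoundaryError(
            "Dirichlet density requested on the simplex boundary; "
            "use an interior parameterization"
        )
    return float(
        gammaln(alpha.sum())
        - gammaln(alpha).sum()
        + ((alpha - 1.0) * np.log(x)).sum()
    )


def complete_loglik(state: ModelState) -> float:
    """ln P(r | kappa omega B) + sum_n [ln P(theta_n | v) + ln P(p_n | B, r, theta_n)].

    Raises
    ------
    NonFiniteLikelihoodError
        If any term is NaN (a -inf multinomial term from an impossible count
        pattern is propagated as -inf, not raised).
    """
    B = state.panel.values
    P = state.counts.values
    theta = state.theta.values
    r = state.response.values
    v, omega, kappa = state.hyper.v, state.hyper.omega, state.hyper.kappa

    alpha_r = kappa * floored_blend(B, omega)
    term_r = dirichlet_logpdf(r, alpha_r)
    if np.isnan(term_r):
        raise NonFiniteLikelihoodError("response-profile prior term is NaN")

    term_theta = 0.0
    for n in range(theta.shape[0]):
        term_theta += dirichlet_logpdf(np.maximum(theta[n], 1e-300), v)
    if np.isnan(term_theta):
        raise NonFiniteLikelihoodError("theta prior term is NaN")

    A = np.column_stack([B, r])
    Q = A @ theta.T  # G x N mixture probabilities
    term_mult = 0.0
    for n in range(P.shape[1]):
        term_mult += multinomial_loglik(P[:, n], Q[:, n] / Q[:, n].sum())
    if np.isnan(term_mult):
        raise NonFiniteLikelihoodError("multinomial data term is NaN")

    return float(term_r + term_theta + term_mult)


def init_state(panel: ReferencePanel, counts: CountMatrix, seed: int = 0) -> ModelState:
    """Build the starting state of the optimization.

    theta rows start uniform at 1/(M+1); kappa at 10,000; v entries are drawn
    as 1+U(0,1) for the reference components and 5+U(0,1) for the response
    component (the response weight gets a larger prior because a single
    profile must compete with M references); omega starts uniform and r at
    the prior mean direction omega.B.
    """
    if list(panel.gene_ids) != list(counts.gene_ids):
        raise AlignmentError("panel and counts gene identifiers differ in content/order")
    G, M = panel.values.shape
    N = counts.n_samples
    rng = np.random.default_rng(seed)
    v = np.empty(M + 1)
    v[:M] = 1.0 + rng.uniform(size=M)
    v[M] = 5.0 + rng.uniform()
    omega = np.full(M, 1.0 / M)
    r = floored_blend(panel.values, omega)
    kappa = _KAPPA_INIT
    kappa_floor = max(1.0, 1.0 / float(r.min()))
    if kappa < kappa_floor:
        logger.info(
            "init_state: raising kappa %.4g -> %.4g so all prior concentrations are >= 1",
            kappa,
            kappa_floor,
        )
        kappa = kappa_floor
    hyper = HyperParams(v=v, omega=omega, kappa=kappa)
    theta = MixtureWeights(np.full((N, M + 1), 1.0 / (M + 1)))
    return ModelState(
        panel=panel,
        counts=counts,
        theta=theta,
        response=ResponseProfile(values=r, gene_ids=list(panel.gene_ids)),
        hyper=hyper,
        loglik_trace=[],
        seed=int(seed),
    )
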