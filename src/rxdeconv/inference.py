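"""MAP estimation by block conjugate-gradient ascent with random restarts.

The complete log posterior is maximized over five blocks — theta (mixture
weights), r (response profile), v (theta-prior concentrations), omega
(response-prior blend weights) and kappa (response-prior strength) — cycled
in that fixed order.  Each block is optimized in an unconstrained space
(softmax for simplex blocks, log(v-1) and log(kappa) for the positives) with
Polak-Ribiere conjugate gradients, so simplex and positivity constraints are
maintained exactly at every step.  Every block update is guarded: a step that
would lower the objective is discarded and the input state returned, which
makes the outer likelihood trace non-decreasing by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, xlogy

from .errors import FitFailureError, InvalidInputError
from .model_core import (
    CountMatrix,
    HyperParams,
    MixtureWeights,
    ModelState,
    ReferencePanel,
    ResponseProfile,
    complete_loglik,
    floored_blend,
    init_state,
)

logger = logging.getLogger("rxdeconv")

BLOCKS = ("theta", "response", "v", "omega", "kappa")

# slack for the ascent guard, relative to |loglik before|
_ASCENT_SLACK = 1e-9


@dataclass(frozen=True)
class FitConfig:
    """Optimization settings.

    ``rel_tol`` is the convergence criterion on the relative change of the
    complete log likelihood between outer iterations; ``update_blocks`` allows
    freezing blocks (used by the gene-subset sensitivity machinery and by
    small-scale oracle checks).
    """

    max_outer_iterations: int = 35
    rel_tol: float = 1e-7
    n_restarts: int = 10
    cg_max_steps: int = 100
    seed: int = 0
    update_blocks: tuple = BLOCKS

    def __post_init__(self):
        if self.max_outer_iterations < 1:
            raise InvalidInputError("max_outer_iterations must be >= 1")
        if not self.rel_tol > 0:
            raise InvalidInputError("rel_tol must be positive")
        if self.n_restarts < 1:
            raise InvalidInputError("n_restarts must be >= 1")
        unknown = set(self.update_blocks) - set(BLOCKS)
        if unknown:
            raise InvalidInputError(f"unknown blocks {sorted(unknown)}")


@dataclass(frozen=True)
class FitResult:
    """Best restart's state plus bookkeeping across restarts."""

    best_state: ModelState
    per_restart_logliks: list = field(default_factory=list)
    converged: bool = False
    iterations_used: int = 0


# ---------------------------------------------------------------------------
# reparameterizations
# ---------------------------------------------------------------------------


def _softmax(y: np.ndarray, axis: int = -1) -> np.ndarray:
    z = y - y.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _softmax_chain(x: np.ndarray, grad_x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Gradient w.r.t. softmax logits given gradient w.r.t. the simplex point."""
    inner = (x * grad_x).sum(axis=axis, keepdims=True)
    return x * (grad_x - inner)


# ---------------------------------------------------------------------------
# block objectives (value and gradient in the unconstrained space)
# ---------------------------------------------------------------------------


def _theta_objective(state: ModelState):
    """Terms of the log posterior that depend on theta, as f(y), y = logits."""
    B = state.panel.values
    P = state.counts.values
    r = state.response.values
    v = state.hyper.v
    A = np.column_stack([B, r])  # G x (M+1)

    def value_grad(y_flat: np.ndarray):
        y = y_flat.reshape(P.shape[1], -1)
        theta = _softmax(y, axis=1)
        theta = np.maximum(theta, 1e-300)
        Q = A @ theta.T  # G x N
        f = xlogy(P, Q).sum() + ((v - 1.0) * np.log(theta)).sum()
        G_theta = (A.T @ (P / Q)).T + (v - 1.0) / theta
        g = _softmax_chain(theta, G_theta, axis=1)
        return -f, -g.ravel()

    return value_grad


def _response_objective(state: ModelState):
    B = state.panel.values
    P = state.counts.values
    theta = state.theta.values
    alpha = state.hyper.kappa * floored_blend(B, state.hyper.omega)
    w_resp = theta[:, -1]  # N response weights
    base = B @ theta[:, :-1].T  # G x N, fixed while r moves

    def value_grad(y: np.ndarray):
        r = _softmax(y)
        r = np.maximum(r, 1e-300)
        Q = base + np.outer(r, w_resp)
        f = xlogy(P, Q).sum() + ((alpha - 1.0) * np.log(r)).sum()
        grad_r = (P / Q) @ w_resp + (alpha - 1.0) / r
        g = _softmax_chain(r, grad_r)
        return -f, -g

    return value_grad


def _v_objective(state: ModelState):
    theta = np.maximum(state.theta.values, 1e-300)
    S = np.log(theta).sum(axis=0)  # per-component sum of log theta over patients
    N = theta.shape[0]

    def value_grad(u: np.ndarray):
        v = 1.0 + np.exp(u)
        f = N * (gammaln(v.sum()) - gammaln(v).sum()) + ((v - 1.0) * S).sum()
        grad_v = N * (digamma(v.sum()) - digamma(v)) + S
        return -f, -(grad_v * (v - 1.0))

    return value_grad


def _omega_objective(state: ModelState):
    B = state.panel.values
    kappa = state.hyper.kappa
    log_r = np.log(state.response.values)

    def value_grad(y: np.ndarray):
        omega = _softmax(y)
        m = floored_blend(B, omega)
        # the kappa floor (all concentrations >= 1) is coupled to omega: an
        # omega move that lowers min(B omega) implicitly raises kappa, so the
        # effective strength is evaluated inside the objective.
        k_min = _kappa_floor(m)
        c_all_sum = digamma((max(kappa, k_min) * m).sum())
        if kappa >= k_min:
            alpha = kappa * m
            f = gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1.0) * log_r).sum()
            grad_m = kappa * (c_all_sum - digamma(alpha) + log_r)
        else:
            j = int(np.argmin(m))
            alpha = m / m[j]
            f = gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1.0) * log_r).sum()
            c = c_all_sum - digamma(alpha) + log_r
            c[j] = 0.0  # alpha_j == 1 is stationary in its own coordinate
            grad_m = c / m[j]
            grad_m[j] -= (m * c).sum() / m[j] ** 2
        # for interior omega the floor/renormalization in floored_blend are
        # inactive to first order (sum(B omega) = 1): plain chain rule via B.
        grad_omega = B.T @ grad_m
        g = _softmax_chain(omega, grad_omega)
        return -f, -g

    return value_grad


def _kappa_floor(m: np.ndarray) -> float:
    """Lower bound on kappa keeping every Dirichlet concentration >= 1.

    With any kappa*m entry below 1 the prior density diverges on the simplex
    boundary and the MAP for r collapses genes to zero; constraining kappa
    above 1/min(m) keeps the posterior mode interior and well-posed.
    """
    return max(1.0, 1.0 / float(m.min()))


def _kappa_objective(state: ModelState):
    m = floored_blend(state.panel.values, state.hyper.omega)
    log_r = np.log(state.response.values)
    k_min = _kappa_floor(m)

    def value_grad(u: np.ndarray):
        kappa = k_min + float(np.exp(u[0]))
        alpha = kappa * m
        f = gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1.0) * log_r).sum()
        dk = (m * (digamma(alpha.sum()) - digamma(alpha) + log_r)).sum()
        return -f, np.array([-dk * (kappa - k_min)])

    return value_grad


def _block_start(state: ModelState, block: str) -> np.ndarray:
    if block == "theta":
        return np.log(np.maximum(state.theta.values, 1e-300)).ravel()
    if block == "response":
        return np.log(state.response.values)
    if block == "v":
        return np.log(np.maximum(state.hyper.v - 1.0, 1e-12))
    if block == "omega":
        return np.log(np.maximum(state.hyper.omega, 1e-300))
    if block == "kappa":
        m = floored_blend(state.panel.values, state.hyper.omega)
        k_min = _kappa_floor(m)
        return np.array([np.log(max(state.hyper.kappa - k_min, 1e-6 * k_min))])
    raise InvalidInputError(f"unknown block {block!r}")


def _apply_block(state: ModelState, block: str, y: np.ndarray) -> ModelState:
    if block == "theta":
        theta = _softmax(y.reshape(state.theta.values.shape), axis=1)
        return state.with_(theta=MixtureWeights(theta))
    if block == "response":
        r = _softmax(y)
        r = np.maximum(r, 1e-300)
        r = r / r.sum()
        return state.with_(
            response=ResponseProfile(values=r, gene_ids=list(state.panel.gene_ids))
        )
    if block == "v":
        v = 1.0 + np.exp(y)
        return state.with_(hyper=HyperParams(v=v, omega=state.hyper.omega, kappa=state.hyper.kappa))
    if block == "omega":
        omega = _softmax(y)
        kappa = state.hyper.kappa
        k_min = _kappa_floor(floored_blend(state.panel.values, omega))
        if kappa < k_min:
            logger.warning(
                "omega update lowered min(omega.B); raising kappa %.4g -> floor %.4g",
                kappa,
                k_min,
            )
            kappa = k_min
        return state.with_(hyper=HyperParams(v=state.hyper.v, omega=omega, kappa=kappa))
    if block == "kappa":
        m = floored_blend(state.panel.values, state.hyper.omega)
        k_min = _kappa_floor(m)
        kappa = k_min + float(np.exp(y[0]))
        if kappa <= k_min * (1 + 1e-9):
            logger.warning("kappa floor %.4g is binding (boundary-mode prior guard)", k_min)
        return state.with_(hyper=HyperParams(v=state.hyper.v, omega=state.hyper.omega, kappa=kappa))
    raise InvalidInputError(f"unknown block {block!r}")


def optimize_block(state: ModelState, block: str, cg_max_steps: int = 100) -> ModelState:
    """Maximize the named block's terms of the log posterior, all else fixed.

    Returns a state whose complete log likelihood is never lower than the
    input's (within relative slack 1e-9): if the conjugate-gradient step fails
    to improve the partial objective the input state is returned unchanged.
    """
    objectives = {
        "theta": _theta_objective,
        "response": _response_objective,
        "v": _v_objective,
        "omega": _omega_objective,
        "kappa": _kappa_objective,
    }
    if block not in objectives:
        raise InvalidInputError(f"unknown block {block!r}; expected one of {BLOCKS}")
    value_grad = objectives[block](state)
    y0 = _block_start(state, block)
    res = minimize(
        value_grad,
        y0,
        jac=True,
        method="CG",
        options={"maxiter": int(cg_max_steps), "gtol": 1e-8},
    )
    candidate = _apply_block(state, block, res.x)
    ll0 = complete_loglik(state)
    ll1 = complete_loglik(candidate)
    if not np.isfinite(ll1) or ll1 < ll0 - _ASCENT_SLACK * max(1.0, abs(ll0)):
        logger.warning(
            "optimize_block(%s): step rejected (%.12g -> %.12g); state unchanged",
            block,
            ll0,
            ll1,
        )
        return state
    return candidate


def fit_map(panel: ReferencePanel, counts: CountMatrix, config: FitConfig) -> FitResult:
    """MAP-fit the model with random restarts; keep the highest-likelihood fit.

    Each restart ``k`` initializes from seed ``config.seed + k``, then cycles
    the unfrozen blocks in fixed order until the relative change in complete
    log likelihood drops below ``rel_tol`` or ``max_outer_iterations`` is hit.
    """
    best = None
    best_ll = -np.inf
    per_restart = []
    best_converged = False
    best_iters = 0
    for k in range(config.n_restarts):
        state = init_state(panel, counts, seed=config.seed + k)
        ll = complete_loglik(state)
        trace = [ll]
        converged = False
        iters = 0
        for _ in range(config.max_outer_iterations):
            for block in BLOCKS:
                if block in config.update_blocks:
                    state = optimize_block(state, block, config.cg_max_steps)
            ll_new = complete_loglik(state)
            trace.append(ll_new)
            iters += 1
            if abs(ll_new - ll) < config.rel_tol * max(1.0, abs(ll)):
                converged = True
                ll = ll_new
                break
            ll = ll_new
        per_restart.append(ll)
        logger.info("restart %d: loglik %.6f after %d outer iterations", k, ll, iters)
        if np.isfinite(ll) and ll > best_ll:
            best_ll = ll
            best = state.with_(loglik_trace=list(trace))
            best_converged = converged
            best_iters = iters
    if best is None:
        raise FitFailureError("all restarts produced non-finite likelihoods")
    return FitResult(
        best_state=best,
        per_restart_logliks=per_restart,
        converged=best_converged,
        iterations_used=best_iters,
    )


def extract_treatment_response(result: FitResult) -> pd.Series:
    """Per-patient % treatment response: the last column of theta."""
    state = result.best_state
    return pd.Series(
        state.theta.response_weights,
        index=state.counts.sample_ids,
        name="pct_treatment_response",
    )


def dominant_reference(result: FitResult) -> pd.Series:
    """0-based index of the reference profile with the highest weight per patient.

    Ties break deterministically to the lowest index (numpy argmax).
    """
    state = result.best_state
    M = state.panel.n_samples
    idx = np.argmax(state.theta.values[:, :M], axis=1)
    return pd.Series(idx, index=state.counts.sample_ids, name="dominant_reference")
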