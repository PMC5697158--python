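"""Network inference: lasso-penalized hard EM on the approximate likelihood.

Proteins are unobserved, so the complete log-likelihood
ℓ(θ) = Σ_k log u(P_k; θ) + log v(M_k, P_k; θ) treats the per-cell protein
vector P_k as a latent variable.  The hard-EM (classification-EM) scheme
alternates:

* E-step: per cell, replace the conditional expectation by the mode —
  maximize ℓ over P_k with θ fixed (box-constrained multistart);
* M-step: maximize ℓ − λ Σ_{i≠j} |θ_ij| over θ with the latent proteins
  fixed, via proximal gradient (ISTA) so off-diagonals shrink to *exact*
  zeros and the inferred topology is unambiguous.

The latent maximization is carried out in logit coordinates z = logit(y):
in the bursty regime the Beta shape a = k_on/d1 of the protein law drops
below 1 and the density diverges at y → 0, so the y-coordinate mode sits
on the boundary and carries no information.  The logit parameterization
absorbs a factor y(1−y) into the density (its Jacobian), which restores a
finite interior mode (at a/(a+b) for a constant-rate gene) and makes the
hard E-step well-posed.  The Jacobian term is independent of θ, so the
M-step is unaffected; the reported objective trace includes it.

All parameters other than θ (promoter rates, degradation rates, Hill
shapes) are assumed known.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .data import SnapshotData
from .network import InteractionParams, NetworkModel
from .stationary import CLIP_EPS, HartreeApprox, clip_unit, log_conditional_mrna

__all__ = [
    "SnapshotData",
    "InferenceConfig",
    "InferenceResult",
    "complete_log_likelihood",
    "penalized_objective",
    "e_step_hard",
    "m_step",
    "fit_hard_em",
    "structure_of",
]


@dataclass(frozen=True)
class InferenceConfig:
    """Settings of the hard-EM fit.

    ``lambda_penalty`` weighs the L1 penalty on off-diagonal θ entries;
    ``theta_init=None`` starts from the null matrix (the "balanced
    behaviours" prior guess).  ``tol`` is the relative change of the
    penalized objective at which the sweep loop stops.
    """

    lambda_penalty: float = 0.0
    pair_penalty: float = 1.0
    theta_init: Optional[np.ndarray] = None
    max_iter: int = 200
    tol: float = 1e-6
    seed: int = 0
    eps: float = CLIP_EPS
    m_step_max_iter: int = 200
    e_step_maxfun: int = 400

    def __post_init__(self) -> None:
        if self.lambda_penalty < 0:
            raise ValueError("lambda_penalty must be nonnegative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class InferenceResult:
    """Output of a hard-EM fit."""

    theta_hat: np.ndarray
    P_hat: np.ndarray
    objective_trace: np.ndarray
    structure: np.ndarray
    converged: bool
    n_sweeps: int


def _with_theta(model: NetworkModel, theta: np.ndarray) -> NetworkModel:
    """Copy of the model with a replaced interaction matrix θ."""
    inter = InteractionParams(
        theta=np.asarray(theta, dtype=float),
        hill_m=model.interactions.hill_m,
        hill_s=model.interactions.hill_s,
    )
    return dataclasses.replace(model, interactions=inter)


class _Likelihood:
    """Vectorized per-cell complete log-likelihood, reusing mixture constants.

    The Beta-mixture shape constants depend only on the (fixed) kinetic
    rates, so they are computed once; only the regulatory field Φ changes
    with θ.
    """

    def __init__(self, model: NetworkModel, X: np.ndarray, mask: np.ndarray, eps: float):
        self.model = model
        self.X = clip_unit(X, eps)
        self.mask = np.asarray(mask, bool)
        self.eps = eps
        self._mixtures = HartreeApprox.from_model(model).mixtures

    def _approx(self, model: NetworkModel) -> HartreeApprox:
        return HartreeApprox(model=model, mixtures=self._mixtures)

    def per_cell(self, theta: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """ℓ_k = log u(P_k) + log v(M_k, P_k) for every cell (shape (m,))."""
        model = _with_theta(self.model, theta)
        Yc = clip_unit(Y, self.eps)
        log_u = self._approx(model).log_density(Yc, self.eps)
        log_v = log_conditional_mrna(self.X, Yc, model, self.mask, self.eps)
        return log_u + log_v

    def total(self, theta: np.ndarray, Y: np.ndarray) -> float:
        return float(np.sum(self.per_cell(theta, Y)))

    @staticmethod
    def log_jacobian(Y: np.ndarray) -> np.ndarray:
        """Per-cell log-Jacobian Σ_i log(y_i (1−y_i)) of the logit map."""
        Yc = clip_unit(Y)
        return np.sum(np.log(Yc) + np.log1p(-Yc), axis=-1)

    def per_cell_logit(self, theta: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """ℓ_k plus the logit-coordinate Jacobian (the E-step objective)."""
        return self.per_cell(theta, Y) + self.log_jacobian(Y)

    def total_logit(self, theta: np.ndarray, Y: np.ndarray) -> float:
        return float(np.sum(self.per_cell_logit(theta, Y)))


def complete_log_likelihood(
    X_row: np.ndarray,
    y: np.ndarray,
    model: NetworkModel,
    mask_row: Optional[np.ndarray] = None,
    eps: float = CLIP_EPS,
) -> float:
    """Approximate complete log-likelihood of one cell: log u(y) + log v(x, y).

    u is the Hartree stationary protein density (mixture form for genes with
    auto-activation, single-Beta otherwise) and v the conditional mRNA law;
    masked genes drop out of v.
    """
    x = np.atleast_1d(np.asarray(X_row, float))
    mask = np.ones(model.n, bool) if mask_row is None else np.asarray(mask_row, bool)
    lik = _Likelihood(model, x[None, :], mask[None, :], eps)
    val = lik.total(model.interactions.theta, np.atleast_1d(np.asarray(y, float))[None, :])
    if not np.isfinite(val):
        raise FloatingPointError("complete log-likelihood is not finite for this cell")
    return val


def _l1_offdiag(theta: np.ndarray) -> float:
    return float(np.sum(np.abs(theta)) - np.sum(np.abs(np.diag(theta))))


def _pair_min(theta: np.ndarray) -> float:
    """Σ_{i<j} min(|θ_ij|, |θ_ji|): the reciprocal-pair redundancy term."""
    a = np.abs(theta)
    n = theta.shape[0]
    return float(
        sum(min(a[i, j], a[j, i]) for i in range(n) for j in range(i + 1, n))
    )


def _offdiag_penalty(theta: np.ndarray, mu: float) -> float:
    """Lasso penalty with an extra charge on the weaker member of each
    reciprocal pair, so that a spuriously split interaction collapses onto
    one direction (plain L1 is indifferent to such splits)."""
    return _l1_offdiag(theta) + mu * _pair_min(theta)


def penalized_objective(
    theta: np.ndarray,
    latent_P: np.ndarray,
    data: SnapshotData,
    model: NetworkModel,
    config: InferenceConfig,
) -> float:
    """Σ_k ℓ_k − λ·[Σ_{i≠j} |θ_ij| + μ Σ_{i<j} min(|θ_ij|, |θ_ji|)].

    Diagonal entries are unpenalized; μ (``config.pair_penalty``) charges
    the weaker member of each reciprocal pair a second time.
    """
    lik = _Likelihood(model, data.X, data.mask, config.eps)
    pen = _offdiag_penalty(np.asarray(theta, float), config.pair_penalty)
    return lik.total(np.asarray(theta, float), latent_P) - config.lambda_penalty * pen


def _latent_starts(
    lik: _Likelihood,
    theta: np.ndarray,
    warm: Optional[np.ndarray],
    full: bool = True,
) -> list[np.ndarray]:
    """Candidate initial latent-protein matrices for the E-step.

    With ``full`` the combinations of per-gene promoter frequency-mode
    occupancies are added (2^n for small n); warm restarts within later EM
    sweeps can skip them.
    """
    model = lik.model
    m, n = lik.X.shape
    starts: list[np.ndarray] = []
    if warm is not None:
        starts.append(warm)
    starts.append(lik.X.copy())  # data-informed: proteins track mRNA
    if full:
        lows, highs = np.empty(n), np.empty(n)
        for i, kin in enumerate(model.kinetics):
            b = kin.koff / kin.d1
            lows[i] = (kin.k0 / kin.d1) / (kin.k0 / kin.d1 + b)
            highs[i] = (kin.k1 / kin.d1) / (kin.k1 / kin.d1 + b)
        if n <= 4:
            for bits in range(2**n):
                y = np.array([highs[i] if (bits >> i) & 1 else lows[i] for i in range(n)])
                starts.append(np.tile(y, (m, 1)))
        else:
            starts.append(np.tile(lows, (m, 1)))
            starts.append(np.tile(highs, (m, 1)))
    return starts


_Z_BOUND = 25.0  # |logit(y)| cap: y within [expit(-25), expit(25)]


def _maximize_latent(
    lik: _Likelihood,
    theta: np.ndarray,
    starts: list[np.ndarray],
    eps: float,
    maxfun: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Best latent proteins per cell over all starts (elementwise argmax).

    Works in logit coordinates z = logit(y).  The objective is separable
    across cells, so a joint box-constrained quasi-Newton run over all
    cells converges to per-cell maxima; gradients are central finite
    differences computed gene-by-gene in a vectorized pass (2n likelihood
    sweeps per gradient).
    """
    from scipy.special import expit, logit

    m, n = lik.X.shape
    h = 1e-5

    def value_and_grad(flat: np.ndarray):
        Z = flat.reshape(m, n)
        f = lik.per_cell_logit(theta, expit(Z))
        grad = np.empty((m, n))
        for i in range(n):
            Zp, Zm = Z.copy(), Z.copy()
            Zp[:, i] = Z[:, i] + h
            Zm[:, i] = Z[:, i] - h
            grad[:, i] = (
                lik.per_cell_logit(theta, expit(Zp)) - lik.per_cell_logit(theta, expit(Zm))
            ) / (2 * h)
        return -np.sum(f), -grad.ravel()

    best_Y, best_f = None, None
    bounds = [(-_Z_BOUND, _Z_BOUND)] * (m * n)
    for Y0 in starts:
        Z0 = np.clip(logit(np.clip(Y0, 1e-9, 1 - 1e-9)), -_Z_BOUND, _Z_BOUND)
        res = optimize.minimize(
            value_and_grad,
            Z0.ravel(),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxfun": maxfun, "ftol": 1e-12, "gtol": 1e-8},
        )
        Y = expit(res.x.reshape(m, n))
        f = lik.per_cell_logit(theta, Y)
        # also keep the raw start in the comparison: never move downhill
        Y0c = expit(Z0)
        f0 = lik.per_cell_logit(theta, Y0c)
        cand_Y = np.where((f >= f0)[:, None], Y, Y0c)
        cand_f = np.maximum(f, f0)
        if best_Y is None:
            best_Y, best_f = cand_Y, cand_f
        else:
            take = cand_f > best_f
            best_Y = np.where(take[:, None], cand_Y, best_Y)
            best_f = np.maximum(best_f, cand_f)
    return best_Y, best_f


def e_step_hard(
    theta: np.ndarray,
    data: SnapshotData,
    model: NetworkModel,
    config: InferenceConfig,
    warm_start: Optional[np.ndarray] = None,
    full_starts: bool = True,
) -> np.ndarray:
    """Hard E-step: per-cell mode of the latent protein vector.

    Maximizes log u(y) + log v(x, y) over y in the open unit box for each
    cell, by multistart box-constrained quasi-Newton (Hartree frequency-mode
    combinations plus the data-informed start y = x, plus an optional warm
    start).  Deterministic.
    """
    lik = _Likelihood(model, data.X, data.mask, config.eps)
    theta = np.asarray(theta, float)
    starts = _latent_starts(lik, theta, warm_start, full=full_starts)
    Y, _ = _maximize_latent(lik, theta, starts, config.eps, config.e_step_maxfun)
    return Y


def _soft_threshold_offdiag(theta: np.ndarray, t: float, mu: float = 0.0) -> np.ndarray:
    """Prox of the off-diagonal penalty at step size t (diagonal untouched).

    Standard soft thresholding, then — for the reciprocal-pair term — an
    extra shrink of the smaller-magnitude member of each (i,j)/(j,i) pair,
    which is the exact prox of t·μ·min(|a|, |b|) given the separable
    quadratic part.
    """
    out = np.sign(theta) * np.maximum(np.abs(theta) - t, 0.0)
    np.fill_diagonal(out, np.diagonal(theta))
    if mu > 0:
        n = theta.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                a, b = out[i, j], out[j, i]
                if abs(a) <= abs(b):
                    out[i, j] = np.sign(a) * max(abs(a) - t * mu, 0.0)
                else:
                    out[j, i] = np.sign(b) * max(abs(b) - t * mu, 0.0)
    return out


def m_step(
    latent_P: np.ndarray,
    data: SnapshotData,
    model: NetworkModel,
    config: InferenceConfig,
    theta_init: Optional[np.ndarray] = None,
) -> np.ndarray:
    """M-step: maximize the penalized likelihood over θ with proteins fixed.

    Proximal-gradient ascent (ISTA with backtracking) on the smooth
    likelihood term, with soft thresholding of the off-diagonal entries —
    the L1 penalty therefore produces exact zeros.  Gradients of the smooth
    part are central finite differences over the n² entries (each one a
    vectorized pass over all cells).
    """
    lik = _Likelihood(model, data.X, data.mask, config.eps)
    n = model.n
    lam = config.lambda_penalty
    mu = config.pair_penalty
    theta = np.array(
        model.interactions.theta if theta_init is None else theta_init, dtype=float
    )

    def g(th: np.ndarray) -> float:  # smooth part: negative log-likelihood
        return -lik.total(th, latent_P)

    def grad_g(th: np.ndarray) -> np.ndarray:
        h = 1e-5
        out = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                tp, tm = th.copy(), th.copy()
                tp[i, j] += h
                tm[i, j] -= h
                out[i, j] = (g(tp) - g(tm)) / (2 * h)
        return out

    L = 1.0
    g_cur = g(theta)
    n_small = 0  # consecutive near-stationary iterations
    for _ in range(config.m_step_max_iter):
        grad = grad_g(theta)
        accepted = False
        for _ in range(60):
            cand = _soft_threshold_offdiag(theta - grad / L, lam / L, mu)
            diff = cand - theta
            g_cand = g(cand)
            quad = g_cur + np.sum(grad * diff) + 0.5 * L * np.sum(diff * diff)
            if g_cand <= quad + 1e-12:
                accepted = True
                break
            L *= 2.0
        if not accepted:
            break
        obj_old = g_cur + lam * _offdiag_penalty(theta, mu)
        obj_new = g_cand + lam * _offdiag_penalty(cand, mu)
        if obj_new > obj_old + 1e-12:  # safeguard: never go uphill
            break
        theta, g_cur = cand, g_cand
        # decay L after success so a transient backtracking spike cannot
        # freeze the step size (and with it the apparent progress) forever
        L = max(L / 2.0, 1e-3)
        if obj_old - obj_new < 1e-9 * max(1.0, abs(obj_old)):
            n_small += 1
            if n_small >= 5:
                break
        else:
            n_small = 0
    def pen_obj(th: np.ndarray) -> float:
        return -g(th) - lam * _offdiag_penalty(th, mu)

    # coordinate line-search polish: proximal-gradient steps can creep when
    # the init is far in a flat (saturated) region; a few rounds of exact
    # 1-D maximization finish the job (improvements only, so the M-step
    # stays an ascent step).  Applied to the smooth coordinates only —
    # diagonals, and off-diagonals that ISTA left well away from the L1
    # kink at 0; entries at or near 0 belong to the prox operator, which
    # owns the sparsity decision
    cur = pen_obj(theta)
    for _ in range(2):
        improved = False
        for i in range(n):
            for j in range(n):
                if i != j and abs(theta[i, j]) <= 0.5:
                    continue

                def f1(v, i=i, j=j):
                    th = theta.copy()
                    th[i, j] = v
                    return -pen_obj(th)

                res = optimize.minimize_scalar(f1, bounds=(-12.0, 12.0), method="bounded")
                if res.success and -res.fun > cur + 1e-10:
                    theta = theta.copy()
                    theta[i, j] = float(res.x)
                    cur = -res.fun
                    improved = True
        if not improved:
            break

    if lam > 0:
        # an off-diagonal sits at an exact L1 optimum of 0 whenever zeroing
        # it does not lower the penalized objective — snap residual
        # near-zero iterates (slow ISTA tails) onto it
        obj_cur = pen_obj(theta)
        for i in range(n):
            for j in range(n):
                if i == j or theta[i, j] == 0.0:
                    continue
                cand = theta.copy()
                cand[i, j] = 0.0
                obj_cand = -g(cand) - lam * _offdiag_penalty(cand, mu)
                if obj_cand >= obj_cur - 1e-9 * max(1.0, abs(obj_cur)):
                    theta, obj_cur = cand, obj_cand
    return theta


def structure_of(theta: np.ndarray, zero_tol: float = 1e-6) -> np.ndarray:
    """Sign/zero pattern of the off-diagonal interactions.

    Entries with |θ_ij| ≤ zero_tol map to 0, others to ±1; the diagonal
    (basal/self-activation aggregate) is not part of the structure and is
    reported as 0.
    """
    theta = np.asarray(theta, dtype=float)
    s = np.where(np.abs(theta) <= zero_tol, 0, np.sign(theta)).astype(int)
    np.fill_diagonal(s, 0)
    return s


def fit_hard_em(
    data: SnapshotData,
    model: NetworkModel,
    config: InferenceConfig = InferenceConfig(),
) -> InferenceResult:
    """Penalized hard-EM estimation of the interaction matrix θ.

    Alternates the hard E-step (latent protein modes) and the proximal
    M-step from ``theta_init`` (default: the null matrix) until the relative
    change of the penalized objective drops below ``config.tol`` or
    ``config.max_iter`` sweeps.  The objective trace is nondecreasing by
    construction of the two half-steps.
    """
    if data.n_genes != model.n:
        raise ValueError("data gene count does not match the model")
    theta = (
        np.zeros((model.n, model.n))
        if config.theta_init is None
        else np.array(config.theta_init, dtype=float)
    )
    lik = _Likelihood(model, data.X, data.mask, config.eps)
    trace: list[float] = []
    P = None
    converged = False
    sweeps = 0
    for sweep in range(config.max_iter):
        sweeps = sweep + 1
        P = e_step_hard(theta, data, model, config, warm_start=P, full_starts=sweep < 2)
        theta = m_step(P, data, model, config, theta_init=theta)
        # penalized objective in the E-step's coordinates (incl. logit Jacobian)
        obj = lik.total_logit(theta, P) - config.lambda_penalty * _offdiag_penalty(theta, config.pair_penalty)
        trace.append(obj)
        if sweep > 0:
            delta = trace[-1] - trace[-2]
            if delta < -1e-6 * max(1.0, abs(trace[-2])):
                raise AssertionError(
                    f"penalized objective decreased across sweep {sweep}: "
                    f"{trace[-2]:.6f} -> {trace[-1]:.6f}"
                )
            if abs(delta) < config.tol * max(1.0, abs(trace[-2])):
                converged = True
                break
    return InferenceResult(
        theta_hat=theta,
        P_hat=P,
        objective_trace=np.array(trace),
        structure=structure_of(theta),
        converged=converged,
        n_sweeps=sweeps,
    )
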