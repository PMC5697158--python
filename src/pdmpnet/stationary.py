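"""Explicit stationary and approximate distributions of the network model.

The statistical backbone of the package:

* the quasi-steady-state conditional law of mRNA given proteins — each gene
  an independent Beta(k_on,i(y)/d0,i, k_off,i/d0,i);
* the Hartree (self-consistent proteomic field) approximation of the
  stationary protein density — a product over genes of Beta densities whose
  shapes depend on the ambient protein field (no self-interaction), or of
  Beta *mixtures* over promoter frequency modes (auto-activation);
* the bursty Gamma limit of the Beta law, used when fitting raw molecule
  counts where only the scale ratio k_off/s_0 is identifiable.

All densities are evaluated in log space; observed values are clipped away
from {0, 1} where Beta densities can diverge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import special, stats

from .network import NetworkModel, kon_all, log_phi_all

__all__ = [
    "CLIP_EPS",
    "HartreeApprox",
    "hartree_density_no_self",
    "hartree_density_auto",
    "log_hartree_no_self",
    "log_hartree_auto",
    "conditional_mrna_density",
    "log_conditional_mrna",
    "gamma_limit_density",
    "marginal_mrna_density_auto",
    "power_transform_density",
]

#: default clipping distance from the {0, 1} boundary for observed values
CLIP_EPS = 1e-9


def clip_unit(x: np.ndarray, eps: float = CLIP_EPS) -> np.ndarray:
    return np.clip(np.asarray(x, dtype=float), eps, 1.0 - eps)


def _log_beta_pdf(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log Beta(a, b) density, broadcasting over all arguments."""
    return (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) - special.betaln(a, b)


def log_hartree_no_self(Y: np.ndarray, model: NetworkModel, eps: float = CLIP_EPS) -> np.ndarray:
    """Log of the product-of-Betas Hartree density (no self-interaction).

    u(y) = Π_i Beta(y_i; k_on,i(y)/d1,i, k_off,i/d1,i).  Exact when the
    promoter rates are constants; a heuristic (non-normalized) approximation
    otherwise.  Vectorized: Y of shape (..., n) → result of shape (...).
    """
    Y = clip_unit(Y, eps)
    a = kon_all(Y, model) / model.d1
    b = model.koff / model.d1
    return np.sum(_log_beta_pdf(Y, a, b), axis=-1)


def hartree_density_no_self(y: np.ndarray, model: NetworkModel, eps: float = CLIP_EPS) -> float:
    """Hartree approximate stationary protein density without self-interaction."""
    return float(np.exp(log_hartree_no_self(np.asarray(y, float), model, eps)))


@dataclass(frozen=True)
class _GeneMixture:
    """Precomputed Beta-mixture constants of one auto-activated gene."""

    c: int
    a: np.ndarray  # shapes a_r, r = 0..c
    b: float
    log_binom: np.ndarray
    log_beta_fn: np.ndarray  # log B(a_r, b)
    log_s_pow: float  # m_ii * log(s_ii)


@dataclass(frozen=True)
class HartreeApprox:
    """Per-gene representation of the Hartree stationary approximation.

    Genes with auto-activation (m_ii > 0) get a (c_i+1)-component Beta
    mixture whose shapes a_{i,r} interpolate the promoter frequency modes
    k_0,i/d1,i … k_1,i/d1,i, with field-dependent weights p_{i,r}(y); genes
    without feedback keep the single Beta factor with shape k_on,i(y)/d1,i.
    """

    model: NetworkModel
    mixtures: tuple[Optional[_GeneMixture], ...]

    @classmethod
    def from_model(cls, model: NetworkModel) -> "HartreeApprox":
        if model.interaction_form != "chromatin_hill":
            # constant/linear forms have no mixture structure; every gene is single-Beta
            return cls(model=model, mixtures=(None,) * model.n)
        mixtures = []
        params = model.interactions
        for i, kin in enumerate(model.kinetics):
            m_self = params.hill_m[i, i]
            if m_self == 0.0:
                mixtures.append(None)
                continue
            c_exact = (kin.k1 - kin.k0) / (kin.d1 * m_self)
            c = max(1, int(np.ceil(c_exact - 1e-12)))
            r = np.arange(c + 1)
            a = ((c - r) * kin.k0 + r * kin.k1) / (kin.d1 * c)
            b = kin.koff / kin.d1
            mixtures.append(
                _GeneMixture(
                    c=c,
                    a=a,
                    b=b,
                    log_binom=special.gammaln(c + 1)
                    - special.gammaln(r + 1)
                    - special.gammaln(c - r + 1),
                    log_beta_fn=special.betaln(a, b),
                    log_s_pow=m_self * np.log(params.hill_s[i, i]),
                )
            )
        return cls(model=model, mixtures=tuple(mixtures))

    def log_weights(self, gene_i: int, Y: np.ndarray) -> np.ndarray:
        """log p_{i,r}(y) for r = 0..c_i; Y of shape (..., n) → (..., c_i+1).

        p_{i,r}(y) ∝ C(c_i, r) B(a_{i,r}, b_i) (Φ_i(y)/s_ii^{m_ii})^r,
        normalized over r (a softmax, computed in log space).
        """
        mix = self.mixtures[gene_i]
        if mix is None:
            raise ValueError(f"gene {gene_i} has no auto-activation mixture (m_ii = 0)")
        log_phi = log_phi_all(np.asarray(Y, float), self.model.interactions)[..., gene_i]
        t = log_phi - mix.log_s_pow
        scores = mix.log_binom + mix.log_beta_fn + np.multiply.outer(t, np.arange(mix.c + 1))
        return scores - special.logsumexp(scores, axis=-1, keepdims=True)

    def log_density(self, Y: np.ndarray, eps: float = CLIP_EPS) -> np.ndarray:
        """Log Hartree density, mixture form where genes self-activate."""
        Y = clip_unit(Y, eps)
        model = self.model
        log_phi = log_phi_all(Y, model.interactions)
        total = np.zeros(Y.shape[:-1])
        kon_cache = None
        for i, mix in enumerate(self.mixtures):
            yi = Y[..., i]
            if mix is None:
                if kon_cache is None:
                    kon_cache = kon_all(Y, model)
                a = kon_cache[..., i] / model.d1[i]
                b = model.koff[i] / model.d1[i]
                total = total + _log_beta_pdf(yi, a, b)
                continue
            t = log_phi[..., i] - mix.log_s_pow
            r = np.arange(mix.c + 1)
            scores = mix.log_binom + mix.log_beta_fn + np.multiply.outer(t, r)
            log_norm = special.logsumexp(scores, axis=-1)
            # p_r * Beta_r(y_i): the B(a_r, b) factors cancel against the weights
            comp = (
                mix.log_binom
                + np.multiply.outer(t, r)
                + np.multiply.outer(np.log(yi), mix.a - 1.0)
            )
            total = total + (
                special.logsumexp(comp, axis=-1)
                + (mix.b - 1.0) * np.log1p(-yi)
                - log_norm
            )
        return total


def log_hartree_auto(Y: np.ndarray, model: NetworkModel, eps: float = CLIP_EPS) -> np.ndarray:
    """Log Hartree density using the Beta-mixture form for self-activating genes."""
    return HartreeApprox.from_model(model).log_density(Y, eps)


def hartree_density_auto(y: np.ndarray, model: NetworkModel, eps: float = CLIP_EPS) -> float:
    """Hartree approximate protein density with auto-activation mixtures."""
    return float(np.exp(log_hartree_auto(np.asarray(y, float), model, eps)))


def log_conditional_mrna(
    X: np.ndarray,
    Y: np.ndarray,
    model: NetworkModel,
    mask: Optional[np.ndarray] = None,
    eps: float = CLIP_EPS,
) -> np.ndarray:
    """Log quasi-steady-state mRNA density given proteins.

    v(x, y) = Π_i Beta(x_i; k_on,i(y)/d0,i, k_off,i/d0,i); masked genes
    contribute a factor 1.  X, Y of shape (..., n) → result of shape (...).
    """
    X = clip_unit(X, eps)
    Y = clip_unit(Y, eps)
    a = kon_all(Y, model) / model.d0
    b = model.koff / model.d0
    terms = _log_beta_pdf(X, a, b)
    if mask is not None:
        terms = np.where(np.asarray(mask, bool), terms, 0.0)
    return np.sum(terms, axis=-1)


def conditional_mrna_density(
    x: np.ndarray,
    y: np.ndarray,
    model: NetworkModel,
    mask: Optional[np.ndarray] = None,
    eps: float = CLIP_EPS,
) -> float:
    return float(np.exp(log_conditional_mrna(np.asarray(x, float), np.asarray(y, float), model, mask, eps)))


def gamma_limit_density(x: np.ndarray, a: float, scale_b: float) -> np.ndarray:
    """Gamma(a, rate=scale_b) density: the bursty limit of Beta(a, b).

    For b ≫ 1 and b ≫ a, Beta(a, b) on [0, 1] concentrates near 0 and
    x^{a-1}(1-x)^{b-1} ≈ x^{a-1} e^{-bx}, i.e. a Gamma(a, rate=b) law.  On
    the molecule-count scale only the ratio k_off/s_0 enters the rate.
    """
    if a <= 0 or scale_b <= 0:
        raise ValueError("shape and rate must be positive")
    return stats.gamma.pdf(np.asarray(x, float), a, scale=1.0 / scale_b)


def _single_gene_mixture(model: NetworkModel) -> tuple[np.ndarray, _GeneMixture]:
    if model.n != 1:
        raise ValueError("marginal_mrna_density_auto requires a single-gene model")
    approx = HartreeApprox.from_model(model)
    mix = approx.mixtures[0]
    if mix is None:
        raise ValueError("single-gene marginal with auto-activation requires m_11 > 0")
    # Φ is the constant exp(θ_11) for n = 1, so the weights are constants
    log_w = approx.log_weights(0, np.zeros(1))
    return np.exp(log_w), mix


def marginal_mrna_density_auto(
    x: np.ndarray,
    model: NetworkModel,
    n_nodes: int = 64,
    physical_scale: bool = False,
    rtol: float = 1e-6,
) -> np.ndarray:
    """Stationary mRNA marginal of a single auto-activated gene.

    Integrates the conditional mRNA law against the Hartree protein mixture,
    m(x) = Σ_r p_r ∫ Beta(y; a_r, b) v(x | y) dy, with each component
    integral evaluated by Gauss–Jacobi quadrature matched to the Beta weight
    (so endpoint singularities are handled exactly).  The result is checked
    against a doubled node count; disagreement beyond ``rtol`` raises.

    With ``physical_scale`` the conditional law is the bursty Gamma limit on
    the molecule-count scale (rate k_off/s_0) instead of the Beta on [0, 1].
    """
    x = np.asarray(x, dtype=float)
    weights, mix = _single_gene_mixture(model)
    kin = model.kinetics[0]

    def eval_nodes(n: int) -> np.ndarray:
        out = np.zeros(x.shape)
        for w_r, a_r in zip(weights, mix.a):
            # Gauss–Jacobi on [-1,1] with weight (1-t)^alpha (1+t)^beta;
            # mapped to y in (0,1) it integrates f(y) y^{a_r-1}(1-y)^{b-1} dy
            nodes, wq = special.roots_jacobi(n, mix.b - 1.0, a_r - 1.0)
            y = (nodes + 1.0) / 2.0
            norm = 2.0 ** (a_r + mix.b - 1.0) * special.beta(a_r, mix.b)
            kon_y = kon_all(y[:, None], model)[:, 0]
            if physical_scale:
                dens = stats.gamma.pdf(
                    x[..., None], kon_y / kin.d0, scale=kin.s0 / kin.koff
                )
            else:
                # guard only against exactly 0/1: the bursty low mode carries
                # real mass at arbitrarily small x and must not be clipped
                xs = np.clip(x, 1e-300, 1.0 - 1e-16)
                dens = np.exp(
                    _log_beta_pdf(xs[..., None], kon_y / kin.d0, kin.koff / kin.d0)
                )
            out = out + w_r * np.sum(dens * (wq / norm), axis=-1)
        return out

    coarse = eval_nodes(n_nodes)
    fine = eval_nodes(2 * n_nodes)
    scale = np.maximum(np.abs(fine), 1e-8)
    err = np.max(np.abs(fine - coarse) / scale)
    if err > max(rtol, 1e-10) * 100:
        raise RuntimeError(
            f"marginal quadrature did not converge: relative error {err:.2e} "
            f"between {n_nodes} and {2 * n_nodes} nodes"
        )
    return fine


def marginal_mrna_cdf_auto(
    x: np.ndarray,
    model: NetworkModel,
    n_nodes: int = 64,
    physical_scale: bool = False,
) -> np.ndarray:
    """CDF of the single-gene auto-activation mRNA marginal.

    Same mixture/quadrature construction as
    :func:`marginal_mrna_density_auto`; used for left-censored likelihoods
    (measurements below a detection floor).
    """
    x = np.asarray(x, dtype=float)
    weights, mix = _single_gene_mixture(model)
    kin = model.kinetics[0]
    out = np.zeros(x.shape)
    for w_r, a_r in zip(weights, mix.a):
        nodes, wq = special.roots_jacobi(n_nodes, mix.b - 1.0, a_r - 1.0)
        y = (nodes + 1.0) / 2.0
        norm = 2.0 ** (a_r + mix.b - 1.0) * special.beta(a_r, mix.b)
        kon_y = kon_all(y[:, None], model)[:, 0]
        if physical_scale:
            cdf = stats.gamma.cdf(x[..., None], kon_y / kin.d0, scale=kin.s0 / kin.koff)
        else:
            cdf = special.betainc(
                kon_y / kin.d0, kin.koff / kin.d0, np.clip(x, 0.0, 1.0)[..., None]
            )
        out = out + w_r * np.sum(cdf * (wq / norm), axis=-1)
    return np.clip(out, 0.0, 1.0)


def power_transform_density(f, alpha: float):
    """Push a density on x ≥ 0 through the diagnostic map z = x^alpha.

    Returns g with g(z) = f(z^{1/alpha}) (1/alpha) z^{1/alpha - 1}; used to
    reveal low-abundance modes (alpha = 1/3 compresses large values).
    alpha = 1 is the identity.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")

    def g(z):
        z = np.asarray(z, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            x = np.power(z, 1.0 / alpha)
            out = f(x) * (1.0 / alpha) * np.power(z, 1.0 / alpha - 1.0)
        return np.where(z > 0, out, 0.0)

    return g
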