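"""Parameterization of the PDMP gene-network model.

A network of n genes is described by per-gene promoter/transcription/
translation kinetics plus an interaction structure.  Each promoter switches
between an inactive and an active state; the activation rate ``k_on,i``
depends on the protein levels of the regulators of gene i, which is how the
directed network enters the dynamics.  All mRNA and protein variables are
kept on the normalized (dimensionless) scale, where both lie in [0, 1] and
the synthesis rates s_0, s_1 act purely as scale factors back to molecule
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "GeneKinetics",
    "InteractionParams",
    "NetworkModel",
    "SystemState",
    "phi",
    "kon",
    "koff",
    "normalize",
    "denormalize",
    "deterministic_rhs",
    "find_fixed_points",
]

DEFAULT_HILL_COEF = 2.0
DEFAULT_HILL_THRESHOLD = 0.1

InteractionForm = Literal["chromatin_hill", "linear_mass_action", "constant"]


@dataclass(frozen=True)
class GeneKinetics:
    """Kinetic rates of a single gene (all in inverse time units).

    k0/k1 are the low and high promoter-activation rates between which the
    effective burst frequency is modulated; koff is the (protein-independent)
    inactivation rate; d0/d1 are mRNA/protein degradation rates; s0/s1 are
    transcription and translation rates, used only for (de)normalization.
    """

    k0: float
    k1: float
    koff: float
    d0: float
    d1: float
    s0: float = 1.0
    s1: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k0", "k1", "koff", "d0", "d1", "s0", "s1"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"GeneKinetics.{name} must be strictly positive, got {v!r}")
        if self.k1 < self.k0:
            raise ValueError(f"k1 ({self.k1}) must be >= k0 ({self.k0})")


@dataclass(frozen=True)
class InteractionParams:
    """Interaction matrix θ plus Hill-type shape parameters.

    theta[i, j] (j != i) is the signed strength with which protein j
    regulates promoter i; theta[i, i] aggregates the basal input and the
    self-activation strength of gene i.  hill_m[i, j] and hill_s[i, j] are
    the Hill coefficient and half-saturation threshold (on the normalized
    protein scale) of the corresponding regulatory term.
    """

    theta: np.ndarray
    hill_m: np.ndarray
    hill_s: np.ndarray

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        m = np.asarray(self.hill_m, dtype=float)
        s = np.asarray(self.hill_s, dtype=float)
        if theta.ndim != 2 or theta.shape[0] != theta.shape[1]:
            raise ValueError("theta must be a square matrix")
        if m.shape != theta.shape or s.shape != theta.shape:
            raise ValueError("hill_m and hill_s must have the same shape as theta")
        if not np.all(np.isfinite(theta)):
            raise ValueError("theta must be finite")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValueError("hill_m entries must be finite and >= 0")
        if np.any(s <= 0) or not np.all(np.isfinite(s)):
            raise ValueError("hill_s entries must be finite and > 0")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "hill_m", m)
        object.__setattr__(self, "hill_s", s)

    @classmethod
    def from_theta(cls, theta: np.ndarray, hill_m=None, hill_s=None) -> "InteractionParams":
        theta = np.asarray(theta, dtype=float)
        n = theta.shape[0]
        if hill_m is None:
            hill_m = np.full((n, n), DEFAULT_HILL_COEF)
        if hill_s is None:
            hill_s = np.full((n, n), DEFAULT_HILL_THRESHOLD)
        return cls(theta=theta, hill_m=np.asarray(hill_m, float), hill_s=np.asarray(hill_s, float))


@dataclass(frozen=True)
class NetworkModel:
    """Complete parameterization of an n-gene PDMP network."""

    kinetics: tuple[GeneKinetics, ...]
    interactions: InteractionParams
    interaction_form: InteractionForm = "chromatin_hill"
    gene_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        kin = tuple(self.kinetics)
        object.__setattr__(self, "kinetics", kin)
        n = len(kin)
        if n < 1:
            raise ValueError("a network needs at least one gene")
        if self.interactions.theta.shape != (n, n):
            raise ValueError(
                f"theta shape {self.interactions.theta.shape} does not match gene count {n}"
            )
        if self.interaction_form not in ("chromatin_hill", "linear_mass_action", "constant"):
            raise ValueError(f"unknown interaction_form {self.interaction_form!r}")
        names = tuple(self.gene_names) or tuple(f"gene{i + 1}" for i in range(n))
        if len(names) != n:
            raise ValueError("gene_names length must equal gene count")
        object.__setattr__(self, "gene_names", names)
        if self.interaction_form == "linear_mass_action":
            _validate_linear_positivity(self)

    @property
    def n(self) -> int:
        return len(self.kinetics)

    # per-gene rate vectors, cached as plain arrays for vectorized code
    def _rates(self, name: str) -> np.ndarray:
        return np.array([getattr(k, name) for k in self.kinetics], dtype=float)

    @property
    def k0(self) -> np.ndarray:
        return self._rates("k0")

    @property
    def k1(self) -> np.ndarray:
        return self._rates("k1")

    @property
    def koff(self) -> np.ndarray:
        return self._rates("koff")

    @property
    def d0(self) -> np.ndarray:
        return self._rates("d0")

    @property
    def d1(self) -> np.ndarray:
        return self._rates("d1")

    @property
    def s0(self) -> np.ndarray:
        return self._rates("s0")

    @property
    def s1(self) -> np.ndarray:
        return self._rates("s1")

    def max_kon(self) -> np.ndarray:
        """Upper bound K_on,i of the activation-rate function of each gene."""
        if self.interaction_form == "chromatin_hill":
            return self.k1
        if self.interaction_form == "constant":
            return self.k0
        # linear form: positive coefficients maximized at y = 1
        theta = self.interactions.theta
        return np.diag(theta) + np.clip(theta - np.diag(np.diag(theta)), 0.0, None).sum(axis=1)


@dataclass
class SystemState:
    """Promoter/mRNA/protein state of one cell at time t (normalized scale)."""

    t: float
    E: np.ndarray
    M: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=int)
        self.M = np.asarray(self.M, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if not np.all((self.E == 0) | (self.E == 1)):
            raise ValueError("promoter states must be 0 or 1")
        if np.any(self.M < 0) or np.any(self.M > 1) or np.any(self.P < 0) or np.any(self.P > 1):
            raise ValueError("normalized M and P must lie in [0, 1]")


def _hill_term(y: np.ndarray, s: np.ndarray, m: np.ndarray) -> np.ndarray:
    """(y/s)^m with the convention 0^0 = 1 (no-feedback reduction).

    numpy's power already maps 0.0**0.0 to 1, which is exactly the
    convention needed for m = 0 entries.
    """
    return np.power(y / s, m)


def _check_protein_vector(y: np.ndarray, n: int) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != n:
        raise ValueError(f"protein vector has length {y.shape[-1]}, expected {n}")
    if not np.all(np.isfinite(y)):
        raise ValueError("protein levels must be finite")
    if np.any(y < 0):
        raise ValueError("protein levels must be nonnegative")
    return y


def log_phi_all(Y: np.ndarray, params: InteractionParams) -> np.ndarray:
    """log Φ_i for every gene, vectorized over cells.

    Y has shape (..., n); the result has the same shape.  Computed in log
    space so that large |θ| never overflows.
    """
    Y = np.asarray(Y, dtype=float)
    theta, m, s = params.theta, params.hill_m, params.hill_s
    n = theta.shape[0]
    # h[..., i, j] = (y_j / s_ij)^{m_ij}
    h = _hill_term(Y[..., None, :], s, m)
    # log[(1 + e^{θ_ij} h) / (1 + h)] computed stably via logaddexp
    log_num = np.logaddexp(0.0, theta + np.log(np.where(h > 0, h, 1.0)))
    log_num = np.where(h > 0, log_num, 0.0)
    log_den = np.log1p(h)
    ratio = log_num - log_den
    off = ~np.eye(n, dtype=bool)
    return np.diagonal(theta).copy() + np.sum(ratio, axis=-1, where=off)


def phi(gene_i: int, y: Sequence[float], params: InteractionParams) -> float:
    """External regulatory input Φ_i(y) of gene i.

    Product over regulators j ≠ i of Hill-type factors, increasing in y_j
    when θ_ij > 0 and decreasing when θ_ij < 0, times the basal factor
    exp(θ_ii).  The neutral value (θ ≡ 0) is 1.
    """
    n = params.theta.shape[0]
    if not 0 <= gene_i < n:
        raise IndexError(f"gene index {gene_i} out of range for n={n}")
    y = _check_protein_vector(np.asarray(y, float), n)
    return float(np.exp(log_phi_all(y, params)[gene_i]))


def kon_all(Y: np.ndarray, model: NetworkModel) -> np.ndarray:
    """Promoter activation rates k_on,i for every gene, vectorized over cells."""
    Y = np.asarray(Y, dtype=float)
    if model.interaction_form == "constant":
        return np.broadcast_to(model.k0, Y.shape).copy()
    if model.interaction_form == "linear_mass_action":
        theta = model.interactions.theta
        out = np.diagonal(theta) + Y @ (theta - np.diag(np.diagonal(theta))).T
        if np.any(out <= 0):
            raise ValueError(
                "linear interaction form produced k_on <= 0; the model is not well-posed"
            )
        return out
    params = model.interactions
    log_phi = log_phi_all(Y, params)
    m_self = np.diagonal(params.hill_m)
    s_self = np.diagonal(params.hill_s)
    h_self = _hill_term(Y, s_self, m_self)
    # k_on = (k0 + k1 Φ h) / (1 + Φ h), stable for huge Φ·h
    with np.errstate(over="ignore"):
        w = np.exp(log_phi) * h_self
    k0, k1 = model.k0, model.k1
    out = np.where(np.isinf(w), k1, (k0 + k1 * w) / (1.0 + w))
    return out


def kon(gene_i: int, y: Sequence[float], model: NetworkModel) -> float:
    """Activation rate k_on,i(y) of gene i.

    For the chromatin form this is a Hill function of y_i with ceiling k1
    and floor k0, whose midpoint is shifted by the regulatory input Φ_i(y);
    it always lies in [k0, k1].
    """
    y = _check_protein_vector(np.asarray(y, float), model.n)
    return float(kon_all(y, model)[gene_i])


def koff(gene_i: int, model: NetworkModel) -> float:
    """Promoter inactivation rate of gene i (constant by modelling choice)."""
    return float(model.kinetics[gene_i].koff)


def _validate_linear_positivity(model: NetworkModel) -> None:
    """Reject linear-form parameterizations allowing k_on <= 0 on [0,1]^n.

    The minimum of an affine function over the unit box is attained at a
    vertex with y_j = 1 for negative coefficients and 0 otherwise.
    """
    theta = model.interactions.theta
    basal = np.diagonal(theta)
    off = theta - np.diag(basal)
    worst = basal + np.clip(off, None, 0.0).sum(axis=1)
    if np.any(worst <= 0):
        bad = int(np.argmax(worst <= 0))
        raise ValueError(
            f"linear interaction form allows k_on <= 0 for gene {bad} (min {worst[bad]:.3g})"
        )


def normalize(physical_M: np.ndarray, physical_P: np.ndarray, model: NetworkModel):
    """Map molecule counts to the dimensionless [0, 1] scale.

    M̄_i = (d0_i/s0_i) M_i and P̄_i = (d0_i d1_i)/(s0_i s1_i) P_i.
    """
    M = np.asarray(physical_M, dtype=float)
    P = np.asarray(physical_P, dtype=float)
    if np.any(M < 0) or np.any(P < 0):
        raise ValueError("physical molecule counts must be nonnegative")
    mscale = model.d0 / model.s0
    pscale = (model.d0 * model.d1) / (model.s0 * model.s1)
    return M * mscale, P * pscale


def denormalize(M: np.ndarray, P: np.ndarray, model: NetworkModel):
    """Inverse of :func:`normalize`: back to molecule counts."""
    M = np.asarray(M, dtype=float)
    P = np.asarray(P, dtype=float)
    return M * (model.s0 / model.d0), P * (model.s0 / model.d0) * (model.s1 / model.d1)


def deterministic_rhs(y: np.ndarray, model: NetworkModel) -> np.ndarray:
    """Right-hand side of the fast-promoter deterministic limit.

    dy_i/dt = d1_i (k_on,i(y)/(k_on,i(y)+k_off,i) − y_i); its fixed points
    are the self-consistent promoter occupancies.
    """
    y = np.asarray(y, dtype=float)
    k = kon_all(y, model)
    return model.d1 * (k / (k + model.koff) - y)


def find_fixed_points(
    model: NetworkModel, n_starts: int = 64, seed: int = 0, tol: float = 1e-9
) -> list[dict]:
    """Locate fixed points of the deterministic limit by multistart root finding.

    Returns a list of dicts with keys ``y`` (the fixed point) and ``stable``
    (all Jacobian eigenvalues have negative real part, by central finite
    differences).
    """
    rng = np.random.default_rng(seed)
    starts = rng.uniform(0.0, 1.0, size=(n_starts, model.n))
    # deterministic starts at the promoter-occupancy extremes: basins around
    # the low burst-frequency mode can be tiny and missed by uniform draws
    lows = model.k0 / (model.k0 + model.koff)
    highs = model.k1 / (model.k1 + model.koff)
    if model.n <= 6:
        corners = [
            np.where([(b >> i) & 1 for i in range(model.n)], highs, lows)
            for b in range(2**model.n)
        ]
        starts = np.vstack([starts, corners])
    found: list[np.ndarray] = []
    for y0 in starts:
        sol = optimize.root(lambda y: deterministic_rhs(np.clip(y, 0, 1), model), y0, tol=tol)
        if not sol.success:
            continue
        y = np.clip(sol.x, 0.0, 1.0)
        if np.max(np.abs(deterministic_rhs(y, model))) > 1e-7:
            continue
        if not any(np.allclose(y, f, atol=1e-5) for f in found):
            found.append(y)
    out = []
    h = 1e-6
    for y in found:
        J = np.empty((model.n, model.n))
        for j in range(model.n):
            e = np.zeros(model.n)
            e[j] = h
            J[:, j] = (
                deterministic_rhs(np.clip(y + e, 0, 1), model)
                - deterministic_rhs(np.clip(y - e, 0, 1), model)
            ) / (2 * h)
        stable = bool(np.all(np.linalg.eigvals(J).real < 0))
        out.append({"y": y, "stable": stable})
    return out
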