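"""Sample-path simulation of the PDMP network model.

Two engines are provided:

* a hybrid Euler–Bernoulli scheme for the full network: between promoter
  events the normalized mRNA/protein ODEs are advanced by an explicit Euler
  step, while each promoter is resampled from the exact two-state transition
  probability over the step (valid when the step is much shorter than every
  kinetic timescale);
* an exact Gillespie (SSA) simulator for the discrete single-gene two-state
  model, used as a molecule-level oracle for the hybrid scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data import SnapshotData
from .network import GeneKinetics, NetworkModel, SystemState, kon_all

__all__ = [
    "SimConfig",
    "Trajectory",
    "SSATrajectory",
    "promoter_update_prob",
    "default_dt",
    "simulate_pdmp",
    "simulate_ensemble",
    "simulate_ssa_single_gene",
    "snapshot",
]

#: safety factor applied to the 1/max-rate validity bound on the Euler step
DT_SAFETY = 0.1

#: default snapshot burn-in, in units of the slowest protein timescale
BURN_IN_PROTEIN_LIFETIMES = 10.0


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a hybrid simulation run.

    ``dt=None`` selects the default step ``safety``/max{K_on, K_off, d0, d1}.
    ``initial_state`` is a :class:`SystemState`, the string ``"zero"``
    (promoters off, no molecules) or ``"random"`` (uniform M, P and
    occupancy-balanced promoters — useful to populate every basin of a
    multistable network).
    """

    t_end: float
    dt: Optional[float] = None
    burn_in: float = 0.0
    seed: int = 0
    initial_state: object = "zero"
    safety: float = DT_SAFETY

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be nonnegative")


@dataclass
class Trajectory:
    """A discretized sample path of the network (normalized scale)."""

    times: np.ndarray
    E: np.ndarray  # (T, n) promoter states
    M: np.ndarray  # (T, n) normalized mRNA
    P: np.ndarray  # (T, n) normalized protein
    seed: int
    model: NetworkModel

    def state_at(self, idx: int) -> SystemState:
        return SystemState(t=self.times[idx], E=self.E[idx], M=self.M[idx], P=self.P[idx])

    def to_frame(self):
        """Long-format DataFrame (time, gene, E, M, P)."""
        import pandas as pd

        n = self.model.n
        T = len(self.times)
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, n),
                "gene": np.tile(self.model.gene_names, T),
                "E": self.E.ravel(),
                "M": self.M.ravel(),
                "P": self.P.ravel(),
            }
        )


@dataclass
class SSATrajectory:
    """Event-time trajectory of the discrete single-gene model (counts)."""

    times: np.ndarray
    G_active: np.ndarray
    M: np.ndarray
    P: np.ndarray
    seed: int

    def time_average(self, which: str = "M", t_start: float = 0.0) -> float:
        """Time-weighted average of a component over [t_start, end]."""
        x = getattr(self, which if which != "E" else "G_active").astype(float)
        t = self.times
        keep = t >= t_start
        t, x = t[keep], x[keep]
        if len(t) < 2:
            raise ValueError("not enough events after t_start")
        dt = np.diff(t)
        return float(np.sum(x[:-1] * dt) / np.sum(dt))


def promoter_update_prob(E: int, a: float, b: float, dt: float) -> float:
    """Probability that a two-state promoter is active after a lag dt.

    Exact solution of the master equation of the 0 ⇄ 1 chain with rates a
    (activation) and b (inactivation), started from state E:
    π = a/(a+b) + (E − a/(a+b))·exp(−(a+b)·dt).
    """
    if a < 0 or b < 0 or a + b <= 0:
        raise ValueError("rates must be nonnegative with a + b > 0")
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    stat = a / (a + b)
    return float(stat + (E - stat) * np.exp(-(a + b) * dt))


def default_dt(model: NetworkModel, safety: float = DT_SAFETY) -> float:
    """Euler step satisfying dt = safety / max{K_on, K_off, d0, d1}."""
    max_rate = max(
        float(np.max(model.max_kon())),
        float(np.max(model.koff)),
        float(np.max(model.d0)),
        float(np.max(model.d1)),
    )
    return safety / max_rate


def default_burn_in(model: NetworkModel) -> float:
    """Default snapshot burn-in: 10 lifetimes of the slowest protein."""
    return BURN_IN_PROTEIN_LIFETIMES / float(np.min(model.d1))


def _check_dt(model: NetworkModel, dt: float, safety: float) -> None:
    rates = {
        "K_on": float(np.max(model.max_kon())),
        "K_off": float(np.max(model.koff)),
        "d0": float(np.max(model.d0)),
        "d1": float(np.max(model.d1)),
    }
    name, worst = max(rates.items(), key=lambda kv: kv[1])
    if dt > safety / worst + 1e-12:
        raise ValueError(
            f"dt={dt:g} violates the validity bound {safety:g}/max-rate "
            f"(limiting rate {name}={worst:g}, bound {safety / worst:g})"
        )


def _cell_rng(seed: int, cell: int) -> np.random.Generator:
    """Independent, order-insensitive per-cell stream from a master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(cell,)))


def _initial_arrays(model: NetworkModel, initial_state, n_cells: int, rng: np.random.Generator):
    n = model.n
    if isinstance(initial_state, SystemState):
        E = np.tile(initial_state.E, (n_cells, 1)).astype(float)
        M = np.tile(initial_state.M, (n_cells, 1)).astype(float)
        P = np.tile(initial_state.P, (n_cells, 1)).astype(float)
    elif initial_state == "zero":
        E = np.zeros((n_cells, n))
        M = np.zeros((n_cells, n))
        P = np.zeros((n_cells, n))
    elif initial_state == "random":
        M = rng.uniform(0.0, 1.0, size=(n_cells, n))
        P = rng.uniform(0.0, 1.0, size=(n_cells, n))
        k = kon_all(P, model)
        E = (rng.uniform(size=(n_cells, n)) < k / (k + model.koff)).astype(float)
    elif initial_state == "modes":
        # occupancy-corner randomization: each gene starts in its low or
        # high burst-frequency mode with probability 1/2, so every basin of
        # a multistable network is populated (a uniform draw concentrates
        # far above the small dissociation thresholds and misses low modes)
        lows = model.k0 / (model.k0 + model.koff)
        highs = model.k1 / (model.k1 + model.koff)
        pick = rng.uniform(size=(n_cells, n)) < 0.5
        P = np.where(pick, highs, lows)
        M = P.copy()
        k = kon_all(P, model)
        E = (rng.uniform(size=(n_cells, n)) < k / (k + model.koff)).astype(float)
    else:
        raise ValueError(f"unknown initial_state {initial_state!r}")
    return E, M, P


def _run_steps(model, E, M, P, dt, n_steps, uniforms, record_at=None):
    """Advance the ensemble; uniforms has shape (n_steps, n_cells, n).

    The promoter is resampled from its exact two-state law with rates frozen
    at the current proteins; M and P take convex-combination Euler updates
    using the *previous* promoter and mRNA values.
    """
    d0dt = model.d0 * dt
    d1dt = model.d1 * dt
    b = model.koff
    recorded = {}
    for t in range(n_steps):
        a = kon_all(P, model)
        stat = a / (a + b)
        pi = stat + (E - stat) * np.exp(-(a + b) * dt)
        E_new = (uniforms[t] < pi).astype(float)
        M_new = (1.0 - d0dt) * M + d0dt * E
        P = (1.0 - d1dt) * P + d1dt * M
        E, M = E_new, M_new
        if record_at is not None and (t + 1) in record_at:
            recorded[t + 1] = (E.copy(), M.copy(), P.copy())
    return E, M, P, recorded


def simulate_pdmp(model: NetworkModel, config: SimConfig) -> Trajectory:
    """Simulate one sample path of the PDMP network with the hybrid scheme."""
    dt = config.dt if config.dt is not None else default_dt(model, config.safety)
    _check_dt(model, dt, config.safety)
    rng = _cell_rng(config.seed, 0)
    E, M, P = _initial_arrays(model, config.initial_state, 1, rng)
    n_steps = int(np.ceil(config.t_end / dt))
    times = np.arange(n_steps + 1) * dt
    Es = np.empty((n_steps + 1, model.n))
    Ms = np.empty((n_steps + 1, model.n))
    Ps = np.empty((n_steps + 1, model.n))
    Es[0], Ms[0], Ps[0] = E[0], M[0], P[0]
    chunk = 8192
    t = 0
    while t < n_steps:
        k = min(chunk, n_steps - t)
        U = rng.uniform(size=(k, 1, model.n))
        d0dt, d1dt, b = model.d0 * dt, model.d1 * dt, model.koff
        for s in range(k):
            a = kon_all(P, model)
            stat = a / (a + b)
            pi = stat + (E - stat) * np.exp(-(a + b) * dt)
            E_new = (U[s] < pi).astype(float)
            M_new = (1.0 - d0dt) * M + d0dt * E
            P = (1.0 - d1dt) * P + d1dt * M
            E, M = E_new, M_new
            Es[t + s + 1], Ms[t + s + 1], Ps[t + s + 1] = E[0], M[0], P[0]
        t += k
    keep = times >= config.burn_in
    return Trajectory(
        times=times[keep],
        E=Es[keep].astype(int),
        M=Ms[keep],
        P=Ps[keep],
        seed=config.seed,
        model=model,
    )


def simulate_ensemble(
    model: NetworkModel,
    n_cells: int,
    config: SimConfig,
    record_times: Optional[np.ndarray] = None,
):
    """Simulate ``n_cells`` independent cells in lock-step (vectorized).

    Each cell draws from its own counter-based RNG stream keyed by
    (master seed, cell index), so results are independent of batching and
    execution order.  Returns ``(times, E, M, P)`` with state arrays of
    shape (n_rec, n_cells, n) sampled at ``record_times`` (default: t_end).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    dt = config.dt if config.dt is not None else default_dt(model, config.safety)
    _check_dt(model, dt, config.safety)
    n = model.n
    n_steps = int(np.ceil(config.t_end / dt))
    if record_times is None:
        record_times = np.array([config.t_end])
    rec_steps = np.unique(np.clip(np.round(np.asarray(record_times) / dt).astype(int), 0, n_steps))
    rngs = [_cell_rng(config.seed, c + 1) for c in range(n_cells)]
    # per-cell initial draws from the cell's own stream, so a cell's whole
    # trajectory is independent of how many other cells are simulated
    inits = [_initial_arrays(model, config.initial_state, 1, r) for r in rngs]
    E = np.concatenate([i[0] for i in inits])
    M = np.concatenate([i[1] for i in inits])
    P = np.concatenate([i[2] for i in inits])
    out = {}
    if 0 in rec_steps:
        out[0] = (E.copy(), M.copy(), P.copy())
    record_at = set(int(s) for s in rec_steps if s > 0)
    chunk = 2048
    t = 0
    while t < n_steps:
        k = min(chunk, n_steps - t)
        # per-cell uniform blocks: (k, n_cells, n)
        U = np.empty((k, n_cells, n))
        for c, r in enumerate(rngs):
            U[:, c, :] = r.uniform(size=(k, n))
        rec = {s - t for s in record_at if t < s <= t + k}
        E, M, P, recorded = _run_steps(model, E, M, P, dt, k, U, record_at=rec)
        for s, v in recorded.items():
            out[t + s] = v
        t += k
    times = np.array(sorted(out)) * dt
    Es = np.stack([out[s][0] for s in sorted(out)])
    Ms = np.stack([out[s][1] for s in sorted(out)])
    Ps = np.stack([out[s][2] for s in sorted(out)])
    return times, Es, Ms, Ps


def snapshot(
    model: NetworkModel,
    n_cells: int,
    config: SimConfig,
    return_proteins: bool = False,
    stationarity_tol: float = 0.1,
):
    """Single-cell mRNA snapshot: independent cells sampled at t_end.

    Runs ``n_cells`` independent PDMP trajectories and records the final
    normalized mRNA levels.  As a stationarity diagnostic, per-gene means at
    t_end and t_end/2 are compared; a relative difference beyond
    ``stationarity_tol`` triggers a warning (the burn-in is then too short).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rec = np.array([config.t_end / 2, config.t_end])
    times, Es, Ms, Ps = simulate_ensemble(model, n_cells, config, record_times=rec)
    X = Ms[-1]
    if len(times) > 1 and n_cells >= 20:
        mean_half, mean_end = Ms[0].mean(axis=0), X.mean(axis=0)
        scale = np.maximum(np.maximum(mean_half, mean_end), 1e-3)
        drift = np.abs(mean_end - mean_half) / scale
        if np.any(drift > stationarity_tol):
            worst = int(np.argmax(drift))
            warnings.warn(
                f"snapshot may not be stationary: gene {model.gene_names[worst]} mean "
                f"drifts by {drift[worst]:.1%} between t_end/2 and t_end",
                stacklevel=2,
            )
    data = SnapshotData(X=X, gene_names=model.gene_names)
    if return_proteins:
        return data, Ps[-1]
    return data


def simulate_ssa_single_gene(
    kinetics: GeneKinetics,
    t_end: float,
    seed: int = 0,
    kon: Optional[float] = None,
    max_events: int = 50_000_000,
) -> SSATrajectory:
    """Exact Gillespie simulation of the discrete single-gene two-state model.

    Reactions (propensities): activation kon·[G], inactivation koff·[G*],
    transcription s0·[G*], translation s1·M, mRNA decay d0·M, protein decay
    d1·P.  [G]+[G*]=1 is conserved.  ``kon`` defaults to ``kinetics.k0``.
    Starts from the empty state (inactive promoter, no molecules).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    kon_rate = float(kinetics.k0 if kon is None else kon)
    koff, s0, s1, d0, d1 = kinetics.koff, kinetics.s0, kinetics.s1, kinetics.d0, kinetics.d1
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    t, g, m, p = 0.0, 0, 0, 0
    times, gs, ms, ps = [0.0], [0], [0], [0]
    # draw exponential/uniform variates in blocks to keep the loop lean
    block = 1 << 14
    exp_buf = rng.exponential(size=block)
    uni_buf = rng.uniform(size=block)
    ib = 0
    n_events = 0
    while t < t_end:
        a1 = kon_rate if g == 0 else 0.0
        a2 = koff if g == 1 else 0.0
        a3 = s0 if g == 1 else 0.0
        a4 = s1 * m
        a5 = d0 * m
        a6 = d1 * p
        total = a1 + a2 + a3 + a4 + a5 + a6
        if total <= 0.0:
            break
        if ib >= block:
            exp_buf = rng.exponential(size=block)
            uni_buf = rng.uniform(size=block)
            ib = 0
        t += exp_buf[ib] / total
        u = uni_buf[ib] * total
        ib += 1
        if t > t_end:
            break
        if u < a1:
            g = 1
        elif u < a1 + a2:
            g = 0
        elif u < a1 + a2 + a3:
            m += 1
        elif u < a1 + a2 + a3 + a4:
            p += 1
        elif u < a1 + a2 + a3 + a4 + a5:
            m -= 1
        else:
            p -= 1
        times.append(t)
        gs.append(g)
        ms.append(m)
        ps.append(p)
        n_events += 1
        if n_events >= max_events:
            raise RuntimeError(f"SSA exceeded {max_events} events before t_end")
    times.append(min(t, t_end))
    gs.append(g)
    ms.append(m)
    ps.append(p)
    return SSATrajectory(
        times=np.array(times),
        G_active=np.array(gs),
        M=np.array(ms),
        P=np.array(ps),
        seed=seed,
    )
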