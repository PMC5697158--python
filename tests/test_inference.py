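"""Hard-EM machinery: likelihood oracle, E/M steps, penalty behaviour."""

import numpy as np
import pytest
from scipy.special import betaln, expit, logit

from pdmpnet.data import SnapshotData
from pdmpnet.inference import (
    InferenceConfig,
    complete_log_likelihood,
    e_step_hard,
    fit_hard_em,
    m_step,
    penalized_objective,
    structure_of,
)
from pdmpnet.network import GeneKinetics, InteractionParams, NetworkModel
from pdmpnet.simulate import SimConfig, snapshot
from pdmpnet.stationary import HartreeApprox, clip_unit


def single_auto(theta11=2.0, k0=0.05, k1=2.0, koff=10.0, d0=0.5, d1=0.1, s_self=0.62):
    kin = GeneKinetics(k0=k0, k1=k1, koff=koff, d0=d0, d1=d1, s0=1e3, s1=10.0)
    return NetworkModel(
        kinetics=(kin,),
        interactions=InteractionParams(
            theta=np.array([[theta11]]), hill_m=np.array([[2.0]]), hill_s=np.array([[s_self]])
        ),
    )


def brute_force_loglik(x, y, model):
    """Naive per-factor evaluation of log u + log v, independent code path."""
    from pdmpnet.network import kon_all

    x = clip_unit(np.atleast_1d(x))
    y = clip_unit(np.atleast_1d(y))
    n = model.n
    approx = HartreeApprox.from_model(model)
    total = 0.0
    kon_y = kon_all(y, model)
    for i in range(n):
        mix = approx.mixtures[i]
        if mix is None:
            a = kon_y[i] / model.d1[i]
            b = model.koff[i] / model.d1[i]
            total += (a - 1) * np.log(y[i]) + (b - 1) * np.log(1 - y[i]) - betaln(a, b)
        else:
            w = np.exp(approx.log_weights(i, y))
            dens = sum(
                w_r
                * y[i] ** (a_r - 1)
                * (1 - y[i]) ** (mix.b - 1)
                / np.exp(betaln(a_r, mix.b))
                for w_r, a_r in zip(w, mix.a)
            )
            total += np.log(dens)
        at = kon_y[i] / model.d0[i]
        bt = model.koff[i] / model.d0[i]
        total += (at - 1) * np.log(x[i]) + (bt - 1) * np.log(1 - x[i]) - betaln(at, bt)
    return total


class TestCompleteLogLikelihood:
    def test_uniform_case_is_zero(self):
        kin = GeneKinetics(k0=0.1, k1=0.1, koff=0.1, d0=0.1, d1=0.1)  # all shapes 1
        model = NetworkModel(
            kinetics=(kin,),
            interactions=InteractionParams.from_theta(np.zeros((1, 1))),
            interaction_form="constant",
        )
        assert complete_log_likelihood([0.4], [0.6], model) == pytest.approx(0.0, abs=1e-10)

    def test_fully_masked_cell_reduces_to_protein_term(self, toggle_model):
        x = np.array([0.2, 0.3])
        y = np.array([0.1, 0.02])
        full = complete_log_likelihood(x, y, toggle_model, mask_row=np.array([False, False]))
        from pdmpnet.stationary import log_hartree_auto

        assert full == pytest.approx(float(log_hartree_auto(y, toggle_model)), rel=1e-10)

    def test_matches_brute_force_oracle(self, toggle_model, rng):
        for _ in range(10):
            x = rng.uniform(0.01, 0.5, 2)
            y = rng.uniform(0.005, 0.3, 2)
            got = complete_log_likelihood(x, y, toggle_model)
            want = brute_force_loglik(x, y, toggle_model)
            assert got == pytest.approx(want, rel=1e-8)


class TestPenalizedObjective:
    def test_zero_lambda_equals_raw_loglik(self, toggle_model, rng):
        X = rng.uniform(0.05, 0.3, (5, 2))
        P = rng.uniform(0.02, 0.2, (5, 2))
        data = SnapshotData(X=X)
        theta = toggle_model.interactions.theta
        cfg0 = InferenceConfig(lambda_penalty=0.0)
        cfg5 = InferenceConfig(lambda_penalty=5.0)
        raw = penalized_objective(theta, P, data, toggle_model, cfg0)
        pen = penalized_objective(theta, P, data, toggle_model, cfg5)
        # off-diagonals are ±8: L1 = 16, reciprocal-pair min term = 8
        assert pen == pytest.approx(raw - 5.0 * (16.0 + 8.0))

    def test_diagonal_not_penalized(self, toggle_model, rng):
        X = rng.uniform(0.05, 0.3, (4, 2))
        P = rng.uniform(0.02, 0.2, (4, 2))
        data = SnapshotData(X=X)
        theta = np.diag([4.0, 4.0])
        for lam in (0.0, 100.0):
            cfg = InferenceConfig(lambda_penalty=lam)
            assert penalized_objective(theta, P, data, toggle_model, cfg) == pytest.approx(
                penalized_objective(theta, P, data, toggle_model, InferenceConfig()), rel=1e-12
            )


class TestEStep:
    def test_matches_dense_grid_search_single_gene(self):
        """1-D latent mode agrees with an exhaustive logit-grid argmax."""
        model = single_auto(2.0)
        X = np.array([[0.02], [0.1], [0.25]])
        data = SnapshotData(X=X)
        cfg = InferenceConfig()
        P = e_step_hard(model.interactions.theta, data, model, cfg)
        from pdmpnet.inference import _Likelihood

        lik = _Likelihood(model, X, data.mask, cfg.eps)
        zgrid = np.linspace(-14, 0, 4000)
        ygrid = expit(zgrid)
        for k in range(3):
            vals = [
                lik.per_cell_logit(model.interactions.theta, np.array([[y]]))[0]
                for y in ygrid
            ]
            best = ygrid[int(np.argmax(vals))]
            got = lik.per_cell_logit(model.interactions.theta, P[[k]])[0]
            assert got >= max(vals) - 5e-3  # grid-resolution slack

    def test_identical_cells_identical_latents(self, toggle_model):
        X = np.array([[0.2, 0.05], [0.2, 0.05], [0.01, 0.15]])
        data = SnapshotData(X=X)
        P = e_step_hard(toggle_model.interactions.theta, data, toggle_model, InferenceConfig())
        np.testing.assert_array_equal(P[0], P[1])
        assert not np.allclose(P[0], P[2])

    def test_deterministic(self, toggle_model, rng):
        X = rng.uniform(0.01, 0.3, (6, 2))
        data = SnapshotData(X=X)
        a = e_step_hard(toggle_model.interactions.theta, data, toggle_model, InferenceConfig())
        b = e_step_hard(toggle_model.interactions.theta, data, toggle_model, InferenceConfig())
        np.testing.assert_array_equal(a, b)


class TestMStep:
    def test_huge_lambda_zeroes_offdiagonals(self, toggle_model, rng):
        X = rng.uniform(0.01, 0.3, (20, 2))
        P = rng.uniform(0.005, 0.2, (20, 2))
        data = SnapshotData(X=X)
        cfg = InferenceConfig(lambda_penalty=1e5)
        theta = m_step(P, data, toggle_model, cfg, theta_init=np.zeros((2, 2)))
        off = theta[~np.eye(2, dtype=bool)]
        assert np.all(off == 0.0)

    def test_single_gene_matches_grid_search(self):
        """1-parameter M-step agrees with a dense θ_11 grid search."""
        model = single_auto(0.0)
        rng = np.random.default_rng(3)
        X = rng.beta(0.5, 5.0, (30, 1)).clip(1e-6, 1 - 1e-6)
        P = rng.beta(0.5, 20.0, (30, 1)).clip(1e-6, 1 - 1e-6)
        data = SnapshotData(X=X)
        cfg = InferenceConfig(lambda_penalty=0.0)
        theta = m_step(P, data, model, cfg, theta_init=np.zeros((1, 1)))
        from pdmpnet.inference import _Likelihood, _with_theta

        lik = _Likelihood(model, X, data.mask, cfg.eps)
        grid = np.linspace(-6, 8, 561)
        vals = [lik.total(np.array([[t]]), P) for t in grid]
        best = grid[int(np.argmax(vals))]
        got = lik.total(theta, P)
        assert got >= max(vals) - 1e-3
        assert theta[0, 0] == pytest.approx(best, abs=0.1)


class TestStructure:
    def test_zero_matrix(self):
        assert np.all(structure_of(np.zeros((3, 3))) == 0)

    def test_toggle_sign_extraction(self):
        theta = np.array([[4.0, -8.0], [-8.0, 4.0]])
        s = structure_of(theta)
        assert s[0, 1] == -1 and s[1, 0] == -1
        assert s[0, 0] == 0 and s[1, 1] == 0  # diagonal excluded from structure

    def test_subthreshold_entries_are_zero(self):
        theta = np.array([[0.0, 1e-9], [2e-7, 0.0]])
        assert np.all(structure_of(theta, zero_tol=1e-6) == 0)


class TestFitHardEM:
    def test_monotone_objective_and_convergence_flag(self, toggle_model):
        data = snapshot(
            toggle_model, 40, SimConfig(t_end=120.0, seed=3, initial_state="modes")
        )
        res = fit_hard_em(data, toggle_model, InferenceConfig(lambda_penalty=5.0, max_iter=40))
        diffs = np.diff(res.objective_trace)
        assert np.all(diffs >= -1e-6 * np.maximum(1.0, np.abs(res.objective_trace[:-1])))
        assert res.P_hat.shape == data.X.shape
        assert np.all((res.P_hat > 0) & (res.P_hat < 1))

    def test_rejects_mismatched_data(self, toggle_model):
        with pytest.raises(ValueError):
            fit_hard_em(SnapshotData(X=np.full((3, 3), 0.1)), toggle_model)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            SnapshotData(X=np.empty((0, 2)))

    def test_masked_gene_matches_deleted_gene(self):
        """Masking one gene everywhere ≈ fitting the remaining gene alone."""
        model2 = NetworkModel(
            kinetics=(single_auto(2.0).kinetics[0],) * 2,
            interactions=InteractionParams(
                theta=np.diag([2.0, 2.0]),
                hill_m=np.full((2, 2), 2.0),
                hill_s=np.full((2, 2), 0.62),
            ),
        )
        data2 = snapshot(model2, 30, SimConfig(t_end=120.0, seed=5, initial_state="modes"))
        masked = SnapshotData(
            X=data2.X,
            mask=np.column_stack([np.ones(30, bool), np.zeros(30, bool)]),
            gene_names=data2.gene_names,
        )
        cfg = InferenceConfig(lambda_penalty=5.0, max_iter=30)
        res_masked = fit_hard_em(masked, model2, cfg)
        model1 = single_auto(2.0)
        res_solo = fit_hard_em(
            SnapshotData(X=data2.X[:, :1]), model1, cfg
        )
        assert res_masked.theta_hat[0, 0] == pytest.approx(
            res_solo.theta_hat[0, 0], abs=0.3
        )
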