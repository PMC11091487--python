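import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

import oracles
from conftest import make_occ_data
from wolfscr.grid import build_adjacency, build_grid
from wolfscr.occupancy import (
    OccupancyModel,
    OccupancyParams,
    camera_event_probs,
    car_precision,
    psi_linpred,
    transect_event_probs,
)


class TestEventMatrices:
    def test_occupied_without_genetics_only_unknown(self):
        row = transect_event_probs(True, 0.0, 0.3, 0, 0.0)
        assert np.allclose(row, [0.7, 0.0, 0.0, 0.3])

    def test_unoccupied_with_genetics_yields_dog_code(self):
        row = transect_event_probs(False, 0.1, 0.0, 1, 0.0)
        assert np.allclose(row, [0.9, 0.0, 0.1, 0.0])

    def test_misidentification_split(self):
        row = transect_event_probs(True, 0.0, 0.5, 1, 0.048)
        assert np.allclose(row, [0.5, 0.476, 0.024, 0.0])

    def test_camera_rows(self):
        assert np.allclose(camera_event_probs(False, 0.9), [1.0, 0.0])
        assert np.allclose(camera_event_probs(True, 0.0), [1.0, 0.0])
        assert np.allclose(camera_event_probs(True, 0.25), [0.75, 0.25])

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            transect_event_probs(True, 0.0, 1.5, 1, 0.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        p1=st.floats(0, 1), p2=st.floats(0, 1), m=st.floats(0, 1),
        g=st.integers(0, 1), occ=st.booleans(),
    )
    def test_rows_sum_to_one(self, p1, p2, m, g, occ):
        row = transect_event_probs(occ, p1, p2, g, m)
        assert np.isclose(row.sum(), 1.0)
        assert np.all(row >= 0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(p3=st.floats(0, 1), occ=st.booleans())
    def test_camera_rows_sum_to_one(self, p3, occ):
        assert np.isclose(camera_event_probs(occ, p3).sum(), 1.0)


class TestCARPrecision:
    def test_zero_phi_gives_degree_diagonal(self, grid5):
        adj = build_adjacency(grid5)
        Q = car_precision(1.0, 0.0, adj)
        assert np.allclose(Q, np.diag(adj.D))

    def test_two_cell_hand_arithmetic(self):
        adj = build_adjacency(build_grid(1, 2, seed=0))
        Q = car_precision(1.0, 0.5, adj)
        assert np.allclose(Q, [[1.0, -0.5], [-0.5, 1.0]])

    def test_sigma_scaling(self, grid5):
        adj = build_adjacency(grid5)
        assert np.allclose(car_precision(2.0, 0.3, adj), car_precision(1.0, 0.3, adj) / 4)

    @pytest.mark.parametrize("phi", [-0.99, 0.0, 0.5, 0.99])
    def test_positive_definite(self, grid5, phi):
        Q = car_precision(1.0, phi, build_adjacency(grid5))
        assert np.array_equal(Q, Q.T)
        assert np.linalg.eigvalsh(Q).min() > 0

    def test_improper_phi_rejected(self, grid5):
        with pytest.raises(ValueError):
            car_precision(1.0, 1.0, build_adjacency(grid5))

    def test_car_logpdf_matches_gaussian(self, grid5):
        """The sampler's CAR log-density agrees with the multivariate normal
        implied by car_precision."""
        adj = build_adjacency(grid5)
        model_data = make_occ_data(np.zeros((25, 2), dtype=int), np.zeros(25))
        m = OccupancyModel(model_data, grid5, psi_covariates=(), effort_effect=False)
        rng = np.random.default_rng(3)
        eps = rng.standard_normal(25)
        sigma, phi = 0.8, 0.4
        Q = car_precision(sigma, phi, adj)
        sign, logdet = np.linalg.slogdet(Q)
        expected = 0.5 * logdet - 0.5 * eps @ Q @ eps
        assert np.isclose(m.car_logpdf(eps, sigma, phi), expected, atol=1e-8)


class TestPsiLinpred:
    def test_null_coefficients_give_half(self, grid5):
        psi = psi_linpred(grid5, np.zeros(4))
        assert np.allclose(psi, 0.5)

    def test_intercept_only_study_estimate(self, grid5):
        psi = psi_linpred(grid5, [logit(0.742)], covariates=())
        assert np.allclose(psi, 0.742)

    def test_altitude_monotonicity(self, grid5):
        psi = psi_linpred(grid5, [0.0, 3.0], covariates=("altitude",))
        alt = grid5.covariate("altitude")
        order = np.argsort(alt)
        assert np.all(np.diff(psi[order]) >= 0)

    def test_length_mismatch(self, grid5):
        with pytest.raises(ValueError):
            psi_linpred(grid5, [0.0, 1.0], covariates=("altitude", "forest"))


def _toy_model_and_params(events, G, psi, P1, P2L, delta, theta, M, grid,
                          camera_events=None, P3=None):
    data = make_occ_data(events, G, camera_events=camera_events)
    model = OccupancyModel(
        data, grid, psi_covariates=(), effort_effect=False, car=False,
        mixture=True,
    )
    params = OccupancyParams(
        beta_psi=np.array([logit(psi)]),
        alpha_p1=np.array([logit(P1)]),
        alpha_p2=np.array([logit(P2L)]),
        delta_p2=delta,
        alpha_p3=None if P3 is None else np.array([logit(P3)]),
        M=M,
        theta=theta,
    )
    return model, params


class TestOccupancyLoglik:
    def test_empty_product_is_zero(self, grid5):
        g = build_grid(1, 1, seed=0)
        model, params = _toy_model_and_params(
            [[-1, -1]], [0], 0.6, 0.1, 0.3, 0.8, 0.4, 0.05, g
        )
        assert model.loglik(params, marginalize=True) == pytest.approx(0.0)

    def test_conditional_single_event(self):
        g = build_grid(1, 1, seed=0)
        model, params = _toy_model_and_params(
            [[3]], [0], 0.6, 0.1, 0.3, 0.0, 0.0, 0.05, g
        )
        params.z_occ = np.array([1])
        params.mix_class = np.array([0])
        # occupied, G=0, event 3 (unverified sign): P2*(1-G) = 0.3, plus the
        # z prior and class prior terms
        expected = np.log(0.6) + np.log(0.3) + np.log(1 - 0.0)
        assert model.loglik(params, marginalize=False) == pytest.approx(expected)

    def test_marginal_matches_bruteforce_enumeration(self):
        """Marginal likelihood equals full enumeration over latent states."""
        g = build_grid(1, 3, seed=2)
        events = np.array([[0, 3], [1, 2], [-1, 0]])
        G = np.array([0, 1, 1])
        psi, P1, P2L, delta, theta, M = 0.62, 0.08, 0.35, 0.9, 0.43, 0.048
        model, params = _toy_model_and_params(
            events, G, psi, P1, P2L, delta, theta, M, g
        )
        P2H = expit(logit(P2L) + delta)
        expected = oracles.occupancy_marginal_loglik(
            events, G, psi, P1, P2L, P2H, theta, M
        )
        got = model.loglik(params, marginalize=True)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_marginal_with_camera_matches_bruteforce(self):
        g = build_grid(1, 2, seed=2)
        events = np.array([[0, 3], [1, -1]])
        cam = np.array([[1, 0], [-1, 0]])
        G = np.array([1, 1])
        psi, P1, P2L, delta, theta, M, P3 = 0.5, 0.1, 0.25, 0.7, 0.3, 0.06, 0.4
        model, params = _toy_model_and_params(
            events, G, psi, P1, P2L, delta, theta, M, g,
            camera_events=cam, P3=P3,
        )
        P2H = expit(logit(P2L) + delta)
        expected = oracles.occupancy_marginal_loglik(
            events, G, psi, P1, P2L, P2H, theta, M, cam_events=cam, P3=P3
        )
        assert model.loglik(params, marginalize=True) == pytest.approx(expected, abs=1e-10)

    def test_marginal_geq_best_conditional(self):
        g = build_grid(1, 2, seed=1)
        events = np.array([[0, 3], [1, 1]])
        G = np.array([1, 1])
        model, params = _toy_model_and_params(
            events, G, 0.55, 0.1, 0.3, 0.5, 0.4, 0.05, g
        )
        marg = model.loglik(params, marginalize=True)
        best = -np.inf
        from itertools import product
        for z in product((0, 1), repeat=2):
            for k in product((0, 1), repeat=2):
                params.z_occ = np.array(z)
                params.mix_class = np.array(k)
                best = max(best, model.loglik(params, marginalize=False))
        assert marg >= best - 1e-12

    def test_genetic_event_requires_analysis_flag(self, grid5):
        events = np.full((25, 4), -1)
        events[0, 0] = 1  # confirmed wolf in a cell without genetic analysis
        with pytest.raises(ValueError, match="G=1"):
            make_occ_data(events, np.zeros(25)).validate()

    def test_reduces_to_two_source_model_without_misid(self):
        """With M=0, G=1 everywhere and no mixture, the transect likelihood
        collapses to a standard occupancy model (independent implementation)."""
        g = build_grid(2, 2, seed=5)
        events = np.array([[0, 1], [1, 1], [0, 0], [-1, 1]])
        G = np.ones(4, dtype=int)
        model, params = _toy_model_and_params(
            events, G, 0.6, 0.0, 0.35, 0.0, 0.0, 0.0, g
        )
        got = model.loglik(params, marginalize=True)
        # independent simple implementation: detection = event>0
        expected = 0.0
        for c in range(4):
            p_occ = 1.0
            any_obs = False
            for t in range(2):
                if events[c, t] < 0:
                    continue
                any_obs = True
                det = events[c, t] > 0
                p_occ *= 0.35 if det else 0.65
            p_un = 0.0 if (events[c] > 0).any() else 1.0
            expected += np.log(0.6 * p_occ + 0.4 * (p_un if any_obs else 1.0))
        assert got == pytest.approx(expected, abs=1e-10)


class TestDetectionLinpreds:
    def test_effort_monotone_and_missing_flagged(self, grid5):
        events = np.full((25, 4), 0)
        events[:, 3] = -1
        eff = np.zeros((25, 4))
        eff[:, :3] = np.linspace(1, 30, 75).reshape(25, 3)
        data = make_occ_data(events, np.zeros(25))
        data.effort_transect = eff
        data.transect_events = np.where(eff > 0, 0, -1)
        model = OccupancyModel(data, grid5, psi_covariates=(), car=False)
        params = OccupancyParams(
            beta_psi=np.array([0.0]),
            alpha_p1=np.array([logit(0.05), 2.71]),
            alpha_p2=np.array([logit(0.3), 2.71]),
            delta_p2=0.5,
        )
        P1, P2L, P2H, _ = model.detection_linpreds(params)
        assert np.isnan(P1[:, 3]).all()
        obs = ~np.isnan(P2L)
        order = np.argsort(eff[obs])
        assert np.all(np.diff(P2L[obs][order]) >= -1e-12)
        # mixture offset acts on the logit scale
        assert np.allclose(
            logit(P2H[obs]) - logit(P2L[obs]), 0.5, atol=1e-9
        )

    def test_zero_effort_slope_constant(self, grid5):
        events = np.zeros((25, 4), dtype=int)
        data = make_occ_data(events, np.zeros(25))
        data.effort_transect = np.random.default_rng(0).uniform(1, 20, (25, 4))
        model = OccupancyModel(data, grid5, psi_covariates=(), car=False)
        params = OccupancyParams(
            beta_psi=np.array([0.0]),
            alpha_p1=np.array([logit(0.05), 0.0]),
            alpha_p2=np.array([logit(0.3), 0.0]),
        )
        P1, P2L, _, _ = model.detection_linpreds(params)
        assert np.allclose(P1, 0.05)
        assert np.allclose(P2L, 0.3)

    def test_negative_effort_rejected(self, grid5):
        events = np.zeros((25, 4), dtype=int)
        data = make_occ_data(events, np.zeros(25))
        data.effort_transect = -np.ones((25, 4))
        with pytest.raises(ValueError):
            data.validate()
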