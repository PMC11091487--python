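import numpy as np
import pytest
from scipy.special import expit, logit

import oracles
from conftest import make_detectors, make_scr_data
from wolfscr.grid import build_grid
from wolfscr.scr import (
    DetectorGeometry,
    SCRModel,
    SCRParams,
    abundance_posterior,
    density_intensity,
    halfnormal_p,
    poisson_binomial_pmf,
)


class TestHalfNormal:
    def test_baseline_at_zero_distance(self):
        assert halfnormal_p(0.2, 0.0, 3.0) == pytest.approx(0.2)

    def test_half_probability_distance(self):
        sigma = 3.49
        d = sigma * np.sqrt(2 * np.log(2))
        assert halfnormal_p(0.4, d, sigma) == pytest.approx(0.2)

    def test_study_scale_values(self):
        # p0 = 0.006 at d = sigma = 3.49 km decays by e^{-1/2}
        assert halfnormal_p(0.006, 3.49, 3.49) == pytest.approx(
            0.006 * np.exp(-0.5), rel=1e-6
        )
        assert halfnormal_p(0.006, 3.49, 3.49) == pytest.approx(0.003639, abs=5e-6)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            halfnormal_p(0.1, 1.0, 0.0)

    def test_monotone_decreasing(self):
        d = np.linspace(0, 30, 50)
        p = halfnormal_p(0.1, d, 3.49)
        assert np.all(np.diff(p) < 0)


class TestDetectorGeometry:
    @pytest.mark.parametrize("sigma", [1.0, 3.49, 12.0])
    def test_factorised_mean_matches_direct_distances(self, sigma):
        g = build_grid(4, 5, seed=3)
        geom = DetectorGeometry(g, make_detectors(g, [6, 13]))
        H = geom.mean_halfnormal(sigma)
        for c in [0, 6, 13, 19]:
            for d in [0, 1]:
                det_cell = geom.det_cells[d]
                direct = oracles.sub_mean_halfnormal(
                    (g.x[c], g.y[c]), (g.x[det_cell], g.y[det_cell]), sigma
                )
                assert H[c, d] == pytest.approx(direct, abs=1e-12)

    def test_p_eff_bounded_by_p0_and_sigma_limit(self):
        g = build_grid(4, 5, seed=3)
        geom = DetectorGeometry(g, make_detectors(g, [6]))
        assert np.all(geom.mean_halfnormal(3.49) <= 1.0)
        assert np.allclose(geom.mean_halfnormal(1e6), 1.0, atol=1e-9)

    def test_per_cell_sigma(self):
        g = build_grid(3, 3, seed=1)
        geom = DetectorGeometry(g, make_detectors(g, [4]))
        sig = np.full(9, 2.0)
        sig[0] = 5.0
        H = geom.mean_halfnormal(sig)
        assert H[0, 0] == pytest.approx(geom.mean_halfnormal(5.0)[0, 0])
        assert H[1, 0] == pytest.approx(geom.mean_halfnormal(2.0)[1, 0])


class TestDensityIntensity:
    def test_flat_intercept(self):
        g = build_grid(10, 29, seed=1)
        lam, EN = density_intensity(g, 0.0)
        assert np.allclose(lam, 1.0)
        assert EN == pytest.approx(290.0)

    def test_reference_population_share(self):
        # intercept log(506/290) on a flat surface integrates to 506
        g = build_grid(10, 29, seed=1)
        _, EN = density_intensity(g, np.log(506 / 290))
        assert EN == pytest.approx(506.0, abs=1e-9)

    def test_log_linear_doubling(self, grid5):
        _, EN1 = density_intensity(grid5, 0.3, {"altitude": 1.0, "forest": -0.5})
        _, EN2 = density_intensity(grid5, 0.3 + np.log(2), {"altitude": 1.0, "forest": -0.5})
        assert EN2 == pytest.approx(2 * EN1)

    def test_relabeling_invariance(self, grid5):
        lam, EN = density_intensity(grid5, 0.1, {"altitude": 0.7})
        perm = np.random.default_rng(0).permutation(grid5.n_cells)
        g2 = build_grid(grid5.n_rows, grid5.n_cols, seed=7)
        g2.cells[list(g2.cells.columns[6:])] = (
            grid5.cells[list(grid5.cells.columns[6:])].to_numpy()[perm]
        )
        lam2, EN2 = density_intensity(g2, 0.1, {"altitude": 0.7})
        assert EN2 == pytest.approx(EN)
        assert np.allclose(np.sort(lam2), np.sort(lam))


class TestAbundancePosterior:
    def test_degenerate_draws(self):
        s = abundance_posterior(np.full(50, 7.0))
        assert s.mean == 7 and s.sd == 0

    def test_hand_arithmetic(self):
        s = abundance_posterior(np.array([100.0, 110.0, 90.0]))
        assert s.mean == pytest.approx(100.0)
        assert s.sd == pytest.approx(10.0)
        assert s.cv == pytest.approx(0.1)

    def test_z_matrix_input_and_ci_monotone(self, rng):
        z = rng.random((200, 30)) < 0.4
        s = abundance_posterior(z.astype(int))
        N = z.sum(axis=1)
        assert s.mean == pytest.approx(N.mean())
        assert s.ci_low <= s.mean <= s.ci_high
        assert s.ci_low == pytest.approx(np.percentile(N, 2.5))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            abundance_posterior(np.array([]))


class TestPoissonBinomial:
    def test_matches_binomial_for_equal_probs(self):
        from scipy.stats import binom
        probs = np.full(20, 0.07)
        for k in range(5):
            assert poisson_binomial_pmf(probs, k) == pytest.approx(
                binom.pmf(k, 20, 0.07), abs=1e-12
            )

    def test_sums_to_one(self, rng):
        probs = rng.random(15) * 0.3
        total = sum(poisson_binomial_pmf(probs, k) for k in range(16))
        assert total == pytest.approx(1.0, abs=1e-10)


def _toy_scr(grid, det_cells, y, M_aug, **model_kwargs):
    data = make_scr_data(grid, det_cells, y)
    model = SCRModel(
        data, grid, density_covariates=("altitude",), effort_on_p0=False,
        density_car=False, M_aug=M_aug, **model_kwargs,
    )
    params = SCRParams(
        p0_intercept=logit(0.05),
        log_sigma0=np.log(2.5),
        mu={"altitude": 0.4},
        mix_delta=0.7,
        mix_pi=0.3,
        psi_aug=0.6,
        M_aug=M_aug,
    )
    return model, params


def _oracle_pieces(grid, model, params, sigma=2.5):
    lam = np.exp(0.4 * oracles.standardize(grid.covariate("altitude")))
    w = lam / lam.sum()
    p0 = np.array([expit(params.p0_intercept),
                   expit(params.p0_intercept + params.mix_delta)])
    comp_w = np.array([1 - params.mix_pi, params.mix_pi])
    det_cells = model.geom.det_cells
    C, n_cells, D = 2, grid.n_cells, len(det_cells)
    probs = np.zeros((C, n_cells, D))
    for k in range(C):
        for c in range(n_cells):
            for d in range(D):
                h = oracles.sub_mean_halfnormal(
                    (grid.x[c], grid.y[c]),
                    (grid.x[det_cells[d]], grid.y[det_cells[d]]), sigma,
                )
                probs[k, c, d] = p0[k] * h
    return lam, w, probs, comp_w


class TestSCRLoglik:
    def test_zero_counts_zero_inclusion(self):
        g = build_grid(2, 2, seed=1)
        model, params = _toy_scr(g, [0], np.zeros((0, 1)), M_aug=3)
        params.psi_aug = 1e-12
        # with psi ~ 0 every augmented individual is excluded: loglik ~ 0
        assert model.loglik(params, marginalize=True) == pytest.approx(0.0, abs=1e-9)

    def test_single_zero_history_binomial(self):
        g = build_grid(1, 1, seed=0)
        model, params = _toy_scr(g, [0], np.zeros((0, 1)), M_aug=1)
        params.psi_aug = 1.0
        params.mix_pi = 0.0
        h = oracles.sub_mean_halfnormal((g.x[0], g.y[0]), (g.x[0], g.y[0]), 2.5)
        p = expit(params.p0_intercept) * h
        expected = 100 * np.log1p(-p)
        assert model.loglik(params, marginalize=True) == pytest.approx(expected, abs=1e-9)

    def test_marginal_matches_bruteforce(self):
        """Marginal SCR likelihood equals enumeration over inclusion states,
        activity-centre cells and mixture components."""
        g = build_grid(2, 2, seed=4)
        y = np.array([[2, 0], [1, 3]])
        model, params = _toy_scr(g, [0, 3], y, M_aug=4)
        lam, w, probs, comp_w = _oracle_pieces(g, model, params)
        expected = oracles.scr_marginal_loglik(
            y, 4, params.psi_aug, probs, comp_w, w, 100
        )
        got = model.loglik(params, marginalize=True)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_conditional_configurations_sum_to_marginal(self):
        from itertools import product
        g = build_grid(1, 2, seed=4)
        y = np.array([[1, 0]])
        M_aug = 2
        model, params = _toy_scr(g, [0, 1], y, M_aug=M_aug)
        marg = model.loglik(params, marginalize=True)
        total = 0.0
        for z1, s0, s1, k0, k1 in product((0, 1), (0, 1), (0, 1), (0, 1), (0, 1)):
            params.z = np.array([1, z1])
            params.s = np.array([s0, s1])
            params.mix_class_ind = np.array([k0, k1])
            ll = model.loglik(params, marginalize=False)
            total += np.exp(ll)
        assert np.log(total) == pytest.approx(marg, abs=1e-10)

    def test_exact_poisson_binomial_mode(self):
        g = build_grid(1, 2, seed=4)
        y = np.array([[1, 0]])
        model, params = _toy_scr(g, [0, 1], y, M_aug=1, aggregation="poisson-binomial")
        params.mix_pi = 0.0
        got = model.loglik(params, marginalize=True)
        # independent: per-sub-detector Bernoulli convolution
        p0 = expit(params.p0_intercept)
        lam = np.exp(0.4 * oracles.standardize(g.covariate("altitude")))
        w = lam / lam.sum()
        total = 0.0
        for c in range(2):
            lik = 1.0
            for d in range(2):
                probs = halfnormal_p(p0, model.geom.sub_distances(c, d), 2.5)
                lik *= poisson_binomial_pmf(probs, int(y[0, d]))
            total += w[c] * lik
        expected = np.log(params.psi_aug) + np.log(total)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_count_exceeding_trials_rejected(self):
        g = build_grid(1, 2, seed=0)
        with pytest.raises(ValueError):
            make_scr_data(g, [0], np.array([[101, 0]])).validate()


class TestSCRFit:
    def test_posterior_N_bounded_by_detected_and_ceiling(self):
        from wolfscr.mcmc import MCMCConfig
        g = build_grid(4, 4, seed=8)
        rng = np.random.default_rng(2)
        y = np.zeros((5, 4), dtype=int)
        y[np.arange(5), rng.integers(0, 4, 5)] = rng.integers(1, 4, 5)
        data = make_scr_data(g, [5, 6, 9, 10], y)
        model = SCRModel(data, g, density_car=False, effort_on_p0=False)
        res = model.fit(MCMCConfig(n_chains=2, n_iter=400, burn_in=100, thin=2, seed=3))
        N = res.pooled("N")
        assert N.min() >= 5
        assert N.max() <= model.M_aug == 55

    def test_same_seed_reproducible(self):
        from wolfscr.mcmc import MCMCConfig
        g = build_grid(3, 3, seed=8)
        y = np.array([[2, 0], [0, 1]])
        data = make_scr_data(g, [0, 4], y)
        cfg = MCMCConfig(n_chains=2, n_iter=200, burn_in=50, thin=2, seed=11)
        r1 = SCRModel(data, g, density_car=False).fit(cfg)
        r2 = SCRModel(data, g, density_car=False).fit(cfg)
        for k in r1.draws:
            assert np.array_equal(r1.draws[k], r2.draws[k])
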