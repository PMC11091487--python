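from itertools import product

import numpy as np
import pytest
from scipy.special import expit, logit

import oracles
from conftest import make_occ_data, make_scr_data
from wolfscr.grid import build_grid
from wolfscr.mcmc import (
    AdaptiveFieldSteps,
    AdaptiveRW,
    InitError,
    MCMCConfig,
    rhat,
    sample_logpost,
)
from wolfscr.occupancy import OccupancyModel, _OccComponent
from wolfscr.scr import SCRModel, _SCRComponent


class TestRhat:
    def test_identical_chains_give_one(self, rng):
        x = rng.standard_normal(500)
        chains = np.stack([x, x])
        assert rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_flagged(self, rng):
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert rhat(chains) > 1.5

    def test_label_permutation_invariant(self, rng):
        chains = rng.standard_normal((4, 300))
        assert rhat(chains) == pytest.approx(rhat(chains[::-1]), abs=1e-12)

    def test_well_mixed_near_one(self, rng):
        chains = rng.standard_normal((2, 2000))
        assert rhat(chains) < 1.02

    def test_agrees_with_arviz(self, rng):
        import arviz as az

        chains = rng.standard_normal((2, 500)) + np.linspace(0, 0.5, 500)
        assert rhat(chains) == pytest.approx(float(az.rhat(chains)), abs=0.02)

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            rhat(rng.standard_normal((1, 100)))


class TestAdaptation:
    def test_frozen_step_constant(self):
        prop = AdaptiveRW(step=0.5)
        rng = np.random.default_rng(0)
        for _ in range(100):
            prop.update(rng.random() < 0.3)
        step_mid = prop.step
        assert step_mid != 0.5  # adapted during warm-up
        prop.freeze()
        for _ in range(100):
            prop.update(rng.random() < 0.3)
        assert prop.step == step_mid

    def test_field_steps_freeze(self):
        steps = AdaptiveFieldSteps(10, step=0.5)
        rng = np.random.default_rng(0)
        steps.update(rng.random(10) < 0.2)
        frozen = steps.steps.copy()
        steps.freeze()
        steps.update(np.ones(10, dtype=bool))
        assert np.array_equal(steps.steps, frozen)


class TestGenericSampler:
    def test_standard_normal_mean(self):
        cfg = MCMCConfig(n_chains=2, n_iter=12_000, burn_in=2_000, thin=1, seed=42)
        res = sample_logpost(lambda x: -0.5 * float(x @ x), [0.0], cfg)
        draws = res.pooled("x0")
        assert abs(draws.mean()) < 0.05
        assert draws.std() == pytest.approx(1.0, abs=0.05)

    def test_beta_bernoulli_conjugate_posterior(self):
        """Uniform prior + 6 successes in 20 trials -> Beta(7, 15); the
        sampled posterior mean must sit within 3 MC standard errors."""
        import arviz as az

        n, k = 20, 6
        def logpost(u):
            u = float(u[0])
            # binomial likelihood on the logit scale + uniform-prior jacobian
            return k * u - n * np.logaddexp(0.0, u) + np.log(expit(u)) + np.log(expit(-u))

        cfg = MCMCConfig(n_chains=2, n_iter=15_000, burn_in=3_000, thin=1, seed=7)
        res = sample_logpost(logpost, [0.0], cfg)
        p = expit(res.pooled("x0"))
        ess = float(az.ess(expit(res.draws["x0"])))
        mc_se = p.std(ddof=1) / np.sqrt(ess)
        assert abs(p.mean() - 7 / 22) < 3 * mc_se

    def test_same_seed_identical_draws(self):
        cfg = MCMCConfig(n_chains=2, n_iter=500, burn_in=100, thin=1, seed=3)
        r1 = sample_logpost(lambda x: -0.5 * float(x @ x), [0.0], cfg)
        r2 = sample_logpost(lambda x: -0.5 * float(x @ x), [0.0], cfg)
        assert np.array_equal(r1.draws["x0"], r2.draws["x0"])

    def test_nonfinite_init_raises(self):
        cfg = MCMCConfig(n_iter=10, burn_in=1, seed=0)
        with pytest.raises(InitError):
            sample_logpost(lambda x: -np.inf, [0.0], cfg)


def _fixed_occ_component(model, seed=0, psi=0.5, P1=0.1, P2=0.4, M=0.05):
    cfg = MCMCConfig(n_iter=10, burn_in=1, seed=seed)
    comp = _OccComponent(model, np.random.default_rng(seed), cfg)
    comp.beta = np.array([logit(psi)])
    comp.a1 = np.array([logit(P1)])
    comp.a2 = np.array([logit(P2)])
    comp.M_l = logit(M)
    comp.refresh_liks()
    return comp


class TestDetailedBalance:
    def test_occupancy_state_gibbs_matches_enumeration(self):
        """Long-run z_occ configuration frequencies match the brute-force
        posterior on a 2-cell problem with fixed parameters."""
        g = build_grid(1, 2, seed=3)
        events = np.array([[1, 0], [0, 0]])
        G = np.array([1, 1])
        data = make_occ_data(events, G)
        model = OccupancyModel(
            data, g, psi_covariates=(), effort_effect=False, car=False,
            mixture=False,
        )
        psi, P1, P2, M = 0.5, 0.1, 0.4, 0.05
        comp = _fixed_occ_component(model, psi=psi, P1=P1, P2=P2, M=M)

        # brute-force posterior over the 4 configurations
        weights = {}
        for z in product((0, 1), repeat=2):
            weights[z] = oracles.occupancy_conditional_lik(
                events, G, psi, P1, P2, P2, 0.0, M, np.array(z)
            )
        total = sum(weights.values())
        probs = {z: w / total for z, w in weights.items()}

        counts = {z: 0 for z in probs}
        n_sweeps = 50_000
        for _ in range(n_sweeps):
            comp.update_z()
            counts[tuple(int(v) for v in comp.z)] += 1
        for z, p in probs.items():
            assert counts[z] / n_sweeps == pytest.approx(p, abs=0.02)

    def test_gated_occupancy_scr_chain_matches_enumeration(self):
        """The coupled sweeps (gated z_occ + activity centres + inclusion)
        leave the exact joint posterior invariant on an enumerable toy:
        long-run state frequencies match brute-force probabilities,
        validating the intensity-renormalisation factor."""
        g = build_grid(1, 2, seed=3)
        events = np.array([[1, 0], [0, 0]])
        G = np.array([1, 1])
        occ_data = make_occ_data(events, G)
        occ_model = OccupancyModel(
            occ_data, g, psi_covariates=(), effort_effect=False, car=False,
            mixture=False,
        )
        y = np.array([[2]])
        scr_data = make_scr_data(g, [0], y)
        scr_model = SCRModel(
            scr_data, g, density_covariates=("altitude",), effort_on_p0=False,
            density_car=False, mixture=False, M_aug=2,
        )
        psi, P1, P2, M = 0.5, 0.1, 0.4, 0.05
        p0, sigma, psi_aug = 0.07, 2.0, 0.6
        rng = np.random.default_rng(11)
        cfg = MCMCConfig(n_iter=10, burn_in=1, seed=0)
        occ_c = _fixed_occ_component(occ_model, psi=psi, P1=P1, P2=P2, M=M)
        scr_c = _SCRComponent(scr_model, rng, cfg, z_occ=occ_c.z)
        scr_c.a0 = logit(p0)
        scr_c.log_sigma = np.log(sigma)
        scr_c.mu = np.array([0.3])
        scr_c.psi_aug = psi_aug
        scr_c.refresh_detection()
        scr_c.refresh_density()
        scr_c.refresh_counts()

        # independent stationary distribution over (z_occ, s0, s1, z1)
        lam = np.exp(0.3 * oracles.standardize(g.covariate("altitude")))
        probs_det = np.zeros((1, 2, 1))
        for c in range(2):
            probs_det[0, c, 0] = p0 * oracles.sub_mean_halfnormal(
                (g.x[c], g.y[c]), (g.x[0], g.y[0]), sigma
            )
        from scipy.stats import binom as binom_dist

        weights = {}
        for z_occ in product((0, 1), repeat=2):
            lam_g = lam * np.array(z_occ)
            if lam_g.sum() <= 0:
                continue
            w = lam_g / lam_g.sum()
            occ_lik = oracles.occupancy_conditional_lik(
                events, G, psi, P1, P2, P2, 0.0, M, np.array(z_occ)
            )
            for s0, s1, z1 in product((0, 1), (0, 1), (0, 1)):
                if w[s0] == 0 or w[s1] == 0:
                    continue
                lik = w[s0] * binom_dist.pmf(2, 100, probs_det[0, s0, 0])
                lik *= w[s1]
                if z1:
                    lik *= psi_aug * binom_dist.pmf(0, 100, probs_det[0, s1, 0])
                else:
                    lik *= 1 - psi_aug
                weights[(z_occ, s0, s1, z1)] = occ_lik * lik
        total = sum(weights.values())
        probs = {k: v / total for k, v in weights.items()}

        counts = {k: 0 for k in probs}
        n_sweeps = 40_000
        for _ in range(n_sweeps):
            T = occ_c.update_z(
                lam=scr_c.lam_all, counts=scr_c.counts,
                n_active=scr_c.n_active, T=scr_c.T, gate=True,
            )
            scr_c.T = float(T)
            scr_c.update_s()
            scr_c.update_z_aug()
            key = (
                tuple(int(v) for v in occ_c.z),
                int(scr_c.s[0]), int(scr_c.s[1]), int(scr_c.z[1]),
            )
            counts[key] += 1
        for k, p in probs.items():
            assert counts[k] / n_sweeps == pytest.approx(p, abs=0.02)
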