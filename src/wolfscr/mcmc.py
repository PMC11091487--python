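"""MCMC engine: adaptive random-walk Metropolis blocks, chain management,
and convergence diagnostics.

The samplers in this package are Metropolis-within-Gibbs: discrete latent
states (occupancy states, inclusion indicators, activity-centre cells) are
drawn from their full conditionals, continuous parameters move by adaptive
random-walk Metropolis.  Step sizes adapt with a diminishing Robbins-Monro
schedule and are frozen at the end of burn-in, so the post-burn-in chain is
a fixed Markov kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri


class InitError(RuntimeError):
    """Raised when a sampler cannot be initialised at a finite posterior."""


@dataclass
class MCMCConfig:
    """Chain settings.  Defaults mirror the real-data analysis protocol
    (two chains of 30,000 iterations); simulation studies use shorter,
    explicitly configured chains."""

    n_chains: int = 2
    n_iter: int = 30_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0
    target_accept: float = 0.44
    adapt_rate: float = 1.0

    def __post_init__(self):
        if not (self.n_iter > self.burn_in >= 0):
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws_per_chain(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


class AdaptiveRW:
    """Scalar or block random-walk proposal with diminishing adaptation."""

    def __init__(self, dim=1, step=0.2, target=0.44, adapt_rate=1.0):
        self.dim = dim
        self.log_step = float(np.log(step))
        self.target = 0.234 if dim > 1 else target
        self.adapt_rate = adapt_rate
        self.t = 0
        self.frozen = False
        self.n_accept = 0
        self.n_prop = 0

    @property
    def step(self) -> float:
        return float(np.exp(self.log_step))

    def propose(self, x, rng):
        if self.dim == 1:
            return x + self.step * rng.standard_normal()
        return x + self.step * rng.standard_normal(self.dim)

    def update(self, accepted: bool):
        self.t += 1
        self.n_prop += 1
        self.n_accept += int(accepted)
        if not self.frozen:
            gamma = self.adapt_rate / self.t**0.6
            self.log_step += gamma * (float(accepted) - self.target)
            self.log_step = float(np.clip(self.log_step, -12.0, 5.0))

    def freeze(self):
        self.frozen = True


class AdaptiveFieldSteps:
    """Per-site step sizes for the single-site field sweeps."""

    def __init__(self, n, step=0.5, target=0.44, adapt_rate=1.0):
        self.log_steps = np.full(n, np.log(step))
        self.target = target
        self.adapt_rate = adapt_rate
        self.t = 0
        self.frozen = False

    @property
    def steps(self) -> np.ndarray:
        return np.exp(self.log_steps)

    def update(self, accept_vec: np.ndarray):
        self.t += 1
        if not self.frozen:
            gamma = self.adapt_rate / self.t**0.6
            self.log_steps += gamma * (accept_vec.astype(float) - self.target)
            np.clip(self.log_steps, -12.0, 5.0, out=self.log_steps)

    def freeze(self):
        self.frozen = True


# ---------------------------------------------------------------------------
# diagnostics


def _split_chains(x: np.ndarray) -> np.ndarray:
    m, n = x.shape
    half = n // 2
    return np.concatenate([x[:, :half], x[:, n - half :]], axis=0)


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    flat = x.ravel()
    ranks = np.argsort(np.argsort(flat, kind="stable"), kind="stable") + 1.0
    z = ndtri((ranks - 3.0 / 8.0) / (flat.size + 0.25))
    return z.reshape(x.shape)


def _basic_rhat(x: np.ndarray) -> float:
    m, n = x.shape
    chain_means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B = n * chain_means.var(ddof=1)
    if W <= 0:
        return 1.0 if B <= 0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def rhat(chains: np.ndarray) -> float:
    """Split rank-normalised potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws).  The split-chain variant on
    rank-normalised draws is used, together with the folded version; the
    larger of the two is returned (conservative).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("rhat needs >= 2 chains of draws")
    if x.shape[1] < 4:
        raise ValueError("rhat needs >= 4 draws per chain")
    x = _split_chains(x)
    if np.allclose(x, x.ravel()[0]):
        return 1.0
    r_bulk = _basic_rhat(_rank_normalize(x))
    folded = np.abs(x - np.median(x))
    r_tail = _basic_rhat(_rank_normalize(folded))
    return max(r_bulk, r_tail)


def ess(chains: np.ndarray) -> float:
    """Bulk effective sample size (via arviz)."""
    import arviz as az

    return float(az.ess(np.asarray(chains, dtype=float)))


# ---------------------------------------------------------------------------
# results container


@dataclass
class PosteriorResult:
    """Posterior draws plus diagnostics for one fitted model.

    ``draws`` maps parameter name -> array of shape (n_chains, n_draws)
    for scalars or (n_chains, n_draws, k) for vectors.
    """

    draws: dict
    config: MCMCConfig
    model_name: str = "model"
    extra: dict = field(default_factory=dict)

    def _scalar_items(self):
        for name, arr in self.draws.items():
            if arr.ndim == 2:
                yield name, arr
            else:
                for j in range(arr.shape[2]):
                    yield f"{name}[{j}]", arr[:, :, j]

    def rhat(self) -> dict:
        return {name: rhat(a) for name, a in self._scalar_items()}

    def ess(self) -> dict:
        return {name: ess(a) for name, a in self._scalar_items()}

    def pooled(self, name: str) -> np.ndarray:
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, a in self._scalar_items():
            flat = a.ravel()
            rows.append(
                {
                    "param": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1) if flat.size > 1 else 0.0,
                    "q2.5": np.percentile(flat, 2.5),
                    "q50": np.percentile(flat, 50),
                    "q97.5": np.percentile(flat, 97.5),
                    "rhat": rhat(a),
                }
            )
        return pd.DataFrame(rows).set_index("param")

    def max_rhat(self) -> float:
        return max(self.rhat().values())


# ---------------------------------------------------------------------------
# generic target sampler (used for conjugate / stationarity checks)


def sample_logpost(
    logpost, x0: np.ndarray, config: MCMCConfig, names: list | None = None
) -> PosteriorResult:
    """Adaptive RW Metropolis on an arbitrary log-density (block update)."""
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    dim = x0.size
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    out = np.empty((config.n_chains, config.n_draws_per_chain, dim))
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        x = x0 + 0.01 * rng.standard_normal(dim)
        lp = logpost(x)
        if not np.isfinite(lp):
            raise InitError("non-finite initial log-posterior")
        prop = AdaptiveRW(dim=dim, step=0.5, adapt_rate=config.adapt_rate)
        k = 0
        for it in range(config.n_iter):
            if it == config.burn_in:
                prop.freeze()
            xp = prop.propose(x, rng)
            lpp = logpost(xp)
            acc = np.log(rng.random()) < lpp - lp
            if acc:
                x, lp = xp, lpp
            prop.update(acc)
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                if k < out.shape[1]:
                    out[c, k] = x
                    k += 1
    draws = {}
    names = names or [f"x{j}" for j in range(dim)]
    for j, nm in enumerate(names):
        draws[nm] = out[:, :, j]
    return PosteriorResult(draws=draws, config=config, model_name="generic")


def run_mcmc(model, config: MCMCConfig):
    """Fit any of the package's model objects (statsmodels-style dispatch)."""
    return model.fit(config)
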