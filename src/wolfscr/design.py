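"""Design-evaluation simulation experiments.

Experiment 1 assesses the actual survey design: replicate datasets are
generated under the study conditions and analysed with four models —
the integrated occupancy+SCR model, a plain SCR model, an SCR model
without the spatial-autocorrelation (CAR) term in the density, and an SCR
model ignoring sampling effort — and relative bias and coefficient of
variation of the abundance estimates are summarised per model.

Experiment 2 sweeps the proportions of the study area sampled genetically
(10-50%) and for presence signs (20-50%), fits the integrated model, and
summarises the outcome with Poisson GLMs (log link) of the rounded percent
absolute bias and percent CV on the two sampled fractions, from which the
minimum fractions achieving bias < 10% and CV < 10% are predicted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import DesignError, build_grid, select_design
from .integrated import IntegratedModel
from .mcmc import MCMCConfig, rhat
from .occupancy import OccupancyModel
from .scr import SCRModel, abundance_posterior
from .simulate import SimConfig, simulate_dataset

VARIANTS = ("integrated", "scr_only", "no_spatial_autocorr", "no_effort")

RHAT_LIMIT = 1.1


class ConvergenceError(RuntimeError):
    pass


@dataclass
class SimOutcome:
    """Abundance-estimation outcome of one fitted replicate."""

    rep_id: int
    model_variant: str
    N_true: int
    n_detected: int
    N_mean: float
    N_sd: float
    ci_low: float
    ci_high: float
    converged: bool
    M_aug: int = 0
    ceiling_limited: bool = False  # posterior truncated by the augmentation cap

    @property
    def relative_bias(self) -> float:
        return (self.N_mean - self.N_true) / self.N_true

    @property
    def cv(self) -> float:
        return self.N_sd / self.N_mean if self.N_mean > 0 else np.nan

    def as_row(self) -> dict:
        return {
            "rep_id": self.rep_id,
            "model_variant": self.model_variant,
            "N_true": self.N_true,
            "n_detected": self.n_detected,
            "N_mean": self.N_mean,
            "N_sd": self.N_sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "relative_bias": self.relative_bias,
            "cv": self.cv,
            "converged": self.converged,
            "M_aug": self.M_aug,
            "ceiling_limited": self.ceiling_limited,
        }


def _variant_model(variant: str, ds):
    """Build the fitted model for one experiment arm."""
    scr_kwargs = dict(density_car=True, effort_on_p0=True, mixture=True)
    if variant == "no_spatial_autocorr":
        scr_kwargs["density_car"] = False
    if variant == "no_effort":
        scr_kwargs["effort_on_p0"] = False
    scr = SCRModel(ds.scr, ds.grid, **scr_kwargs)
    if variant == "integrated":
        occ = OccupancyModel(ds.occupancy, ds.grid, adjacency=scr.adj)
        return IntegratedModel(occ, scr)
    return scr


def fit_variant(
    variant: str, ds, mcmc: MCMCConfig, rhat_limit: float = RHAT_LIMIT
) -> SimOutcome | None:
    """Fit one arm on one simulated dataset; None if unfittable (no captures)."""
    if ds.scr.n_individuals == 0:
        return None
    model = _variant_model(variant, ds)
    res = model.fit(mcmc)
    ab = abundance_posterior(res.pooled("N"))
    converged = rhat(res.draws["N"]) <= rhat_limit
    scr_model = model.scr if hasattr(model, "scr") else model
    M_aug = scr_model.M_aug
    return SimOutcome(
        rep_id=-1,
        model_variant=variant,
        N_true=ds.population.N_true,
        n_detected=ds.scr.n_individuals,
        N_mean=ab.mean,
        N_sd=ab.sd,
        ci_low=ab.ci_low,
        ci_high=ab.ci_high,
        converged=converged,
        M_aug=M_aug,
        ceiling_limited=bool(ab.ci_high >= 0.95 * M_aug),
    )


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class Experiment1Result:
    outcomes: pd.DataFrame
    n_excluded: dict

    def summary(self) -> pd.DataFrame:
        return summarize_bias_cv(self.outcomes, by="model_variant")


def run_experiment1(
    cfg: SimConfig,
    variants=VARIANTS,
    n_reps: int = 20,
    seed: int = 0,
    mcmc: MCMCConfig | None = None,
    rhat_limit: float = RHAT_LIMIT,
) -> Experiment1Result:
    """Simulate ``n_reps`` datasets and fit every variant on each."""
    unknown = set(variants) - set(VARIANTS)
    if unknown:
        raise ValueError(f"unknown variants: {unknown}")
    mcmc = mcmc or MCMCConfig(n_iter=4000, burn_in=1500, thin=5)
    root = np.random.SeedSequence(seed)
    rows = []
    excluded = {v: 0 for v in variants}
    for rep, ss in enumerate(root.spawn(n_reps)):
        ds = simulate_dataset(cfg, seed=np.random.default_rng(ss))
        fit_seeds = ss.spawn(len(variants))
        for v, vss in zip(variants, fit_seeds):
            cfg_v = MCMCConfig(
                n_chains=mcmc.n_chains, n_iter=mcmc.n_iter, burn_in=mcmc.burn_in,
                thin=mcmc.thin, seed=_child_seed(vss), adapt_rate=mcmc.adapt_rate,
            )
            out = fit_variant(v, ds, cfg_v, rhat_limit=rhat_limit)
            if out is None:
                excluded[v] += 1
                continue
            out.rep_id = rep
            if not out.converged:
                excluded[v] += 1
            rows.append(out.as_row())
    df = pd.DataFrame(rows)
    return Experiment1Result(outcomes=df, n_excluded=excluded)


@dataclass
class PoissonGLMResult:
    coef: np.ndarray
    se: np.ndarray
    names: list
    model: object = None

    def predict(self, X) -> np.ndarray:
        return np.exp(np.asarray(X) @ self.coef)


def poisson_glm(y, X, names=None) -> PoissonGLMResult:
    """Poisson GLM with log link (IRLS maximum likelihood via statsmodels)."""
    import statsmodels.api as sm

    y = np.asarray(y)
    X = np.asarray(X, dtype=float)
    if np.any(y < 0) or not np.issubdtype(y.dtype, np.integer):
        if np.any(np.asarray(y, float) % 1 != 0) or np.any(y < 0):
            raise ValueError("response must be non-negative integers")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=100)
    if not res.converged:
        raise ConvergenceError("IRLS did not converge in 100 iterations")
    names = names or [f"x{j}" for j in range(X.shape[1])]
    return PoissonGLMResult(
        coef=np.asarray(res.params), se=np.asarray(res.bse), names=list(names), model=res
    )


@dataclass
class Experiment2Result:
    outcomes: pd.DataFrame
    glm_bias: PoissonGLMResult
    glm_cv: PoissonGLMResult

    def predicted_min_frac_genetic(
        self, target_percent: float = 10.0, frac_presence: float = 0.30,
        which: str = "bias",
    ) -> float:
        """Smallest genetic sampling fraction whose predicted response
        (percent |bias| or percent CV) falls below the target, at a given
        presence-sampling fraction."""
        g = self.glm_bias if which == "bias" else self.glm_cv
        b0, b_fg, b_fp = g.coef
        if b_fg >= 0:
            return np.nan
        return float((np.log(target_percent) - b0 - b_fp * frac_presence) / b_fg)


def run_experiment2(
    cfg: SimConfig,
    n_reps: int = 50,
    seed: int = 0,
    mcmc: MCMCConfig | None = None,
    frac_grid=None,
    fg_range=(0.10, 0.50),
    fp_range=(0.20, 0.50),
    rhat_limit: float = RHAT_LIMIT,
) -> Experiment2Result:
    """Sampling-fraction sweep analysed with the integrated model."""
    mcmc = mcmc or MCMCConfig(n_iter=4000, burn_in=1500, thin=5)
    root = np.random.SeedSequence(seed)
    rows = []
    for rep, ss in enumerate(root.spawn(n_reps)):
        rng = np.random.default_rng(ss)
        if frac_grid is not None:
            fg, fp = frac_grid[rep % len(frac_grid)]
        else:
            fg = rng.uniform(*fg_range)
            fp = rng.uniform(*fp_range)
        n_cells = cfg.n_rows * cfg.n_cols
        n_areas = max(1, int(round(fg * n_cells / 9)))
        grid = build_grid(cfg.n_rows, cfg.n_cols, seed=rng)
        try:
            design = select_design(grid, fp, n_areas, seed=rng)
        except DesignError:
            continue
        ds = simulate_dataset(cfg, seed=rng, grid=grid, design=design)
        cfg_fit = MCMCConfig(
            n_chains=mcmc.n_chains, n_iter=mcmc.n_iter, burn_in=mcmc.burn_in,
            thin=mcmc.thin, seed=_child_seed(ss), adapt_rate=mcmc.adapt_rate,
        )
        out = fit_variant("integrated", ds, cfg_fit, rhat_limit=rhat_limit)
        if out is None:
            continue
        rows.append(
            {
                "rep_id": rep,
                "frac_genetic": 9 * n_areas / n_cells,
                "frac_presence": fp,
                "N_true": out.N_true,
                "N_mean": out.N_mean,
                "relative_bias": out.relative_bias,
                "abs_bias_pct": int(round(100 * abs(out.relative_bias))),
                "cv_pct": int(round(100 * out.cv)),
                "converged": out.converged,
            }
        )
    df = pd.DataFrame(rows)
    ok = df[df["converged"]]
    if ok.empty:
        raise ConvergenceError("no converged experiment-2 replicates")
    X = np.column_stack(
        [np.ones(len(ok)), ok["frac_genetic"].to_numpy(), ok["frac_presence"].to_numpy()]
    )
    glm_bias = poisson_glm(
        ok["abs_bias_pct"].to_numpy(), X, names=["intercept", "frac_genetic", "frac_presence"]
    )
    glm_cv = poisson_glm(
        ok["cv_pct"].to_numpy(), X, names=["intercept", "frac_genetic", "frac_presence"]
    )
    return Experiment2Result(outcomes=df, glm_bias=glm_bias, glm_cv=glm_cv)


def summarize_bias_cv(outcomes: pd.DataFrame, by: str | None = None) -> pd.DataFrame:
    """Mean relative bias, % of estimates with |bias|<20%, mean CV and
    % of estimates with CV<10%, over converged replicates."""
    df = outcomes[outcomes["converged"]] if "converged" in outcomes else outcomes
    if df.empty:
        raise ValueError("no converged outcomes to summarise")

    def agg(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "n": len(g),
                "mean_bias": g["relative_bias"].mean(),
                "frac_bias_lt_20": float((g["relative_bias"].abs() < 0.20).mean()),
                "mean_cv": g["cv"].mean(),
                "frac_cv_lt_10": float((g["cv"] < 0.10).mean()),
            }
        )

    if by is None:
        return agg(df).to_frame().T
    return df.groupby(by).apply(agg, include_groups=False)
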