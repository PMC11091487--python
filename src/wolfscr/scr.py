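"""Spatially explicit capture-recapture (SCR) with data augmentation.

Individuals carry a latent activity centre on the cell lattice (the centre
of each 10 x 10 km cell).  Detection at a detector placed at a cell
centroid decays with distance as a half-normal,

    p(d) = p0 * exp(-d^2 / (2 sigma^2)),

and each detector aggregates 100 sub-detectors on an interior 1-km grid:
the count of an individual at a detector is modelled as
Binomial(100, p_bar), with p_bar the half-normal probability averaged over
the 100 sub-detector distances (a partially aggregated binomial observation
process; the exact per-sub-detector Poisson-binomial is available behind
``aggregation="poisson-binomial"``).

Baseline detection p0 is logit-linear in standardised log(1+effort) (and
optionally snow, sex, and per-area random intercepts) with a two-class
finite mixture for residual individual heterogeneity.  Expected density is
an inhomogeneous point process, log-linear in cell covariates with an
optional CAR random field; activity centres are placed over cells with
probability proportional to the local intensity.  Abundance is estimated by
data augmentation: the observed individuals are topped up to
``M_aug = 11 * n_detected`` pseudo-individuals with inclusion indicators
z_i ~ Bernoulli(psi_aug), and N = sum(z).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit, logsumexp

from . import _kernels
from .grid import Adjacency, Grid, SUB_OFFSETS_1D, build_adjacency
from .mcmc import AdaptiveFieldSteps, AdaptiveRW, InitError, MCMCConfig, PosteriorResult
from .occupancy import COEF_PRIOR_SD, PHI_BOUND, SOFT_SUM_SD, _standardize

K_SUB_DEFAULT = 100
AUGMENTATION_FACTOR = 11  # M_aug = 11 x n_detected (adds 10x the observed)

DEFAULT_DENSITY_COVARIATES = ("altitude", "forest", "human_density")


def _lse(a: np.ndarray, axis: int = 0) -> np.ndarray:
    """Fast log-sum-exp without scipy's dispatch overhead."""
    m = np.max(a, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    out = np.log(np.sum(np.exp(a - m), axis=axis))
    return out + np.squeeze(m, axis=axis)


# ---------------------------------------------------------------------------
# detection function


def halfnormal_p(p0, d, sigma):
    """Half-normal detection probability p0 * exp(-d^2 / (2 sigma^2))."""
    p0 = np.asarray(p0, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    if np.any((p0 < 0) | (p0 > 1)):
        raise ValueError("p0 must be in [0, 1]")
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    return p0 * np.exp(-(d**2) / (2.0 * np.asarray(sigma, float) ** 2))


def poisson_binomial_pmf(probs: np.ndarray, k: int) -> float:
    """P(sum of independent Bernoulli(probs) == k), by convolution."""
    pmf = np.zeros(len(probs) + 1)
    pmf[0] = 1.0
    for p in probs:
        pmf[1:] = pmf[1:] * (1 - p) + pmf[:-1] * p
        pmf[0] *= 1 - p
    return float(pmf[k])


def density_intensity(grid: Grid, mu0: float, coefs: dict | None = None, eps=None):
    """Per-cell expected abundance lambda_x = exp(mu0 + X mu + eps) and its
    total E[N] = sum(lambda).  Covariates are z-scored within the grid."""
    eta = np.full(grid.n_cells, float(mu0))
    for name, c in (coefs or {}).items():
        eta += c * _standardize(grid.covariate(name))
    if eps is not None:
        eps = np.asarray(eps, dtype=float)
        if eps.shape != (grid.n_cells,):
            raise ValueError("eps must have one value per cell")
        eta += eps
    lam = np.exp(eta)
    return lam, float(lam.sum())


class DetectorGeometry:
    """Sub-detector-averaged half-normal kernels between every cell and
    detector.  Exploits the lattice structure: the average of the 2-D
    half-normal over the 10x10 sub-grid factorises into per-axis averages
    over a small set of unique centroid displacements."""

    def __init__(self, grid: Grid, detectors: pd.DataFrame, K_sub: int = K_SUB_DEFAULT):
        self.grid = grid
        self.detectors = detectors.reset_index(drop=True)
        self.K_sub = K_sub
        det_cells = self.detectors["cell_id"].to_numpy(dtype=int)
        self.det_cells = det_cells
        dc = grid.col[det_cells]
        dr = grid.row[det_cells]
        self._ix = (grid.col[:, None] - dc[None, :] + grid.n_cols - 1).astype(int)
        self._iy = (grid.row[:, None] - dr[None, :] + grid.n_rows - 1).astype(int)
        self._ux = (np.arange(2 * grid.n_cols - 1) - (grid.n_cols - 1)) * 10.0
        self._uy = (np.arange(2 * grid.n_rows - 1) - (grid.n_rows - 1)) * 10.0

    @property
    def n_detectors(self) -> int:
        return len(self.detectors)

    def _axis_mean(self, u: np.ndarray, sigma: float) -> np.ndarray:
        z = (u[:, None] + SUB_OFFSETS_1D[None, :]) / sigma
        return np.exp(-0.5 * z**2).mean(axis=1)

    def mean_halfnormal(self, sigma) -> np.ndarray:
        """(n_cells, n_detectors) mean of exp(-d^2/(2 sigma^2)) over each
        detector's 100 sub-detectors; ``sigma`` may be scalar or per-cell."""
        if np.ndim(sigma) == 0:
            gx = self._axis_mean(self._ux, float(sigma))
            gy = self._axis_mean(self._uy, float(sigma))
            return gx[self._ix] * gy[self._iy]
        sigma = np.asarray(sigma, dtype=float)
        H = np.empty((self.grid.n_cells, self.n_detectors))
        for s in np.unique(sigma):
            rows = np.flatnonzero(sigma == s)
            gx = self._axis_mean(self._ux, float(s))
            gy = self._axis_mean(self._uy, float(s))
            H[rows] = gx[self._ix[rows]] * gy[self._iy[rows]]
        return H

    def sub_distances(self, cell: int, det: int) -> np.ndarray:
        """(100,) distances from a cell centroid to one detector's sub-detectors."""
        ox, oy = np.meshgrid(SUB_OFFSETS_1D, SUB_OFFSETS_1D)
        dx = self.grid.x[cell] - (self.grid.x[self.det_cells[det]] + ox.ravel())
        dy = self.grid.y[cell] - (self.grid.y[self.det_cells[det]] + oy.ravel())
        return np.hypot(dx, dy)


# ---------------------------------------------------------------------------
# data / parameters


@dataclass
class SCRData:
    """Individual x detector genetic detection counts."""

    y: np.ndarray                    # (n_ind, n_detectors) ints in [0, K_sub]
    detectors: pd.DataFrame          # detector_id,cell_id,x_km,y_km,area_id
    sex: np.ndarray | None = None    # per-individual {"F","M","U"}
    effort_cell: np.ndarray | None = None  # km walked, per detector
    snow: np.ndarray | None = None         # per detector
    K_sub: int = K_SUB_DEFAULT

    @property
    def n_individuals(self) -> int:
        return self.y.shape[0]

    @property
    def n_detectors(self) -> int:
        return self.y.shape[1]

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        if self.sex is None:
            self.sex = np.full(self.n_individuals, "U")
        self.sex = np.asarray(self.sex)
        if self.effort_cell is None:
            self.effort_cell = np.zeros(self.n_detectors)
        self.effort_cell = np.asarray(self.effort_cell, dtype=float)
        if self.snow is None:
            self.snow = np.zeros(self.n_detectors)
        self.snow = np.asarray(self.snow, dtype=float)

    def validate(self) -> None:
        if np.any(self.y < 0) or np.any(self.y > self.K_sub):
            raise ValueError(f"counts must lie in [0, {self.K_sub}]")
        if self.n_individuals and not (self.y.sum(axis=1) > 0).all():
            raise ValueError("every listed individual must have >= 1 detection")
        if self.y.shape[1] != len(self.detectors):
            raise ValueError("y columns must match the detector table")


@dataclass
class SCRParams:
    """Parameters and latent states of the SCR model.

    Detection: logit p0 = p0_intercept + p0_effort * effort_std(detector)
    + p0_snow * snow + p0_sex * male + area_effect + mix_delta * high_class.
    Spatial scale: log sigma = log_sigma0 + sigma_ungulate * ungulates_std.
    Density: log lambda = mu0 + X mu + dens_eps.
    """

    p0_intercept: float
    log_sigma0: float
    mu0: float = 0.0
    mu: dict = field(default_factory=dict)
    p0_effort: float = 0.0
    p0_snow: float = 0.0
    p0_sex: float = 0.0
    area_effects: np.ndarray | None = None
    mix_delta: float = 0.0
    mix_pi: float = 0.0
    sigma_ungulate: float = 0.0
    dens_eps: np.ndarray | None = None
    psi_aug: float = 0.5
    M_aug: int | None = None
    z: np.ndarray | None = None
    s: np.ndarray | None = None
    mix_class_ind: np.ndarray | None = None
    sex_latent: np.ndarray | None = None


@dataclass
class AbundanceSummary:
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    cv: float
    n_draws: int

    def as_dict(self) -> dict:
        return {
            "N_mean": self.mean,
            "N_sd": self.sd,
            "N_ci_low": self.ci_low,
            "N_ci_high": self.ci_high,
            "cv": self.cv,
        }


def abundance_posterior(draws: np.ndarray) -> AbundanceSummary:
    """Summaries of posterior N.  ``draws`` is either a vector of N values
    or a (n_draws, M) matrix of inclusion indicators (N = row sums)."""
    arr = np.asarray(draws)
    if arr.size == 0:
        raise ValueError("empty posterior draws")
    N = arr.sum(axis=1) if arr.ndim == 2 else arr.astype(float)
    mean = float(N.mean())
    sd = float(N.std(ddof=1)) if N.size > 1 else 0.0
    lo, hi = np.percentile(N, [2.5, 97.5])
    return AbundanceSummary(
        mean=mean, sd=sd, ci_low=float(lo), ci_high=float(hi),
        cv=sd / mean if mean > 0 else np.nan, n_draws=int(N.size),
    )


# ---------------------------------------------------------------------------
# likelihood (reference implementation; the sampler uses cached log-space
# versions of the same quantities)


def _p0_logit_matrix(model: "SCRModel", params: SCRParams) -> np.ndarray:
    """(n_components, n_detectors) logit baselines per mixture component."""
    eta = params.p0_intercept + params.p0_effort * model.effort_std
    eta = eta + params.p0_snow * model.data.snow
    if params.area_effects is not None:
        eta = eta + np.asarray(params.area_effects)[model.area_idx]
    comp = model.component_table(params)
    return eta[None, :] + comp["offset"][:, None]


def scr_loglik(
    data: SCRData,
    params: SCRParams,
    grid: Grid,
    geometry: DetectorGeometry | None = None,
    model: "SCRModel | None" = None,
    marginalize: bool = True,
    z_occ: np.ndarray | None = None,
    aggregation: str = "binomial",
) -> float:
    """SCR log-likelihood including the augmented all-zero individuals.

    Marginal mode sums each individual's contribution over its inclusion
    state z_i, activity-centre cell and mixture component; conditional mode
    evaluates at the provided latent states (including their priors, so
    that exponentiating and summing over latent configurations recovers the
    marginal likelihood exactly).
    """
    model = model or SCRModel(data, grid, geometry=geometry, aggregation=aggregation)
    return model.loglik(params, marginalize=marginalize, z_occ=z_occ)


# ---------------------------------------------------------------------------
# model


class SCRModel:
    """SCR model bound to one dataset, grid and detector network."""

    def __init__(
        self,
        data: SCRData,
        grid: Grid,
        geometry: DetectorGeometry | None = None,
        adjacency: Adjacency | None = None,
        density_covariates=DEFAULT_DENSITY_COVARIATES,
        effort_on_p0: bool = True,
        snow_on_p0: bool = False,
        sex_effect: bool = False,
        area_effects: bool = False,
        density_car: bool = True,
        sigma_ungulate: bool = False,
        mixture: bool = True,
        M_aug: int | None = None,
        aggregation: str = "binomial",
    ):
        data.validate()
        self.data = data
        self.grid = grid
        self.geom = geometry or DetectorGeometry(grid, data.detectors, data.K_sub)
        self.adj = adjacency or build_adjacency(grid)
        self.density_covariates = tuple(density_covariates)
        self.effort_on_p0 = effort_on_p0
        self.snow_on_p0 = snow_on_p0
        self.sex_effect = sex_effect
        self.use_area_effects = area_effects
        self.density_car = density_car
        self.use_sigma_ungulate = sigma_ungulate
        self.mixture = mixture
        self.aggregation = aggregation
        self.M_aug = M_aug if M_aug is not None else AUGMENTATION_FACTOR * data.n_individuals
        if self.M_aug < data.n_individuals:
            raise ValueError("M_aug must cover all detected individuals")

        le = np.log1p(data.effort_cell)
        self.effort_std = _standardize(le) if effort_on_p0 else np.zeros_like(le)
        self.area_idx = data.detectors["area_id"].to_numpy(dtype=int)
        self.n_areas = int(self.area_idx.max()) + 1 if len(self.area_idx) else 0
        self.X_dens = (
            np.column_stack([_standardize(grid.covariate(c)) for c in self.density_covariates])
            if self.density_covariates
            else np.zeros((grid.n_cells, 0))
        )
        self.ungulates_std = _standardize(grid.covariate("n_ungulate_species"))
        self._prep_car()

    def _prep_car(self):
        self._deg = self.adj.D.copy()
        self._indptr, self._indices = self.adj.neighbor_lists()
        mask = self._deg > 0
        self._car_mask = mask
        if mask.any():
            ds = self._deg[mask]
            Ws = self.adj.W[np.ix_(mask, mask)].astype(float)
            self._car_eigs = np.linalg.eigvalsh(Ws / np.sqrt(np.outer(ds, ds)))
            self._car_logdet_D = float(np.sum(np.log(ds)))
        else:
            self._car_eigs = np.empty(0)
            self._car_logdet_D = 0.0

    def car_logpdf(self, eps, sigma, phi) -> float:
        if sigma <= 0 or abs(phi) >= 1:
            return -np.inf
        n = len(eps)
        quad = float(eps @ (self._deg * eps) - phi * (eps @ (self.adj.W @ eps)))
        iso = ~self._car_mask
        if iso.any():
            quad += float(np.sum(eps[iso] ** 2))
        logdet = self._car_logdet_D + float(np.sum(np.log1p(-phi * self._car_eigs)))
        return 0.5 * (logdet - 2 * n * np.log(sigma)) - 0.5 * quad / sigma**2

    # -- components (mixture class x latent sex) -------------------------

    def component_table(self, params: SCRParams) -> dict:
        """Mixture components: detection class (low/high) x sex when the sex
        effect is active.  Returns logit offsets and per-individual log
        prior weights (detected individuals with known sex get restricted
        weights; augmented individuals are sex-Bernoulli(0.5))."""
        deltas = [0.0, params.mix_delta] if self.mixture else [0.0]
        pis = (
            [1 - params.mix_pi, params.mix_pi] if self.mixture else [1.0]
        )
        if self.sex_effect:
            offsets, classes, sexes = [], [], []
            for k, dlt in enumerate(deltas):
                for sx in (0, 1):
                    offsets.append(dlt + params.p0_sex * sx)
                    classes.append(k)
                    sexes.append(sx)
            offsets = np.array(offsets)
            comp_pi = np.array([pis[k] * 0.5 for k in classes])
            sexes = np.array(sexes)
        else:
            offsets = np.array(deltas)
            comp_pi = np.array(pis)
            classes = list(range(len(deltas)))
            sexes = None
        with np.errstate(divide="ignore"):
            logw = np.log(comp_pi)
        return {"offset": offsets, "log_weight": logw, "classes": np.array(classes), "sex": sexes}

    def _individual_log_weights(self, comp: dict) -> np.ndarray:
        """(n_detected, C) log prior weights per detected individual."""
        n = self.data.n_individuals
        C = len(comp["offset"])
        lw = np.tile(comp["log_weight"], (n, 1))
        if self.sex_effect and comp["sex"] is not None:
            for i, sx in enumerate(self.data.sex):
                if sx == "M":
                    lw[i, comp["sex"] == 0] = -np.inf
                    lw[i, comp["sex"] == 1] += np.log(2.0)  # renormalise 0.5 split
                elif sx == "F":
                    lw[i, comp["sex"] == 1] = -np.inf
                    lw[i, comp["sex"] == 0] += np.log(2.0)
        return lw

    def sigma_cells(self, params: SCRParams):
        if self.use_sigma_ungulate and params.sigma_ungulate != 0.0:
            return np.exp(params.log_sigma0 + params.sigma_ungulate * self.ungulates_std)
        return float(np.exp(params.log_sigma0))

    def intensity(self, params: SCRParams, z_occ=None) -> tuple:
        """Unnormalised per-cell intensity (possibly gated) and its total."""
        eta = params.mu0 + self.X_dens @ np.array(
            [params.mu.get(c, 0.0) for c in self.density_covariates]
        )
        if params.dens_eps is not None:
            eta = eta + params.dens_eps
        lam = np.exp(eta)
        if z_occ is not None:
            lam = lam * (np.asarray(z_occ) > 0)
        return lam, float(lam.sum())

    # -- reference likelihood ---------------------------------------------

    def _comp_cell_logliks(self, params: SCRParams, y_row: np.ndarray) -> np.ndarray:
        """(C, n_cells) log P(y_row | s = c, component) over all cells."""
        K = self.data.K_sub
        H = self.geom.mean_halfnormal(self.sigma_cells(params))  # (n_cells, n_det)
        eta = _p0_logit_matrix(self, params)  # (C, n_det)
        p = expit(eta)[:, None, :] * H[None, :, :]  # (C, n_cells, n_det)
        p = np.clip(p, 1e-300, 1 - 1e-12)
        if self.aggregation == "poisson-binomial":
            C, n_cells = p.shape[0], p.shape[1]
            out = np.zeros((C, n_cells))
            p0 = expit(eta)
            sig = self.sigma_cells(params)
            for ci in range(C):
                for c in range(n_cells):
                    ll = 0.0
                    for d in range(self.data.n_detectors):
                        s = sig if np.ndim(sig) == 0 else sig[c]
                        probs = halfnormal_p(p0[ci, d], self.geom.sub_distances(c, d), s)
                        ll += np.log(poisson_binomial_pmf(probs, int(y_row[d])))
                    out[ci, c] = ll
            return out
        logbin = (
            gammaln(K + 1) - gammaln(y_row + 1) - gammaln(K - y_row + 1)
        )[None, None, :]
        ll = logbin + y_row * np.log(p) + (K - y_row) * np.log1p(-p)
        return ll.sum(axis=2)

    def loglik(
        self,
        params: SCRParams,
        marginalize: bool = True,
        z_occ: np.ndarray | None = None,
    ) -> float:
        lam, T = self.intensity(params, z_occ=z_occ)
        if T <= 0:
            return -np.inf
        with np.errstate(divide="ignore"):
            logw_cell = np.log(lam) - np.log(T)
        comp = self.component_table(params)
        lw_det = self._individual_log_weights(comp)
        M = params.M_aug if params.M_aug is not None else self.M_aug
        n_det = self.data.n_individuals
        psi = params.psi_aug
        zero_row = np.zeros(self.data.n_detectors, dtype=int)
        ll_zero = self._comp_cell_logliks(params, zero_row)  # (C, n_cells)

        if marginalize:
            total = 0.0
            for i in range(n_det):
                ll = self._comp_cell_logliks(params, self.data.y[i])
                m = logsumexp(lw_det[i][:, None] + ll + logw_cell[None, :])
                total += np.logaddexp(
                    np.log(psi) + m, -np.inf  # detected: z=1 with y>0 impossible under z=0
                )
            m0 = logsumexp(comp["log_weight"][:, None] + ll_zero + logw_cell[None, :])
            n_aug = M - n_det
            if n_aug > 0:
                with np.errstate(divide="ignore"):
                    total += n_aug * np.logaddexp(np.log(psi) + m0, np.log1p(-psi))
            return float(total)

        # conditional on z, s (and component via mix_class_ind/sex_latent)
        z = np.asarray(params.z, dtype=int)
        s = np.asarray(params.s, dtype=int)
        comp_idx = self._conditional_components(params, comp)
        total = 0.0
        for i in range(M):
            total += np.log(psi) if z[i] == 1 else np.log1p(-psi)
            y_row = self.data.y[i] if i < n_det else zero_row
            lw = lw_det[i] if i < n_det else comp["log_weight"]
            total += lw[comp_idx[i]]
            total += logw_cell[s[i]]
            if z[i] == 1:
                ll = self._comp_cell_logliks(params, y_row)
                total += ll[comp_idx[i], s[i]]
            elif y_row.any():
                return -np.inf
        return float(total)

    def _conditional_components(self, params: SCRParams, comp: dict) -> np.ndarray:
        M = params.M_aug if params.M_aug is not None else self.M_aug
        mix = (
            np.asarray(params.mix_class_ind, dtype=int)
            if params.mix_class_ind is not None
            else np.zeros(M, dtype=int)
        )
        if not self.sex_effect:
            return mix
        sex = (
            np.asarray(params.sex_latent, dtype=int)
            if params.sex_latent is not None
            else np.zeros(M, dtype=int)
        )
        return mix * 2 + sex

    # -- fitting ----------------------------------------------------------

    def fit(self, config: MCMCConfig | None = None) -> "SCRResults":
        config = config or MCMCConfig()
        seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
        chains = []
        for c in range(config.n_chains):
            rng = np.random.default_rng(seeds[c])
            comp = _SCRComponent(self, rng, config)
            store = {k: [] for k in comp.monitor_names()}
            for it in range(config.n_iter):
                if it == config.burn_in:
                    comp.freeze()
                comp.step()
                if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                    for k, v in comp.monitored().items():
                        store[k].append(v)
            chains.append({k: np.asarray(v) for k, v in store.items()})
        draws = {k: np.stack([ch[k] for ch in chains], axis=0) for k in chains[0]}
        return SCRResults(draws=draws, config=config, model_name="scr", extra={"model": self})


class SCRResults(PosteriorResult):
    """Posterior for an SCR fit; adds abundance summaries."""

    def abundance(self) -> AbundanceSummary:
        return abundance_posterior(self.pooled("N"))

    def summary(self) -> pd.DataFrame:
        return super().summary()


# ---------------------------------------------------------------------------
# sampler component (reused by the integrated model)


class _SCRComponent:
    """Current state + update moves of the SCR part of one chain.

    ``z_occ`` is a shared int8 gate vector (all ones for a stand-alone SCR
    fit); the component maintains the running gated intensity total T and
    the per-cell counts of active activity centres.
    """

    def __init__(self, model: SCRModel, rng, config: MCMCConfig, z_occ=None):
        self.m = model
        self.rng = rng
        n_cells = model.grid.n_cells
        self.z_occ = (
            z_occ if z_occ is not None else np.ones(n_cells, dtype=np.int8)
        )
        nd = model.data.n_individuals
        M = model.M_aug
        self.nd, self.M = nd, M

        # detection state
        tot = model.data.y.sum()
        denom = max(1, nd) * max(1, model.data.n_detectors) * model.data.K_sub
        self.a0 = float(logit(np.clip(tot / denom, 1e-5, 0.2)))
        self.b_eff = 0.0
        self.b_snow = 0.0
        self.b_sex = 0.0
        self.area_eff = np.zeros(model.n_areas) if model.use_area_effects else None
        self.log_tau = 0.0
        self.log_delta = 0.5
        self.pi_l = logit(0.2)
        self.log_sigma = np.log(3.0)
        self.sig_ung = 0.0
        # density state
        self.mu = np.zeros(model.X_dens.shape[1])
        self.dens_eps = np.zeros(n_cells)
        self.log_sig_d = np.log(0.5)
        self.u_phi_d = np.arctanh(0.5 / PHI_BOUND)
        # latent state
        self.z = np.zeros(M, dtype=np.int8)
        self.z[:nd] = 1
        self.psi_aug = float(np.clip(2.0 * nd / max(M, 1), 0.1, 0.9))
        self.z[nd:] = (rng.random(M - nd) < self.psi_aug).astype(np.int8)
        self.s = np.zeros(M, dtype=np.int64)
        best_det = np.argmax(model.data.y, axis=1) if nd else np.empty(0, dtype=int)
        self.s[:nd] = model.geom.det_cells[best_det]
        # detected individuals' cells must be occupied at initialisation
        self.z_occ[self.s[:nd]] = 1
        occ_cells = np.flatnonzero(self.z_occ > 0)
        if occ_cells.size == 0:
            # no captures and no initially occupied cells: start fully open
            self.z_occ[:] = 1
            occ_cells = np.arange(n_cells)
        self.s[nd:] = rng.choice(occ_cells, size=M - nd)

        # per-detected-individual sparse count structure
        self.nz_det = [np.flatnonzero(model.data.y[i]) for i in range(nd)]
        self.nz_y = [model.data.y[i, idx].astype(float) for i, idx in enumerate(self.nz_det)]

        ar = config.adapt_rate
        det_dim = (
            2 + int(model.mixture) + int(model.effort_on_p0)
            + int(model.snow_on_p0) + int(model.sex_effect)
        )
        self.p_det = AdaptiveRW(dim=det_dim, step=0.1, adapt_rate=ar)
        self.p_sig = AdaptiveRW(
            dim=2 if model.use_sigma_ungulate else 1, step=0.05, adapt_rate=ar
        )
        self.p_mu = (
            AdaptiveRW(dim=len(self.mu), step=0.1, adapt_rate=ar) if len(self.mu) else None
        )
        self.p_area = (
            AdaptiveRW(dim=model.n_areas + 1, step=0.1, adapt_rate=ar)
            if model.use_area_effects
            else None
        )
        self.p_deps = AdaptiveFieldSteps(n_cells, step=0.5, adapt_rate=ar)
        self.p_card = AdaptiveRW(dim=2, step=0.2, adapt_rate=ar)
        self._props = [p for p in (self.p_det, self.p_sig, self.p_mu, self.p_area, self.p_card) if p]

        self.refresh_detection()
        self.refresh_density()
        self.refresh_counts()
        if not np.isfinite(self.obs_loglik()):
            raise InitError("scr component: non-finite initial observation likelihood")

    # -- caches -----------------------------------------------------------

    def params(self) -> SCRParams:
        return SCRParams(
            p0_intercept=self.a0,
            log_sigma0=self.log_sigma,
            mu0=0.0,
            mu={c: m for c, m in zip(self.m.density_covariates, self.mu)},
            p0_effort=self.b_eff,
            p0_snow=self.b_snow,
            p0_sex=self.b_sex,
            area_effects=self.area_eff,
            mix_delta=float(np.exp(self.log_delta)),
            mix_pi=float(expit(self.pi_l)) if self.m.mixture else 0.0,
            sigma_ungulate=self.sig_ung,
            dens_eps=self.dens_eps if self.m.density_car else None,
            psi_aug=self.psi_aug,
            M_aug=self.M,
            z=self.z,
            s=self.s,
        )

    _SCR_CACHE = ("H", "comp", "logq", "logB", "lw_det", "logm0", "_obs_ll")

    def refresh_detection(self):
        """Recompute H, per-component detection fields and zero-count logliks."""
        self._refresh_H()
        self._refresh_p()

    def _refresh_H(self):
        self.H = self.m.geom.mean_halfnormal(self.m.sigma_cells(self.params()))

    def _refresh_p(self):
        m = self.m
        params = self.params()
        comp = m.component_table(params)
        self.comp = comp
        eta_det = _p0_logit_matrix(m, params)  # (C, n_det)
        p = expit(eta_det)[:, None, :] * self.H[None, :, :]
        p = np.clip(p, 1e-300, 1 - 1e-9)
        log1mp = np.log1p(-p)
        self.logq = m.data.K_sub * log1mp.sum(axis=2)        # (C, n_cells)
        self.logB = np.log(p) - log1mp                       # (C, n_cells, n_det)
        self.lw_det = m._individual_log_weights(comp)        # (nd, C)
        # marginal all-zero loglik per cell
        self.logm0 = _lse(comp["log_weight"][:, None] + self.logq, axis=0)
        self._obs_ll = None

    def refresh_density(self):
        eta = self.m.X_dens @ self.mu
        if self.m.density_car:
            eta = eta + self.dens_eps
        self.logw = eta
        lam = np.exp(eta) * (self.z_occ > 0)
        self.lam_all = np.exp(eta)
        self.T = float(lam.sum())

    def refresh_counts(self):
        self.counts = np.bincount(
            self.s[self.z == 1], minlength=self.m.grid.n_cells
        ).astype(np.int64)
        self.n_active = int(self.z.sum())

    # -- likelihood pieces -------------------------------------------------

    def _logm_detected(self, i: int) -> np.ndarray:
        """(n_cells,) marginal (over components) loglik of individual i."""
        ll = self.logq + np.einsum(
            "d,cnd->cn", self.nz_y[i], self.logB[:, :, self.nz_det[i]]
        ) if len(self.nz_det[i]) else self.logq
        return _lse(self.lw_det[i][:, None] + ll, axis=0)

    def _logm_detected_at(self, i: int, c: int) -> float:
        ll = self.logq[:, c].copy()
        nz = self.nz_det[i]
        if len(nz):
            ll += self.logB[:, c, nz] @ self.nz_y[i]
        return float(_lse(self.lw_det[i] + ll, axis=0))

    def obs_loglik(self) -> float:
        """Observation loglik of all active individuals at current (s, z),
        marginal over mixture components (inactive individuals contribute 0)."""
        if self._obs_ll is not None:
            return self._obs_ll
        total = 0.0
        for i in range(self.nd):
            total += self._logm_detected_at(i, int(self.s[i]))
        aug_active = self.s[self.nd :][self.z[self.nd :] == 1]
        if aug_active.size:
            cnt = np.bincount(aug_active, minlength=self.m.grid.n_cells)
            total += float(cnt @ self.logm0)
        self._obs_ll = float(total)
        return self._obs_ll

    # -- moves ------------------------------------------------------------

    def update_z_aug(self):
        if self.M == self.nd:
            return
        lo = logit(self.psi_aug) + self.logm0[self.s[self.nd :]]
        self.z[self.nd :] = (self.rng.random(self.M - self.nd) < expit(lo)).astype(np.int8)
        self.refresh_counts()
        self._obs_ll = None

    def update_psi_aug(self):
        n1 = int(self.z.sum())
        self.psi_aug = float(self.rng.beta(1 + n1, 1 + self.M - n1))

    def _gated_logw(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(self.z_occ > 0, self.logw, -np.inf)

    def update_s(self):
        glw = self._gated_logw()
        # detected individuals: cell posterior ~ gated intensity x marginal lik
        for i in range(self.nd):
            lp = glw + self._logm_detected(i)
            g = lp + self.rng.gumbel(size=lp.shape)
            self.s[i] = int(np.argmax(g))
        # augmented: active from lam*m0, inactive from lam
        n_aug = self.M - self.nd
        if n_aug:
            act = self.z[self.nd :] == 1
            for mask, extra in ((act, self.logm0), (~act, None)):
                k = int(mask.sum())
                if k == 0:
                    continue
                lp = glw + extra if extra is not None else glw
                w = np.exp(lp - _lse(lp))
                w = w / w.sum()
                cells = self.rng.choice(self.m.grid.n_cells, size=k, p=w)
                idx = self.nd + np.flatnonzero(mask)
                self.s[idx] = cells
        self.refresh_counts()
        self._obs_ll = None

    def update_density(self):
        m = self.m
        if self.p_mu is not None:
            def logpost(mu):
                eta = m.X_dens @ mu
                if m.density_car:
                    eta = eta + self.dens_eps
                lam = np.exp(eta) * (self.z_occ > 0)
                T = lam.sum()
                if T <= 0:
                    return -np.inf
                ll = float(self.counts @ eta) - self.n_active * np.log(T)
                return ll - 0.5 * float(mu @ mu) / COEF_PRIOR_SD**2

            prop = self.p_mu.propose(self.mu, self.rng)
            acc = np.log(self.rng.random()) < logpost(prop) - logpost(self.mu)
            if acc:
                self.mu = prop
                self.refresh_density()
            self.p_mu.update(acc)
        if m.density_car:
            n = m.grid.n_cells
            accv = np.zeros(n, dtype=np.int8)
            self.T = _kernels.dens_field_sweep(
                self.dens_eps, m.X_dens @ self.mu, self.z_occ, self.counts,
                self.n_active, self.T,
                m._indptr, m._indices, m._deg,
                float(np.exp(2 * self.log_sig_d)), PHI_BOUND * np.tanh(self.u_phi_d),
                SOFT_SUM_SD**2,
                self.p_deps.steps, self.rng.standard_normal(n), self.rng.random(n), accv,
            )
            self.p_deps.update(accv)
            self.refresh_density()

            def logpost_h(ls, up):
                sig = np.exp(ls)
                phi = PHI_BOUND * np.tanh(up)
                lp = m.car_logpdf(self.dens_eps, sig, phi)
                lp += -0.5 * sig**2 + ls
                lp += np.log1p(-np.tanh(up) ** 2)
                return lp

            cur = np.array([self.log_sig_d, self.u_phi_d])
            prop = self.p_card.propose(cur, self.rng)
            acc = np.log(self.rng.random()) < logpost_h(*prop) - logpost_h(*cur)
            if acc:
                self.log_sig_d, self.u_phi_d = float(prop[0]), float(prop[1])
            self.p_card.update(acc)

    def _det_state_vec(self) -> np.ndarray:
        v = [self.a0, self.log_delta]
        if self.m.mixture:
            v.append(self.pi_l)
        if self.m.effort_on_p0:
            v.append(self.b_eff)
        if self.m.snow_on_p0:
            v.append(self.b_snow)
        if self.m.sex_effect:
            v.append(self.b_sex)
        return np.array(v)

    def _set_det_state(self, v):
        self.a0, self.log_delta = float(v[0]), float(v[1])
        k = 2
        if self.m.mixture:
            self.pi_l = float(v[k]); k += 1
        if self.m.effort_on_p0:
            self.b_eff = float(v[k]); k += 1
        if self.m.snow_on_p0:
            self.b_snow = float(v[k]); k += 1
        if self.m.sex_effect:
            self.b_sex = float(v[k]); k += 1

    def _det_prior(self) -> float:
        lp = -0.5 * (self.a0 + 4.0) ** 2 / 2.0**2          # logit p0 ~ N(-4, 2)
        lp += -0.5 * self.log_delta**2 / COEF_PRIOR_SD**2
        for b in (self.b_eff, self.b_snow, self.b_sex):
            lp += -0.5 * b**2 / COEF_PRIOR_SD**2
        u = self.pi_l
        lp += np.log(expit(u)) + np.log(expit(-u))          # uniform mix_pi
        lp += -0.5 * (self.log_sigma - np.log(3.0)) ** 2    # log sigma ~ N(log 3, 1)
        lp += -0.5 * self.sig_ung**2 / COEF_PRIOR_SD**2
        if self.area_eff is not None:
            tau = np.exp(self.log_tau)
            lp += -0.5 * float(self.area_eff @ self.area_eff) / tau**2
            lp += -len(self.area_eff) * np.log(tau)
            lp += -0.5 * tau**2 + self.log_tau              # half-Normal(1) on tau
        return lp

    def _mh_detection_block(self, get, set_, prop, refresh):
        ll0 = self.obs_loglik() + self._det_prior()
        snap = {k: getattr(self, k, None) for k in self._SCR_CACHE}
        cur = get()
        set_(prop.propose(cur, self.rng))
        refresh()
        ll1 = self.obs_loglik() + self._det_prior()
        acc = np.log(self.rng.random()) < ll1 - ll0
        if not acc:
            set_(cur)
            for k, v in snap.items():
                setattr(self, k, v)
        prop.update(acc)

    def update_detection(self):
        self._mh_detection_block(
            self._det_state_vec, self._set_det_state, self.p_det, self._refresh_p
        )
        if self.m.use_sigma_ungulate:
            def get():
                return np.array([self.log_sigma, self.sig_ung])

            def set_(v):
                self.log_sigma, self.sig_ung = float(v[0]), float(v[1])

            self._mh_detection_block(get, set_, self.p_sig, self.refresh_detection)
        else:
            self._mh_detection_block(
                lambda: self.log_sigma,
                lambda v: setattr(self, "log_sigma", float(np.atleast_1d(v)[0])),
                self.p_sig,
                self.refresh_detection,
            )
        if self.area_eff is not None:
            def geta():
                return np.concatenate([self.area_eff, [self.log_tau]])

            def seta(v):
                self.area_eff = np.asarray(v[:-1])
                self.log_tau = float(v[-1])

            self._mh_detection_block(geta, seta, self.p_area, self._refresh_p)

    def step(self):
        self.update_detection()
        self.update_s()
        self.update_z_aug()
        self.update_psi_aug()
        self.update_density()

    def freeze(self):
        for p in self._props:
            p.freeze()
        self.p_deps.freeze()

    # -- monitoring -------------------------------------------------------

    def monitor_names(self):
        names = ["N", "psi_aug", "p0_low", "p0_high", "mix_pi", "sigma", "sigma_dens"]
        if len(self.mu):
            names.append("mu")
        if self.m.effort_on_p0:
            names.append("b_effort")
        return names

    def monitored(self) -> dict:
        out = {
            "N": float(self.z.sum()),
            "psi_aug": self.psi_aug,
            "p0_low": float(expit(self.a0)),
            "p0_high": float(expit(self.a0 + np.exp(self.log_delta))),
            "mix_pi": float(expit(self.pi_l)) if self.m.mixture else 0.0,
            "sigma": float(np.exp(self.log_sigma)),
            "sigma_dens": float(np.exp(self.log_sig_d)) if self.m.density_car else 0.0,
        }
        if len(self.mu):
            out["mu"] = self.mu.copy()
        if self.m.effort_on_p0:
            out["b_effort"] = self.b_eff
        return out
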