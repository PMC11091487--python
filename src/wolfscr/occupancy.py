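"""Single-season, multi-source, multi-event occupancy model with
misidentification.

Two detection data sources are modelled per 10x10 km cell and session:

* transects, coded 0 (no detection), 1 (field wolf, genetically confirmed
  wolf), 2 (field wolf, genetically a dog: a misidentification), 3 (field
  wolf, not analysed: unknown), with state-conditional event probabilities

      unoccupied: [1-P1, 0,               P1*G,       P1*(1-G)]
      occupied:   [1-P2, P2*G*(1-M),      P2*G*M,     P2*(1-G)]

  where P1 is the false-detection (dog-sign) probability, P2 the detection
  probability in occupied cells, G the indicator that the cell's samples
  were genetically analysed, and M the misidentification probability;
* cameras, coded 0/1, with no misidentification: occupied cells are
  detected with probability P3, unoccupied cells never.

Occupancy probability is logit-linear in cell covariates plus a proper CAR
(conditional autoregressive) spatial random effect with precision
(D - phi*W)/sigma^2 on the rook adjacency graph.  Detection probabilities
are logit-linear in standardised log(1+effort) (km walked, or trap-nights)
and optionally snow cover; residual cell heterogeneity in P2 uses a
two-class finite mixture with membership probability theta.

Because grid closure cannot be assumed over a 7-month season, "occupancy"
is interpreted as probability of use of a cell; this changes nothing
computationally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from . import _kernels
from .grid import Adjacency, Grid, build_adjacency
from .mcmc import AdaptiveFieldSteps, AdaptiveRW, InitError, MCMCConfig, PosteriorResult

EVENT_MISSING = -1

DEFAULT_PSI_COVARIATES = ("altitude", "forest", "human_density")

#: weakly informative prior SD for regression coefficients (variance 2.25)
COEF_PRIOR_SD = 1.5
#: soft sum-to-zero constraint SD on sum(eps), to separate CAR field and intercept
SOFT_SUM_SD = 1.0
PHI_BOUND = 0.99


# ---------------------------------------------------------------------------
# event matrices


def transect_event_probs(occupied, P1, P2, G, M):
    """State-conditional probabilities of the four transect events.

    Broadcasts over array inputs; the trailing axis of the result indexes
    the event code {0, 1, 2, 3}.  Rows sum to one by construction.
    """
    P1, P2, G, M = np.broadcast_arrays(
        np.asarray(P1, float), np.asarray(P2, float), np.asarray(G, float), np.asarray(M, float)
    )
    for name, p in (("P1", P1), ("P2", P2), ("M", M)):
        if np.any((p < 0) | (p > 1)):
            raise ValueError(f"{name} out of [0, 1]")
    occ = np.asarray(occupied, bool)
    out = np.empty(P1.shape + (4,), dtype=float)
    out[..., 0] = np.where(occ, 1 - P2, 1 - P1)
    out[..., 1] = np.where(occ, P2 * G * (1 - M), 0.0)
    out[..., 2] = np.where(occ, P2 * G * M, P1 * G)
    out[..., 3] = np.where(occ, P2 * (1 - G), P1 * (1 - G))
    return out


def camera_event_probs(occupied, P3):
    """State-conditional probabilities of the two camera events {0, 1}."""
    P3 = np.asarray(P3, dtype=float)
    if np.any((P3 < 0) | (P3 > 1)):
        raise ValueError("P3 out of [0, 1]")
    occ = np.asarray(occupied, bool)
    out = np.empty(P3.shape + (2,), dtype=float)
    out[..., 0] = np.where(occ, 1 - P3, 1.0)
    out[..., 1] = np.where(occ, P3, 0.0)
    return out


def car_precision(sigma_car: float, phi_car: float, adj: Adjacency) -> np.ndarray:
    """Precision matrix Q = (D - phi*W) / sigma^2 of the proper CAR prior."""
    if sigma_car <= 0:
        raise ValueError("sigma_car must be > 0")
    if abs(phi_car) >= 1:
        raise ValueError("|phi_car| must be < 1 for a proper CAR")
    D = np.diag(adj.D)
    return (D - phi_car * adj.W) / sigma_car**2


def psi_linpred(grid: Grid, beta_psi, eps=None, covariates=None) -> np.ndarray:
    """Per-cell occupancy probability expit(X beta + eps).

    ``beta_psi[0]`` is the intercept; remaining coefficients act on the
    z-scored covariates named in ``covariates``.
    """
    beta = np.atleast_1d(np.asarray(beta_psi, dtype=float))
    if covariates is None:
        covariates = () if beta.size == 1 else DEFAULT_PSI_COVARIATES
    if beta.size != len(covariates) + 1:
        raise ValueError(
            f"beta_psi has {beta.size} coefficients for {len(covariates)} covariates + intercept"
        )
    X = _design_with_intercept(grid, covariates)
    eta = X @ beta
    if eps is not None:
        eps = np.asarray(eps, dtype=float)
        if eps.shape != (grid.n_cells,):
            raise ValueError("eps must have one value per cell")
        eta = eta + eps
    return expit(eta)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _design_with_intercept(grid: Grid, covariates) -> np.ndarray:
    cols = [np.ones(grid.n_cells)]
    for name in covariates:
        cols.append(_standardize(grid.covariate(name)))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# data and parameters


@dataclass
class OccupancyData:
    """Detection histories for one season (−1 codes a missing cell-session)."""

    transect_events: np.ndarray          # (n_cells, n_sessions) int in {-1,0..3}
    effort_transect: np.ndarray          # km walked, same shape
    G: np.ndarray                        # (n_cells,) 0/1 genetic-analysis flag
    snow: np.ndarray | None = None       # (n_cells,) standardized snow cover
    camera_events: np.ndarray | None = None   # (n_cells, n_sessions) in {-1,0,1}
    effort_camera: np.ndarray | None = None   # trap-nights

    @property
    def n_cells(self) -> int:
        return self.transect_events.shape[0]

    @property
    def n_sessions(self) -> int:
        return self.transect_events.shape[1]

    def __post_init__(self):
        self.transect_events = np.asarray(self.transect_events, dtype=int)
        self.effort_transect = np.asarray(self.effort_transect, dtype=float)
        self.G = np.asarray(self.G, dtype=int)
        if self.snow is None:
            self.snow = np.zeros(self.n_cells)
        self.snow = np.asarray(self.snow, dtype=float)
        if self.camera_events is not None:
            self.camera_events = np.asarray(self.camera_events, dtype=int)
            if self.effort_camera is None:
                self.effort_camera = np.ones_like(self.camera_events, dtype=float)

    def validate(self) -> None:
        ev = self.transect_events
        if not np.isin(ev, [-1, 0, 1, 2, 3]).all():
            raise ValueError("transect event codes must be in {-1, 0, 1, 2, 3}")
        if np.any(self.effort_transect < 0):
            raise ValueError("effort must be non-negative")
        genetic_events = np.isin(ev, [1, 2]).any(axis=1)
        if np.any(genetic_events & (self.G == 0)):
            bad = np.flatnonzero(genetic_events & (self.G == 0))
            raise ValueError(
                f"events 1/2 require genetic analysis (G=1); offending cells {bad.tolist()}"
            )
        if np.any((ev >= 0) & (self.effort_transect <= 0)):
            raise ValueError("observed transect events require positive effort")
        if self.camera_events is not None:
            if not np.isin(self.camera_events, [-1, 0, 1]).all():
                raise ValueError("camera event codes must be in {-1, 0, 1}")
            if self.camera_events.shape != ev.shape:
                raise ValueError("camera matrix shape mismatch")


@dataclass
class OccupancyParams:
    """Full parameter/latent state of the occupancy model."""

    beta_psi: np.ndarray
    alpha_p1: np.ndarray                  # logit-linear coefficients of P1
    alpha_p2: np.ndarray                  # logit-linear coefficients of P2 (low class)
    delta_p2: float = 0.0                 # logit offset of the high-detection class
    alpha_p3: np.ndarray | None = None
    M: float = 0.0
    theta: float = 0.5                    # P(high class)
    eps: np.ndarray | None = None
    sigma_car: float = 1.0
    phi_car: float = 0.0
    z_occ: np.ndarray | None = None
    mix_class: np.ndarray | None = None   # per-cell 0=low, 1=high


# ---------------------------------------------------------------------------
# model


class OccupancyModel:
    """Multi-event occupancy model bound to one dataset and grid.

    Parameters
    ----------
    data, grid : the detection histories and the state-space lattice.
    psi_covariates : covariate names entering the occupancy linear predictor.
    effort_effect, snow_effect, session_intercepts : structure of the
        detection linear predictors (standardised log(1+effort) is always
        the effort scale).
    car : include the CAR spatial random effect in logit(psi).
    mixture : two-class finite mixture on P2.
    """

    def __init__(
        self,
        data: OccupancyData,
        grid: Grid,
        adjacency: Adjacency | None = None,
        psi_covariates=DEFAULT_PSI_COVARIATES,
        effort_effect: bool = True,
        snow_effect: bool = False,
        session_intercepts: bool = False,
        car: bool = True,
        mixture: bool = True,
    ):
        data.validate()
        if data.n_cells != grid.n_cells:
            raise ValueError("data and grid disagree on the number of cells")
        self.data = data
        self.grid = grid
        self.adj = adjacency or build_adjacency(grid)
        self.psi_covariates = tuple(psi_covariates)
        self.effort_effect = effort_effect
        self.snow_effect = snow_effect
        self.session_intercepts = session_intercepts
        self.car = car
        self.mixture = mixture

        self.X_psi = _design_with_intercept(grid, self.psi_covariates)
        self._trans_mask = data.transect_events >= 0
        self.effort_std = self._std_effort(data.effort_transect, self._trans_mask)
        if data.camera_events is not None:
            self._cam_mask = data.camera_events >= 0
            self.effort_cam_std = self._std_effort(data.effort_camera, self._cam_mask)
        else:
            self._cam_mask = None
            self.effort_cam_std = None
        self._prep_car()

    @staticmethod
    def _std_effort(effort, mask):
        le = np.log1p(effort)
        obs = le[mask]
        mu = obs.mean() if obs.size else 0.0
        sd = obs.std() if obs.size else 1.0
        return (le - mu) / (sd if sd > 0 else 1.0)

    def _prep_car(self):
        D = self.adj.D.copy()
        self._deg = D
        self._indptr, self._indices = self.adj.neighbor_lists()
        mask = D > 0
        self._car_mask = mask
        if mask.any():
            Ws = self.adj.W[np.ix_(mask, mask)].astype(float)
            ds = D[mask]
            Mm = Ws / np.sqrt(np.outer(ds, ds))
            self._car_eigs = np.linalg.eigvalsh(Mm)
            self._car_logdet_D = float(np.sum(np.log(ds)))
        else:
            self._car_eigs = np.empty(0)
            self._car_logdet_D = 0.0

    # -- detection linear predictors -------------------------------------

    def _det_design(self, which: str) -> np.ndarray:
        """(n, T, q) design tensor for one detection parameter."""
        n, T = self.data.n_cells, self.data.n_sessions
        eff = self.effort_cam_std if which == "p3" else self.effort_std
        cols = [np.ones((n, T))]
        if self.session_intercepts:
            for t in range(1, T):
                d = np.zeros((n, T))
                d[:, t] = 1.0
                cols.append(d)
        if self.effort_effect:
            cols.append(eff)
        if self.snow_effect:
            cols.append(np.repeat(self.data.snow[:, None], T, axis=1))
        return np.stack(cols, axis=2)

    def n_det_coefs(self) -> int:
        return (
            1
            + (self.data.n_sessions - 1) * self.session_intercepts
            + int(self.effort_effect)
            + int(self.snow_effect)
        )

    def detection_linpreds(self, params: OccupancyParams):
        """Per cell-session P1, P2 (low and high class) and P3; NaN where
        the cell-session was not sampled (zero effort = missing)."""
        X1 = self._det_design("p1")
        X2 = self._det_design("p2")
        P1 = expit(X1 @ np.asarray(params.alpha_p1, float))
        eta2 = X2 @ np.asarray(params.alpha_p2, float)
        P2_low = expit(eta2)
        P2_high = expit(eta2 + params.delta_p2)
        P1[~self._trans_mask] = np.nan
        P2_low[~self._trans_mask] = np.nan
        P2_high[~self._trans_mask] = np.nan
        P3 = None
        if self.data.camera_events is not None and params.alpha_p3 is not None:
            P3 = expit(self._det_design("p3") @ np.asarray(params.alpha_p3, float))
            P3[~self._cam_mask] = np.nan
        return P1, P2_low, P2_high, P3

    # -- likelihood -------------------------------------------------------

    def _session_liks(self, params: OccupancyParams):
        """Per-cell likelihood products: (L_un, L_low, L_high)."""
        P1, P2L, P2H, P3 = self.detection_linpreds(params)
        ev = self.data.transect_events
        G = self.data.G[:, None].astype(float)
        evc = np.clip(ev, 0, None)[..., None]

        def gather(probs):
            lik = np.take_along_axis(probs, evc, axis=2)[..., 0]
            lik[~self._trans_mask] = 1.0
            return lik

        lik_un = gather(transect_event_probs(False, np.nan_to_num(P1, nan=0.5), 0.0, G, 0.0))
        lik_L = gather(
            transect_event_probs(True, 0.0, np.nan_to_num(P2L, nan=0.5), G, params.M)
        )
        lik_H = gather(
            transect_event_probs(True, 0.0, np.nan_to_num(P2H, nan=0.5), G, params.M)
        )
        L_un = lik_un.prod(axis=1)
        L_low = lik_L.prod(axis=1)
        L_high = lik_H.prod(axis=1)
        if P3 is not None:
            cev = self.data.camera_events
            cevc = np.clip(cev, 0, None)[..., None]
            probs_occ = camera_event_probs(True, np.nan_to_num(P3, nan=0.5))
            lik_occ = np.take_along_axis(probs_occ, cevc, axis=2)[..., 0]
            lik_occ[~self._cam_mask] = 1.0
            lik_un_c = np.where(cev == 1, 0.0, 1.0)
            lik_un_c[~self._cam_mask] = 1.0
            L_un = L_un * lik_un_c.prod(axis=1)
            cl = lik_occ.prod(axis=1)
            L_low = L_low * cl
            L_high = L_high * cl
        return L_un, L_low, L_high

    def loglik(self, params: OccupancyParams, marginalize: bool = True) -> float:
        """Data log-likelihood given parameters (CAR prior not included).

        With ``marginalize`` the latent occupancy states and mixture
        classes are summed out cell by cell; otherwise the likelihood is
        conditioned on ``params.z_occ`` (and ``params.mix_class`` when
        provided, else the mixture is summed out).
        """
        psi = psi_linpred(self.grid, params.beta_psi, params.eps, self.psi_covariates)
        L_un, L_low, L_high = self._session_liks(params)
        th = params.theta if self.mixture else 0.0
        L_occ_marg = th * L_high + (1 - th) * L_low
        with np.errstate(divide="ignore"):
            if marginalize:
                return float(np.sum(np.log(psi * L_occ_marg + (1 - psi) * L_un)))
            if params.z_occ is None:
                raise ValueError("conditional likelihood needs z_occ")
            z = np.asarray(params.z_occ)
            if params.mix_class is not None:
                mc = np.asarray(params.mix_class)
                L_occ = np.where(mc == 1, L_high, L_low)
                occ_term = np.log(psi) + np.log(L_occ) + np.where(
                    mc == 1, np.log(th), np.log(1 - th)
                )
            else:
                occ_term = np.log(psi) + np.log(L_occ_marg)
            un_term = np.log(1 - psi) + np.log(L_un)
            return float(np.sum(np.where(z == 1, occ_term, un_term)))

    def car_logpdf(self, eps, sigma_car, phi_car) -> float:
        """Log-density of the CAR field (isolated cells: N(0, sigma^2))."""
        if sigma_car <= 0 or abs(phi_car) >= 1:
            return -np.inf
        n = len(eps)
        quad = float(eps @ (self._deg * eps) - phi_car * (eps @ (self.adj.W @ eps)))
        iso = ~self._car_mask
        if iso.any():
            quad += float(np.sum(eps[iso] ** 2))  # deg 0: unit precision scale
        logdet = self._car_logdet_D + float(np.sum(np.log1p(-phi_car * self._car_eigs)))
        return 0.5 * (logdet - 2 * n * np.log(sigma_car)) - 0.5 * quad / sigma_car**2

    # -- fitting ----------------------------------------------------------

    def fit(self, config: MCMCConfig | None = None) -> "OccupancyResults":
        config = config or MCMCConfig()
        seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
        chains = []
        for c in range(config.n_chains):
            rng = np.random.default_rng(seeds[c])
            comp = _OccComponent(self, rng, config)
            store = {k: [] for k in comp.monitor_names()}
            for it in range(config.n_iter):
                if it == config.burn_in:
                    comp.freeze()
                comp.step()
                if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                    for k, v in comp.monitored().items():
                        store[k].append(v)
            chains.append({k: np.asarray(v) for k, v in store.items()})
        draws = {
            k: np.stack([ch[k] for ch in chains], axis=0) for k in chains[0]
        }
        return OccupancyResults(draws=draws, config=config, model_name="occupancy",
                                extra={"model": self})


class OccupancyResults(PosteriorResult):
    """Posterior for the occupancy model; adds occupied-fraction summaries."""

    def occupied_fraction(self) -> dict:
        f = self.pooled("frac_occ")
        return {
            "mean": float(f.mean()),
            "q2.5": float(np.percentile(f, 2.5)),
            "q97.5": float(np.percentile(f, 97.5)),
        }


# ---------------------------------------------------------------------------
# sampler component (shared with the integrated model)


class _OccComponent:
    """Current state + update moves of the occupancy component of a chain.

    Per-cell likelihood products under each state/class are cached and only
    the pieces a proposal actually touches are recomputed (e.g. a theta move
    reweights the stored class products without re-evaluating them)."""

    def __init__(self, model: OccupancyModel, rng, config: MCMCConfig):
        self.m = model
        self.rng = rng
        d = model.data
        ev = d.transect_events
        seen = np.isin(ev, [1, 3]).any(axis=1)
        if d.camera_events is not None:
            seen |= (d.camera_events == 1).any(axis=1)
        self.z = seen.astype(np.int8)
        # fixed event-indicator masks for fast likelihood evaluation
        self._m0 = (ev == 0).astype(float)
        self._m1 = (ev == 1).astype(float)
        self._m2 = (ev == 2).astype(float)
        self._m3 = (ev == 3).astype(float)
        self._mmiss = (ev == -1).astype(float)
        self._G2 = d.G[:, None].astype(float)
        self._X_trans = model._det_design("p1")
        if d.camera_events is not None:
            cev = d.camera_events
            self._X_cam = model._det_design("p3")
            self._cam_m0 = (cev == 0).astype(float)
            self._cam_m1 = (cev == 1).astype(float)
            self._cam_miss = (cev == -1).astype(float)
            # unoccupied cells: camera detections impossible
            self._cam_un_prod = np.where((cev == 1).any(axis=1), 0.0, 1.0)
        else:
            self._X_cam = None
        p_occ = float(np.clip(self.z.mean(), 0.05, 0.95))
        k = model.X_psi.shape[1]
        self.beta = np.zeros(k)
        self.beta[0] = logit(p_occ)
        q = model.n_det_coefs()
        self.a1 = np.zeros(q)
        self.a1[0] = logit(0.1)
        self.a2 = np.zeros(q)
        self.a2[0] = logit(0.3)
        self.log_delta = 0.0
        self.a3 = None
        if d.camera_events is not None:
            self.a3 = np.zeros(q)
            self.a3[0] = logit(0.2)
        self.theta_l = 0.0   # logit theta
        self.M_l = logit(0.05)
        self.eps = np.zeros(model.grid.n_cells)
        self.log_sig = np.log(0.5)
        self.u_phi = np.arctanh(0.5 / PHI_BOUND)
        self.car = model.car
        self.mixture = model.mixture

        ar = config.adapt_rate
        self.p_beta = AdaptiveRW(dim=k, step=0.1, adapt_rate=ar)
        self.p_a1 = AdaptiveRW(dim=q, step=0.1, adapt_rate=ar)
        self.p_a2 = AdaptiveRW(dim=q + 1, step=0.1, adapt_rate=ar)
        self.p_a3 = AdaptiveRW(dim=q, step=0.1, adapt_rate=ar) if self.a3 is not None else None
        self.p_theta = AdaptiveRW(step=0.3, adapt_rate=ar)
        self.p_M = AdaptiveRW(step=0.3, adapt_rate=ar)
        self.p_car = AdaptiveRW(dim=2, step=0.2, adapt_rate=ar)
        self.p_eps = AdaptiveFieldSteps(model.grid.n_cells, step=0.5, adapt_rate=ar)
        self._props = [self.p_beta, self.p_a1, self.p_a2, self.p_theta, self.p_M, self.p_car]
        if self.p_a3 is not None:
            self._props.append(self.p_a3)

        self.refresh_liks()
        if not np.isfinite(self.det_loglik_given_z()):
            raise InitError("occupancy component: non-finite initial detection likelihood")

    # -- caches -----------------------------------------------------------

    def _params(self) -> OccupancyParams:
        return OccupancyParams(
            beta_psi=self.beta,
            alpha_p1=self.a1,
            alpha_p2=self.a2,
            delta_p2=np.exp(self.log_delta),
            alpha_p3=self.a3,
            M=expit(self.M_l),
            theta=expit(self.theta_l) if self.mixture else 0.0,
            eps=self.eps if self.car else None,
            sigma_car=np.exp(self.log_sig),
            phi_car=PHI_BOUND * np.tanh(self.u_phi),
            z_occ=self.z,
        )

    _CACHE_KEYS = (
        "P1", "P2L", "P2H", "_cam_occ_prod",
        "L_un", "L_low", "L_high", "L_occ", "logL1", "logL0", "_det_ll",
    )

    def refresh_liks(self):
        self._refresh_p1()
        self._refresh_p2()
        self._refresh_cam()
        self._compose()

    def _refresh_p1(self):
        self.P1 = expit(self._X_trans @ self.a1)

    def _refresh_p2(self):
        eta = self._X_trans @ self.a2
        self.P2L = expit(eta)
        self.P2H = expit(eta + np.exp(self.log_delta)) if self.mixture else self.P2L

    def _refresh_cam(self):
        if self._X_cam is None:
            self._cam_occ_prod = None
            return
        P3 = expit(self._X_cam @ self.a3)
        lik = self._cam_m0 * (1 - P3) + self._cam_m1 * P3 + self._cam_miss
        self._cam_occ_prod = lik.prod(axis=1)

    def _compose(self):
        """Per-cell session products under each state/class from cached P's."""
        M = expit(self.M_l)
        G = self._G2
        lik_un = (
            self._m0 * (1 - self.P1)
            + self._m2 * (self.P1 * G)
            + self._m3 * (self.P1 * (1 - G))
            + self._mmiss
        )
        self.L_un = lik_un.prod(axis=1)

        def occprod(P2):
            lik = (
                self._m0 * (1 - P2)
                + self._m1 * (P2 * G * (1 - M))
                + self._m2 * (P2 * G * M)
                + self._m3 * (P2 * (1 - G))
                + self._mmiss
            )
            return lik.prod(axis=1)

        self.L_low = occprod(self.P2L)
        self.L_high = occprod(self.P2H) if self.mixture else self.L_low
        if self._X_cam is not None:
            self.L_un = self.L_un * self._cam_un_prod
            self.L_low = self.L_low * self._cam_occ_prod
            self.L_high = self.L_high * self._cam_occ_prod
        self._reweight()

    def _reweight(self):
        th = expit(self.theta_l) if self.mixture else 0.0
        self.L_occ = th * self.L_high + (1 - th) * self.L_low
        with np.errstate(divide="ignore"):
            self.logL1 = np.log(self.L_occ)
            self.logL0 = np.log(self.L_un)
        self._det_ll = None

    def psi(self) -> np.ndarray:
        eta = self.m.X_psi @ self.beta
        if self.car:
            eta = eta + self.eps
        return expit(eta)

    def det_loglik_given_z(self) -> float:
        if self._det_ll is None:
            ll = np.where(self.z == 1, self.logL1, self.logL0)
            self._det_ll = float(ll.sum())
        return self._det_ll

    # -- moves ------------------------------------------------------------

    def _mh_det_block(self, get, set_, prop, refresh):
        ll0 = self.det_loglik_given_z() + self._det_prior()
        snap = {k: getattr(self, k, None) for k in self._CACHE_KEYS}
        cur = get()
        set_(prop.propose(cur, self.rng))
        refresh()
        ll1 = self.det_loglik_given_z() + self._det_prior()
        acc = np.log(self.rng.random()) < ll1 - ll0
        if not acc:
            set_(cur)
            for k, v in snap.items():
                setattr(self, k, v)
        prop.update(acc)

    def _det_prior(self) -> float:
        lp = -0.5 * float(self.a1 @ self.a1 + self.a2 @ self.a2) / COEF_PRIOR_SD**2
        lp += -0.5 * self.log_delta**2 / COEF_PRIOR_SD**2
        if self.a3 is not None:
            lp += -0.5 * float(self.a3 @ self.a3) / COEF_PRIOR_SD**2
        # uniform priors on theta, M -> logistic jacobians
        for u in (self.theta_l, self.M_l):
            lp += np.log(expit(u)) + np.log(expit(-u))
        return lp

    def update_detection(self):
        self._mh_det_block(
            lambda: self.a1.copy(),
            lambda v: setattr(self, "a1", np.asarray(v)),
            self.p_a1,
            lambda: (self._refresh_p1(), self._compose()),
        )

        def get2():
            return np.concatenate([self.a2, [self.log_delta]])

        def set2(v):
            self.a2 = np.asarray(v[:-1])
            self.log_delta = float(v[-1])

        self._mh_det_block(
            get2, set2, self.p_a2, lambda: (self._refresh_p2(), self._compose())
        )
        if self.mixture:
            self._mh_det_block(
                lambda: self.theta_l,
                lambda v: setattr(self, "theta_l", float(v)),
                self.p_theta,
                self._reweight,
            )
        self._mh_det_block(
            lambda: self.M_l,
            lambda v: setattr(self, "M_l", float(v)),
            self.p_M,
            self._compose,
        )
        if self.a3 is not None:
            self._mh_det_block(
                lambda: self.a3.copy(),
                lambda v: setattr(self, "a3", np.asarray(v)),
                self.p_a3,
                lambda: (self._refresh_cam(), self._compose()),
            )

    def update_z(self, lam=None, counts=None, n_active=0, T=0.0, gate=False):
        """Gibbs sweep of z_occ; with gate=True the SCR point process couples in."""
        psi = self.psi()
        u = self.rng.random(len(self.z))
        self._det_ll = None
        if gate:
            return _kernels.zocc_sweep(
                self.z, psi, self.logL1, self.logL0, lam, counts,
                int(n_active), float(T), 1, u,
            )
        _kernels.zocc_sweep(
            self.z, psi, self.logL1, self.logL0,
            np.zeros(1), np.zeros(1, dtype=np.int64), 0, 0.0, 0, u,
        )
        return T

    def update_eps(self):
        if not self.car:
            return
        n = len(self.eps)
        xb = self.m.X_psi @ self.beta
        acc = np.zeros(n, dtype=np.int8)
        _kernels.car_logit_sweep(
            self.eps, self.z.astype(np.int8), xb,
            self.m._indptr, self.m._indices, self.m._deg,
            float(np.exp(2 * self.log_sig)), PHI_BOUND * np.tanh(self.u_phi),
            SOFT_SUM_SD**2,
            self.p_eps.steps, self.rng.standard_normal(n), self.rng.random(n), acc,
        )
        self.p_eps.update(acc)

    def _z_loglik(self, beta) -> float:
        eta = self.m.X_psi @ beta
        if self.car:
            eta = eta + self.eps
        # Bernoulli-logit loglik of z
        return float(np.sum(self.z * eta - np.logaddexp(0.0, eta)))

    def update_beta(self):
        ll0 = self._z_loglik(self.beta) - 0.5 * float(self.beta @ self.beta) / COEF_PRIOR_SD**2
        prop = self.p_beta.propose(self.beta, self.rng)
        ll1 = self._z_loglik(prop) - 0.5 * float(prop @ prop) / COEF_PRIOR_SD**2
        acc = np.log(self.rng.random()) < ll1 - ll0
        if acc:
            self.beta = prop
        self.p_beta.update(acc)

    def update_car_hypers(self):
        if not self.car:
            return

        def logpost(log_sig, u_phi):
            sig = np.exp(log_sig)
            phi = PHI_BOUND * np.tanh(u_phi)
            lp = self.m.car_logpdf(self.eps, sig, phi)
            lp += -0.5 * sig**2 + log_sig            # half-Normal(1) + jacobian
            lp += np.log1p(-np.tanh(u_phi) ** 2)     # uniform phi + tanh jacobian
            return lp

        cur = np.array([self.log_sig, self.u_phi])
        prop = self.p_car.propose(cur, self.rng)
        ll0 = logpost(*cur)
        ll1 = logpost(*prop)
        acc = np.log(self.rng.random()) < ll1 - ll0
        if acc:
            self.log_sig, self.u_phi = float(prop[0]), float(prop[1])
        self.p_car.update(acc)

    def step(self):
        self.update_detection()
        self.update_z()
        self.update_eps()
        self.update_beta()
        self.update_car_hypers()

    def freeze(self):
        for p in self._props:
            p.freeze()
        self.p_eps.freeze()

    # -- monitoring -------------------------------------------------------

    def monitor_names(self):
        names = ["beta_psi", "alpha_p1", "alpha_p2", "delta_p2", "theta", "M",
                 "sigma_car", "phi_car", "psi_mean", "frac_occ"]
        if self.a3 is not None:
            names.append("alpha_p3")
        return names

    def monitored(self) -> dict:
        psi = self.psi()
        out = {
            "beta_psi": self.beta.copy(),
            "alpha_p1": self.a1.copy(),
            "alpha_p2": self.a2.copy(),
            "delta_p2": float(np.exp(self.log_delta)),
            "theta": float(expit(self.theta_l)) if self.mixture else 0.0,
            "M": float(expit(self.M_l)),
            "sigma_car": float(np.exp(self.log_sig)),
            "phi_car": float(PHI_BOUND * np.tanh(self.u_phi)),
            "psi_mean": float(psi.mean()),
            "frac_occ": float(self.z.mean()),
        }
        if self.a3 is not None:
            out["alpha_p3"] = self.a3.copy()
        return out


def occupancy_loglik(model: OccupancyModel, params: OccupancyParams, marginalize=True):
    """Module-level convenience wrapper around :meth:`OccupancyModel.loglik`."""
    return model.loglik(params, marginalize=marginalize)
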