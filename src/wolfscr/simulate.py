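"""Synthetic populations and survey datasets.

The generator reproduces the statistical structure the estimation models
assume, at the scale of the design-evaluation study: a reduced 290-cell
(29,000 km^2) study area holding 19.8% of a reference population of 2557
wolves (506 individuals), activity centres placed proportionally to a
habitat-suitability surface, two-class detection heterogeneity both for
individuals (genetic captures: p = 0.0012 / 0.006, 83% low, sigma = 3.49 km)
and for cells (transect detection: P2 = 0.13 / 0.63, 43% high class),
dog-scat false positives (P1) with misidentification probability M = 0.048,
and sampling restricted to randomly selected extensive cells (presence
signs) and intensive 3x3 areas (genetic captures, 4 areas = 12.4% of the
grid).  Sampling effort varies across cells and sessions and enters every
detection probability on the logit scale, matching the fitted models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .grid import Grid, SamplingDesign
from .occupancy import OccupancyData, transect_event_probs, _standardize
from .scr import DetectorGeometry, SCRData, halfnormal_p


@dataclass
class SimConfig:
    """Study conditions for the simulation experiments."""

    # state space
    n_rows: int = 10
    n_cols: int = 29
    # population size: a fixed share of the reference estimate
    reference_population: int = 2557
    population_fraction: float = 0.198
    # genetic (SCR) detection
    p_low: float = 0.0012
    p_high: float = 0.006
    w_low: float = 0.83              # fraction of individuals in the low class
    sigma_km: float = 3.49
    p0_effort_slope: float = 0.42    # logit-scale effect of standardised log-effort
    # presence-sign (occupancy) detection
    P2_low: float = 0.13
    P2_high: float = 0.63
    theta_high: float = 0.43         # fraction of cells in the high class
    M: float = 0.048                 # misidentification probability
    P1: float = 0.05                 # false (dog-sign) detection probability
    det_effort_slope: float = 2.71
    n_sessions: int = 4
    # per-cell-and-session transect effort (km walked), gamma distributed
    effort_mean_km: float = 5.14
    effort_sd_km: float = 3.8
    # sampling design
    frac_presence: float = 0.30
    n_intensive_areas: int = 4
    # cameras (off by default: the design evaluation uses transect signs)
    include_camera: bool = False
    P3: float = 0.25
    camera_effort_slope: float = 1.81
    trapnights_mean: float = 63.0
    trapnights_sd: float = 50.0
    # occupancy truth: None = a cell is occupied iff it holds an activity
    # centre; a float r links occupancy to "use" within r km of a centre
    use_radius_km: float | None = None
    aggregation: str = "binomial"

    @property
    def N_true(self) -> int:
        return int(round(self.population_fraction * self.reference_population))

    def __post_init__(self):
        for name in ("p_low", "p_high", "P2_low", "P2_high", "sigma_km",
                     "effort_mean_km", "effort_sd_km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("w_low", "theta_high", "frac_presence", "M", "P1"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class TruePopulation:
    """Ground-truth individuals: activity-centre cells, sex, detection class."""

    N_true: int
    cells: np.ndarray        # (N,) activity-centre cell per individual
    sex: np.ndarray          # (N,) "F"/"M"
    detect_class: np.ndarray  # (N,) 0 = low, 1 = high capture probability


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_population(grid: Grid, cfg: SimConfig, seed=0) -> TruePopulation:
    """Place N_true activity centres proportionally to habitat suitability."""
    rng = _rng(seed)
    w = grid.covariate("suitability").astype(float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("suitability surface must be non-negative with positive mass")
    w = w / w.sum()
    N = cfg.N_true
    cells = rng.choice(grid.n_cells, size=N, p=w)
    sex = np.where(rng.random(N) < 0.5, "F", "M")
    detect_class = (rng.random(N) >= cfg.w_low).astype(int)
    return TruePopulation(N_true=N, cells=cells, sex=sex, detect_class=detect_class)


def simulate_effort(grid: Grid, design: SamplingDesign, cfg: SimConfig, seed=0) -> np.ndarray:
    """(n_cells, n_sessions) km walked; positive in extensive cells, 0 elsewhere."""
    rng = _rng(seed)
    shape = (cfg.effort_mean_km / cfg.effort_sd_km) ** 2
    scale = cfg.effort_sd_km**2 / cfg.effort_mean_km
    eff = np.zeros((grid.n_cells, cfg.n_sessions))
    ext = design.extensive_cells
    eff[ext] = np.maximum(rng.gamma(shape, scale, size=(len(ext), cfg.n_sessions)), 0.05)
    return eff


def simulate_genetic_sampling(
    pop: TruePopulation,
    design: SamplingDesign,
    grid: Grid,
    cfg: SimConfig,
    seed=0,
    effort: np.ndarray | None = None,
) -> tuple[SCRData, np.ndarray]:
    """Binomial(100) genetic capture counts at every detector.

    Returns the observed SCRData (all-zero individuals removed) and the
    indices of the detected individuals within the true population.
    """
    rng = _rng(seed)
    if design.n_detectors == 0:
        raise ValueError("design has no detectors")
    if effort is None:
        effort = simulate_effort(grid, design, cfg, rng)
    det_cells = design.detectors["cell_id"].to_numpy(dtype=int)
    effort_cell = effort.sum(axis=1)[det_cells]
    e_std = _standardize(np.log1p(effort_cell))

    geom = DetectorGeometry(grid, design.detectors)
    H = geom.mean_halfnormal(cfg.sigma_km)[pop.cells]      # (N, n_det)
    base = np.where(pop.detect_class == 1, logit(cfg.p_high), logit(cfg.p_low))
    p0 = expit(base[:, None] + cfg.p0_effort_slope * e_std[None, :])
    pbar = np.clip(p0 * H, 0.0, 1.0)
    if cfg.aggregation == "poisson-binomial":
        y = np.zeros_like(pbar, dtype=int)
        for d in range(design.n_detectors):
            for i in range(pop.N_true):
                probs = halfnormal_p(p0[i, d], geom.sub_distances(pop.cells[i], d), cfg.sigma_km)
                y[i, d] = int(rng.binomial(1, probs).sum())
    else:
        y = rng.binomial(100, pbar)
    detected = np.flatnonzero(y.sum(axis=1) > 0)
    data = SCRData(
        y=y[detected],
        detectors=design.detectors,
        sex=pop.sex[detected],
        effort_cell=effort_cell,
    )
    data.validate()
    return data, detected


def true_occupancy(pop: TruePopulation, grid: Grid, cfg: SimConfig) -> np.ndarray:
    """Per-cell occupancy truth (activity-centre presence, or use within a
    radius when ``cfg.use_radius_km`` is set)."""
    counts = np.bincount(pop.cells, minlength=grid.n_cells)
    occ = counts > 0
    if cfg.use_radius_km is not None:
        cx, cy = grid.x[pop.cells], grid.y[pop.cells]
        d2 = (grid.x[:, None] - cx[None, :]) ** 2 + (grid.y[:, None] - cy[None, :]) ** 2
        occ = occ | (d2 <= cfg.use_radius_km**2).any(axis=1)
    return occ.astype(int)


def simulate_presence_sampling(
    pop: TruePopulation,
    design: SamplingDesign,
    grid: Grid,
    cfg: SimConfig,
    seed=0,
    effort: np.ndarray | None = None,
) -> OccupancyData:
    """Multi-event transect histories (and optional camera histories)."""
    rng = _rng(seed)
    if effort is None:
        effort = simulate_effort(grid, design, cfg, rng)
    n, T = grid.n_cells, cfg.n_sessions
    occ = true_occupancy(pop, grid, cfg)
    G = design.intensive_mask().astype(int)
    ext = design.extensive_mask()

    obs = ext[:, None] & (effort > 0)
    le = np.log1p(effort)
    mu, sd = le[obs].mean(), le[obs].std()
    e_std = (le - mu) / (sd if sd > 0 else 1.0)

    high = (rng.random(n) < cfg.theta_high).astype(int)
    base2 = np.where(high == 1, logit(cfg.P2_high), logit(cfg.P2_low))
    P2 = expit(base2[:, None] + cfg.det_effort_slope * e_std)
    P1 = expit(logit(cfg.P1) + cfg.det_effort_slope * e_std)

    probs = transect_event_probs(
        occ[:, None].astype(bool), P1, P2, G[:, None].astype(float), cfg.M
    )  # (n, T, 4)
    cum = probs.cumsum(axis=2)
    u = rng.random((n, T))
    events = np.minimum((u[..., None] >= cum).sum(axis=2), 3)
    events[~obs] = -1

    camera_events = None
    effort_camera = None
    if cfg.include_camera:
        shape = (cfg.trapnights_mean / cfg.trapnights_sd) ** 2
        scale = cfg.trapnights_sd**2 / cfg.trapnights_mean
        effort_camera = np.zeros((n, T))
        effort_camera[ext] = np.maximum(
            rng.gamma(shape, scale, size=(int(ext.sum()), T)), 0.5
        )
        lec = np.log1p(effort_camera)
        muc, sdc = lec[obs].mean(), lec[obs].std()
        ec_std = (lec - muc) / (sdc if sdc > 0 else 1.0)
        P3 = expit(logit(cfg.P3) + cfg.camera_effort_slope * ec_std)
        camera_events = (rng.random((n, T)) < P3 * occ[:, None]).astype(int)
        camera_events[~obs] = -1

    snow = _standardize(rng.standard_normal(n))
    data = OccupancyData(
        transect_events=events,
        effort_transect=effort,
        G=G,
        snow=snow,
        camera_events=camera_events,
        effort_camera=effort_camera,
    )
    data.validate()
    return data


@dataclass
class SimulatedDataset:
    grid: Grid
    design: SamplingDesign
    population: TruePopulation
    occupancy: OccupancyData
    scr: SCRData
    detected: np.ndarray
    effort: np.ndarray
    cfg: SimConfig


def simulate_dataset(
    cfg: SimConfig,
    seed=0,
    grid: Grid | None = None,
    design: SamplingDesign | None = None,
) -> SimulatedDataset:
    """One full replicate: grid, design, population and both survey datasets."""
    from .grid import build_grid, select_design

    rng = _rng(seed)
    if grid is None:
        grid = build_grid(cfg.n_rows, cfg.n_cols, seed=rng)
    if design is None:
        design = select_design(grid, cfg.frac_presence, cfg.n_intensive_areas, seed=rng)
    pop = simulate_population(grid, cfg, rng)
    effort = simulate_effort(grid, design, cfg, rng)
    scr_data, detected = simulate_genetic_sampling(pop, design, grid, cfg, rng, effort=effort)
    occ_data = simulate_presence_sampling(pop, design, grid, cfg, rng, effort=effort)
    return SimulatedDataset(
        grid=grid, design=design, population=pop, occupancy=occ_data,
        scr=scr_data, detected=detected, effort=effort, cfg=cfg,
    )
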