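"""Analysis grid, adjacency, strata and sampling-design selection.

The state space is the standard European 10 x 10 km reporting lattice.  Cells
carry environmental covariates (here synthetic Gaussian random fields, since
the package is simulation-driven), a presence stratum, and the sampling design
distinguishes *extensive* cells (presence-sign transects only) from
*intensive* 3 x 3 blocks of cells where non-invasive genetic samples are
collected.  Each intensive cell hosts one detector at its centroid, which is
associated with 100 sub-detectors on an interior 1 x 1 km sub-grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

CELL_KM = 10.0
AREA_KM2 = 100.0
N_SUBDETECTORS = 100

#: covariates attached to every grid cell
COVARIATES = (
    "altitude",
    "forest",
    "urban",
    "road_density",
    "agriculture",
    "human_density",
    "ruggedness",
    "n_ungulate_species",
    "suitability",
)

STRATA = ("stable", "sporadic", "supposed", "adjacent", "outside")

# 1-km sub-grid offsets (km) of the 100 sub-detectors relative to the
# detector (= cell centroid); they tile the 10-km cell exactly.
SUB_OFFSETS_1D = np.arange(10) - 4.5


class DesignError(RuntimeError):
    """Raised when a sampling design cannot be constructed."""


@dataclass
class Grid:
    """Regular lattice of 10 x 10 km cells with covariates and strata."""

    n_rows: int
    n_cols: int
    cells: pd.DataFrame  # cell_id,row,col,x_km,y_km,stratum,<covariates>

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def x(self) -> np.ndarray:
        return self.cells["x_km"].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.cells["y_km"].to_numpy()

    @property
    def row(self) -> np.ndarray:
        return self.cells["row"].to_numpy()

    @property
    def col(self) -> np.ndarray:
        return self.cells["col"].to_numpy()

    @property
    def stratum(self) -> np.ndarray:
        return self.cells["stratum"].to_numpy()

    def covariate(self, name: str) -> np.ndarray:
        return self.cells[name].to_numpy(dtype=float)

    def covariate_matrix(self, names) -> np.ndarray:
        """Column-stacked covariate values, shape (n_cells, len(names))."""
        return self.cells[list(names)].to_numpy(dtype=float)

    def validate(self) -> None:
        df = self.cells
        if not np.array_equal(df["cell_id"].to_numpy(), np.arange(self.n_cells)):
            raise ValueError("cell_ids must be contiguous from 0")
        if not np.all(np.isfinite(df[list(COVARIATES)].to_numpy(dtype=float))):
            raise ValueError("covariates must be finite")
        if not set(df["stratum"]).issubset(STRATA):
            raise ValueError(f"unknown stratum labels: {set(df['stratum']) - set(STRATA)}")


@dataclass
class Adjacency:
    """Rook (shared-border) adjacency of the lattice."""

    W: np.ndarray  # (n, n) binary, symmetric, zero diagonal
    D: np.ndarray  # (n,) row sums of W

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def neighbor_lists(self):
        """CSR-style (indptr, indices) arrays for kernel loops."""
        idx = [np.flatnonzero(self.W[i]) for i in range(self.n)]
        indptr = np.zeros(self.n + 1, dtype=np.int64)
        indptr[1:] = np.cumsum([len(a) for a in idx])
        indices = np.concatenate(idx) if self.n else np.empty(0, dtype=np.int64)
        return indptr, indices.astype(np.int64)


@dataclass
class SamplingDesign:
    """Extensive / intensive split plus the detector network."""

    extensive_cells: np.ndarray            # sorted cell ids
    intensive_areas: list                  # list of 9-cell id arrays
    detectors: pd.DataFrame                # detector_id,cell_id,x_km,y_km,area_id
    n_cells: int

    @property
    def intensive_cells(self) -> np.ndarray:
        if not self.intensive_areas:
            return np.empty(0, dtype=int)
        return np.sort(np.concatenate(self.intensive_areas))

    @property
    def n_detectors(self) -> int:
        return len(self.detectors)

    def extensive_mask(self) -> np.ndarray:
        m = np.zeros(self.n_cells, dtype=bool)
        m[self.extensive_cells] = True
        return m

    def intensive_mask(self) -> np.ndarray:
        m = np.zeros(self.n_cells, dtype=bool)
        m[self.intensive_cells] = True
        return m

    def subdetector_coords(self, detector_id: int) -> np.ndarray:
        """(100, 2) coordinates of one detector's sub-detectors (km)."""
        row = self.detectors.loc[self.detectors["detector_id"] == detector_id].iloc[0]
        ox, oy = np.meshgrid(SUB_OFFSETS_1D, SUB_OFFSETS_1D)
        return np.column_stack([row["x_km"] + ox.ravel(), row["y_km"] + oy.ravel()])

    def validate(self) -> None:
        ext = set(self.extensive_cells.tolist())
        for area in self.intensive_areas:
            if len(area) != 9:
                raise ValueError("intensive areas must contain 9 cells")
            if not set(area.tolist()) <= ext:
                raise ValueError("every intensive cell must also be extensive")


@dataclass
class CovariateSpec:
    """How synthetic covariate surfaces are generated.

    Each covariate is spatially smoothed white noise (disc kernel of
    ``smoothing_radius`` cells), standardised to zero mean / unit SD.
    Suitability is a logistic transform of altitude and forest, with slopes
    matching the reported density effects of those covariates.
    """

    smoothing_radius: int = 2
    suitability_coefs: dict = field(
        default_factory=lambda: {"altitude": 1.08, "forest": 1.11}
    )
    n_ungulate_max: int = 6


def _disc_footprint(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= r**2


def _smooth_field(shape, rng, radius) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if radius > 0 and min(shape) > 1:
        fp = _disc_footprint(radius).astype(float)
        fp /= fp.sum()
        noise = ndimage.correlate(noise, fp, mode="nearest")
    sd = noise.std()
    if sd > 0:
        noise = (noise - noise.mean()) / sd
    else:
        noise = np.zeros(shape)
    return noise


def build_grid(
    n_rows: int,
    n_cols: int,
    covariate_spec: CovariateSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> Grid:
    """Build a ``n_rows x n_cols`` grid with synthetic covariate surfaces."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be positive")
    spec = covariate_spec or CovariateSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    df = pd.DataFrame(
        {
            "cell_id": np.arange(n_rows * n_cols),
            "row": rows,
            "col": cols,
            "x_km": cols * CELL_KM,
            "y_km": rows * CELL_KM,
            "stratum": "outside",
        }
    )
    fields = {}
    for name in COVARIATES:
        if name == "suitability":
            continue
        f = _smooth_field((n_rows, n_cols), rng, spec.smoothing_radius).ravel()
        if name == "n_ungulate_species":
            # quantile-bin the latent field into 0..n_ungulate_max species counts
            ranks = np.argsort(np.argsort(f))
            f = np.floor(ranks / len(f) * (spec.n_ungulate_max + 1))
            f = np.minimum(f, spec.n_ungulate_max)
        fields[name] = f
    lin = sum(c * fields[k] for k, c in spec.suitability_coefs.items())
    fields["suitability"] = expit(lin)
    for name in COVARIATES:
        df[name] = fields[name]
    grid = Grid(n_rows, n_cols, df)
    grid.validate()
    return grid


def build_adjacency(grid: Grid) -> Adjacency:
    """Rook (shared-border) adjacency matrix and its degree diagonal."""
    n = grid.n_cells
    W = np.zeros((n, n), dtype=np.int8)
    r, c = grid.row, grid.col
    idx = {(int(ri), int(ci)): i for i, (ri, ci) in enumerate(zip(r, c))}
    for i in range(n):
        for dr, dc in ((1, 0), (0, 1)):
            j = idx.get((int(r[i]) + dr, int(c[i]) + dc))
            if j is not None:
                W[i, j] = W[j, i] = 1
    return Adjacency(W=W, D=W.sum(axis=1).astype(float))


def assign_strata(
    grid: Grid, occupancy_proxy: np.ndarray, thresholds, adjacency: Adjacency | None = None
) -> Grid:
    """Label cells stable/sporadic/supposed by proxy thresholds.

    ``thresholds = (t_supposed, t_sporadic, t_stable)`` must be
    non-decreasing.  Unlabelled cells that share a border with a labelled
    cell become "adjacent"; the remainder is "outside" (unsurveyed).
    """
    t1, t2, t3 = thresholds
    if not (t1 <= t2 <= t3):
        raise ValueError("thresholds must be ordered (ascending)")
    proxy = np.asarray(occupancy_proxy, dtype=float)
    if proxy.shape != (grid.n_cells,):
        raise ValueError("proxy must have one value per cell")
    labels = np.full(grid.n_cells, "outside", dtype=object)
    labels[proxy >= t1] = "supposed"
    labels[proxy >= t2] = "sporadic"
    labels[proxy >= t3] = "stable"
    adj = adjacency or build_adjacency(grid)
    labelled = labels != "outside"
    touches = (adj.W @ labelled.astype(int)) > 0
    labels[~labelled & touches] = "adjacent"
    out = Grid(grid.n_rows, grid.n_cols, grid.cells.copy())
    out.cells["stratum"] = labels
    return out


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _allocate_by_stratum(counts: dict, frac: float) -> dict:
    """Largest-remainder allocation of round_half_up(frac * total) cells."""
    total = _round_half_up(frac * sum(counts.values()))
    quotas = {s: frac * n for s, n in counts.items()}
    base = {s: int(np.floor(q)) for s, q in quotas.items()}
    base = {s: min(b, counts[s]) for s, b in base.items()}
    short = total - sum(base.values())
    remainders = sorted(
        counts, key=lambda s: (quotas[s] - np.floor(quotas[s])), reverse=True
    )
    i = 0
    while short > 0 and i < 10 * len(counts):
        s = remainders[i % len(remainders)]
        if base[s] < counts[s]:
            base[s] += 1
            short -= 1
        i += 1
    return base


def select_design(
    grid: Grid,
    frac_extensive: float,
    n_intensive_areas: int,
    seed: int | np.random.Generator = 0,
    max_retries: int = 10_000,
) -> SamplingDesign:
    """Stratified-random extensive cells plus non-overlapping 3x3 intensive areas.

    The extensive sample size is ``round_half_up(frac_extensive * n_cells)``,
    allocated across strata by largest remainder so every stratum is sampled
    at (approximately) the same fraction.  Intensive 3x3 blocks are placed by
    rejection sampling of block anchors and their cells are always added to
    the extensive set.
    """
    if not (0 < frac_extensive <= 1):
        raise ValueError("frac_extensive must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    strata = grid.stratum
    counts = {s: int(np.sum(strata == s)) for s in STRATA if np.any(strata == s)}
    alloc = _allocate_by_stratum(counts, frac_extensive)
    chosen = []
    for s, k in alloc.items():
        pool = np.flatnonzero(strata == s)
        chosen.append(rng.choice(pool, size=k, replace=False))
    extensive = np.sort(np.concatenate(chosen)) if chosen else np.empty(0, dtype=int)

    # 3x3 intensive blocks, rejection-sampled anchors (lower-left cell)
    areas: list[np.ndarray] = []
    if n_intensive_areas > 0:
        if grid.n_rows < 3 or grid.n_cols < 3:
            raise DesignError("grid too small for a 3x3 intensive area")
        occupied = np.zeros(grid.n_cells, dtype=bool)
        tries = 0
        while len(areas) < n_intensive_areas:
            tries += 1
            if tries > max_retries:
                raise DesignError(
                    f"could not place {n_intensive_areas} non-overlapping 3x3 areas"
                )
            r0 = rng.integers(0, grid.n_rows - 2)
            c0 = rng.integers(0, grid.n_cols - 2)
            block = np.array(
                [(r0 + dr) * grid.n_cols + (c0 + dc) for dr in range(3) for dc in range(3)]
            )
            if occupied[block].any():
                continue
            occupied[block] = True
            areas.append(np.sort(block))
        extensive = np.unique(np.concatenate([extensive, np.concatenate(areas)]))

    det_rows = []
    det_id = 0
    for area_id, block in enumerate(areas):
        for cid in block:
            det_rows.append(
                {
                    "detector_id": det_id,
                    "cell_id": int(cid),
                    "x_km": float(grid.x[cid]),
                    "y_km": float(grid.y[cid]),
                    "area_id": area_id,
                }
            )
            det_id += 1
    detectors = pd.DataFrame(
        det_rows, columns=["detector_id", "cell_id", "x_km", "y_km", "area_id"]
    )
    design = SamplingDesign(
        extensive_cells=extensive,
        intensive_areas=areas,
        detectors=detectors,
        n_cells=grid.n_cells,
    )
    design.validate()
    return design
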