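"""CSV/JSON file formats, input validation and run manifests.

All files are UTF-8 comma-separated with a header row and "." decimals.
Cell, session and detector identifiers are 0-based in memory and 1-based
in files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import COVARIATES, Grid, SamplingDesign
from .occupancy import OccupancyData
from .scr import SCRData

GRID_COLUMNS = ["cell_id", "row", "col", "x_km", "y_km", "stratum", *COVARIATES]
DESIGN_COLUMNS = ["cell_id", "is_extensive", "is_intensive", "area_id"]
OCC_COLUMNS = ["cell_id", "session", "source", "event_code", "effort"]
CAPTURE_COLUMNS = ["individual_id", "detector_id", "count", "sex"]
DETECTOR_COLUMNS = ["detector_id", "cell_id", "x_km", "y_km", "area_id", "effort_km"]


# ---------------------------------------------------------------------------
# writers


def grid_to_csv(grid: Grid, path) -> None:
    df = grid.cells.copy()
    df["cell_id"] = df["cell_id"] + 1
    df[GRID_COLUMNS].to_csv(path, index=False)


def grid_from_csv(path) -> Grid:
    df = pd.read_csv(path)
    df["cell_id"] = df["cell_id"] - 1
    n_rows = int(df["row"].max()) + 1
    n_cols = int(df["col"].max()) + 1
    grid = Grid(n_rows, n_cols, df.reset_index(drop=True))
    grid.validate()
    return grid


def design_to_csv(design: SamplingDesign, path) -> None:
    ext = design.extensive_mask()
    inten = design.intensive_mask()
    area = np.full(design.n_cells, -1)
    for aid, block in enumerate(design.intensive_areas):
        area[block] = aid
    pd.DataFrame(
        {
            "cell_id": np.arange(design.n_cells) + 1,
            "is_extensive": ext.astype(int),
            "is_intensive": inten.astype(int),
            "area_id": np.where(area >= 0, area + 1, 0),
        }
    ).to_csv(path, index=False)


def design_from_csv(path, grid: Grid) -> SamplingDesign:
    df = pd.read_csv(path)
    ext = np.flatnonzero(df["is_extensive"].to_numpy() == 1)
    areas = []
    for aid in sorted(set(df.loc[df["area_id"] > 0, "area_id"])):
        areas.append(np.sort(df.loc[df["area_id"] == aid, "cell_id"].to_numpy() - 1))
    rows = []
    det_id = 0
    for aid, block in enumerate(areas):
        for cid in block:
            rows.append(
                {
                    "detector_id": det_id,
                    "cell_id": int(cid),
                    "x_km": float(grid.x[cid]),
                    "y_km": float(grid.y[cid]),
                    "area_id": aid,
                }
            )
            det_id += 1
    detectors = pd.DataFrame(
        rows, columns=["detector_id", "cell_id", "x_km", "y_km", "area_id"]
    )
    return SamplingDesign(
        extensive_cells=ext, intensive_areas=areas, detectors=detectors,
        n_cells=grid.n_cells,
    )


def occupancy_to_csv(data: OccupancyData, path) -> None:
    rows = []
    for source, ev, eff in (
        ("transect", data.transect_events, data.effort_transect),
        ("camera", data.camera_events, data.effort_camera),
    ):
        if ev is None:
            continue
        for c in range(data.n_cells):
            for t in range(data.n_sessions):
                if ev[c, t] < 0:
                    continue
                rows.append(
                    {
                        "cell_id": c + 1,
                        "session": t + 1,
                        "source": source,
                        "event_code": int(ev[c, t]),
                        "effort": float(eff[c, t]),
                    }
                )
    pd.DataFrame(rows, columns=OCC_COLUMNS).to_csv(path, index=False)


def occupancy_from_csv(path, grid: Grid, design: SamplingDesign, n_sessions: int = 4):
    df = pd.read_csv(path)
    n = grid.n_cells
    tr_ev = np.full((n, n_sessions), -1, dtype=int)
    tr_eff = np.zeros((n, n_sessions))
    cam_ev = None
    cam_eff = None
    for _, r in df.iterrows():
        c, t = int(r["cell_id"]) - 1, int(r["session"]) - 1
        if r["source"] == "transect":
            tr_ev[c, t] = int(r["event_code"])
            tr_eff[c, t] = float(r["effort"])
        else:
            if cam_ev is None:
                cam_ev = np.full((n, n_sessions), -1, dtype=int)
                cam_eff = np.zeros((n, n_sessions))
            cam_ev[c, t] = int(r["event_code"])
            cam_eff[c, t] = float(r["effort"])
    G = design.intensive_mask().astype(int)
    data = OccupancyData(
        transect_events=tr_ev, effort_transect=tr_eff, G=G,
        camera_events=cam_ev, effort_camera=cam_eff,
    )
    data.validate()
    return data


def scr_to_csv(data: SCRData, captures_path, detectors_path) -> None:
    rows = []
    for i in range(data.n_individuals):
        for d in np.flatnonzero(data.y[i]):
            rows.append(
                {
                    "individual_id": i + 1,
                    "detector_id": int(d) + 1,
                    "count": int(data.y[i, d]),
                    "sex": data.sex[i],
                }
            )
    pd.DataFrame(rows, columns=CAPTURE_COLUMNS).to_csv(captures_path, index=False)
    det = data.detectors.copy()
    det["detector_id"] = det["detector_id"] + 1
    det["cell_id"] = det["cell_id"] + 1
    det["area_id"] = det["area_id"] + 1
    det["effort_km"] = data.effort_cell
    det[DETECTOR_COLUMNS].to_csv(detectors_path, index=False)


def scr_from_csv(captures_path, detectors_path) -> SCRData:
    caps = pd.read_csv(captures_path)
    det = pd.read_csv(detectors_path)
    det["detector_id"] = det["detector_id"] - 1
    det["cell_id"] = det["cell_id"] - 1
    det["area_id"] = det["area_id"] - 1
    n_det = len(det)
    ids = sorted(set(caps["individual_id"]))
    idx = {v: i for i, v in enumerate(ids)}
    y = np.zeros((len(ids), n_det), dtype=int)
    sex = np.full(len(ids), "U", dtype=object)
    for _, r in caps.iterrows():
        i = idx[r["individual_id"]]
        y[i, int(r["detector_id"]) - 1] = int(r["count"])
        sex[i] = r["sex"]
    data = SCRData(
        y=y,
        detectors=det[["detector_id", "cell_id", "x_km", "y_km", "area_id"]],
        sex=np.asarray(sex),
        effort_cell=det["effort_km"].to_numpy(dtype=float),
    )
    data.validate()
    return data


def draws_to_csv(result, path) -> None:
    cols = {name: arr.ravel() for name, arr in result._scalar_items()}
    pd.DataFrame(cols).to_csv(path, index=False)


def summary_to_json(result, path, extra: dict | None = None) -> None:
    out = {
        "model": result.model_name,
        "params": {
            name: {
                "mean": float(a.mean()),
                "sd": float(a.std(ddof=1)) if a.size > 1 else 0.0,
                "rhat": float(r),
            }
            for (name, a), r in zip(result._scalar_items(), result.rhat().values())
        },
    }
    if extra:
        out.update(extra)
    Path(path).write_text(json.dumps(out, indent=2))


def write_manifest(path, seed: int, config: dict, inputs: dict | None = None) -> None:
    """Record everything needed to re-run a command exactly."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package_version": __version__,
        "seed": int(seed),
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "inputs": inputs or {},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    def add(self, file: str, row, message: str) -> None:
        self.violations.append({"file": str(file), "row": row, "message": message})

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "all inputs valid"
        return "\n".join(
            f"{v['file']}:{v['row']}: {v['message']}" for v in self.violations
        )


def _check_columns(df, cols, path, report) -> bool:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        report.add(path, 0, f"missing columns: {missing}")
        return False
    return True


def validate_inputs(paths: dict) -> ValidationReport:
    """Schema and cross-reference checks over a set of input CSVs.

    ``paths`` may contain any of: grid, design, occupancy, captures,
    detectors.  Row numbers refer to 1-based data rows (excluding header).
    """
    report = ValidationReport()
    frames = {}
    for key, path in paths.items():
        p = Path(path)
        if not p.exists():
            report.add(path, 0, "file not found")
            continue
        try:
            frames[key] = pd.read_csv(p)
        except Exception as e:  # malformed content
            report.add(path, 0, f"unreadable CSV: {e}")

    n_cells = None
    if "grid" in frames:
        df = frames["grid"]
        if _check_columns(df, GRID_COLUMNS, paths["grid"], report):
            n_cells = len(df)
            for i, r in df.iterrows():
                for cov in COVARIATES:
                    if not np.isfinite(r[cov]):
                        report.add(paths["grid"], i + 1, f"non-finite {cov}")
    if "design" in frames:
        df = frames["design"]
        if _check_columns(df, DESIGN_COLUMNS, paths["design"], report):
            bad = df[(df["is_intensive"] == 1) & (df["is_extensive"] != 1)]
            for i in bad.index:
                report.add(paths["design"], i + 1, "intensive cell not marked extensive")
    if "occupancy" in frames:
        df = frames["occupancy"]
        if _check_columns(df, OCC_COLUMNS, paths["occupancy"], report):
            for i, r in df.iterrows():
                if r["source"] == "transect" and r["event_code"] not in (0, 1, 2, 3):
                    report.add(paths["occupancy"], i + 1,
                               f"invalid transect event code {r['event_code']}")
                if r["source"] == "camera" and r["event_code"] not in (0, 1):
                    report.add(paths["occupancy"], i + 1,
                               f"invalid camera event code {r['event_code']}")
                if r["effort"] < 0:
                    report.add(paths["occupancy"], i + 1, "negative effort")
                if n_cells is not None and not (1 <= r["cell_id"] <= n_cells):
                    report.add(paths["occupancy"], i + 1,
                               f"cell_id {r['cell_id']} outside grid")
    det_ids = None
    if "detectors" in frames:
        df = frames["detectors"]
        if _check_columns(df, DETECTOR_COLUMNS, paths["detectors"], report):
            det_ids = set(df["detector_id"])
            if n_cells is not None:
                bad = df[(df["cell_id"] < 1) | (df["cell_id"] > n_cells)]
                for i in bad.index:
                    report.add(paths["detectors"], i + 1,
                               f"detector references unknown cell {df.loc[i, 'cell_id']}")
    if "captures" in frames:
        df = frames["captures"]
        if _check_columns(df, CAPTURE_COLUMNS, paths["captures"], report):
            for i, r in df.iterrows():
                if not (0 <= r["count"] <= 100):
                    report.add(paths["captures"], i + 1, f"count {r['count']} outside [0, 100]")
                if det_ids is not None and r["detector_id"] not in det_ids:
                    report.add(paths["captures"], i + 1,
                               f"unknown detector_id {r['detector_id']}")
                if r["sex"] not in ("F", "M", "U"):
                    report.add(paths["captures"], i + 1, f"invalid sex {r['sex']}")
    return report
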