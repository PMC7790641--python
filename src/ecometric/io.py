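"""CSV/JSON schemas and plain-text raster extraction.

Interchange is RFC 4180 CSV with a header row, UTF-8, '.' decimal:

* ``traits.csv`` — species,score
* ``communities.csv`` — point_id,x,y,species (long; one row per occurrence)
* ``environment.csv`` — point_id,precip_mm
* ``calibration.csv`` — point_id,x,y,mean,sd,richness,env_log
* ``fossil_sites.csv`` — site_id,x,y,age_class,species,score (long)
* ``gcm.csv`` — site_id,glacial_ccsm4_mm,glacial_miroc_mm,interglacial_mm
* ``models.json`` — fitted estimators (explicit nulls for unoccupied bins)
* ``truth.json`` — generator parameters of a synthetic run

Numbers are serialized with full round-trip precision so a write-then-read
reproduces values exactly.  Raster point extraction reads the ESRI ASCII
grid format (a plain-text single-band raster).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .communities import TraitTable, load_and_validate_traits
from .errors import ValidationError
from .estimators import ModelSet, modelset_from_dict, modelset_to_dict
from .paleo import FossilSite, GCMValues
from .reporting import FilterReport
from .synthetic import SyntheticLandscape

__all__ = [
    "FilterReport",
    "read_traits", "write_traits",
    "read_communities", "write_communities",
    "read_environment", "write_environment",
    "read_calibration_table", "write_calibration_table",
    "read_fossil_sites", "write_fossil_sites",
    "read_gcm", "write_gcm",
    "save_models", "load_models",
    "write_landscape", "write_json", "read_json",
    "read_ascii_grid", "write_ascii_grid", "extract_env_at_points",
]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(required) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return df


def _fmt(v: float) -> str:
    return repr(float(v))


# -- traits ------------------------------------------------------------------


def read_traits(path: str | Path) -> TraitTable:
    df = _read_csv(path, ["species", "score"])
    for i, raw in enumerate(df["score"]):
        try:
            score = int(raw)
        except (TypeError, ValueError):
            score = None
        if score not in (1, 2, 3):
            raise ValidationError(
                f"{path}, row {i + 2}: score {raw!r} for species "
                f"'{df['species'].iloc[i]}' outside {{1, 2, 3}}"
            )
    return load_and_validate_traits(df)


def write_traits(traits: TraitTable, path: str | Path) -> None:
    pd.DataFrame(traits.items(), columns=["species", "score"]).to_csv(path, index=False)


# -- communities + environment ----------------------------------------------


def read_communities(path: str | Path) -> tuple[pd.DataFrame, dict[str, frozenset[str]]]:
    """Long-format occurrences → (points table, point_id → species set)."""
    df = _read_csv(path, ["point_id", "x", "y", "species"])
    df["point_id"] = df["point_id"].astype(str)
    points = df.drop_duplicates("point_id")[["point_id", "x", "y"]].reset_index(drop=True)
    lists = {
        pid: frozenset(sub["species"].astype(str))
        for pid, sub in df.groupby("point_id", sort=False)
    }
    return points, lists


def write_communities(
    points: pd.DataFrame, community_lists: dict[str, frozenset[str]], path: str | Path
) -> None:
    rows = []
    xy = points.set_index("point_id")
    for pid in points["point_id"]:
        for sp in sorted(community_lists[pid]):
            rows.append((pid, xy.loc[pid, "x"], xy.loc[pid, "y"], sp))
    pd.DataFrame(rows, columns=["point_id", "x", "y", "species"]).to_csv(path, index=False)


def read_environment(path: str | Path) -> dict[str, float]:
    df = _read_csv(path, ["point_id", "precip_mm"])
    env: dict[str, float] = {}
    for i, (pid, mm) in enumerate(zip(df["point_id"].astype(str), df["precip_mm"])):
        try:
            value = float(mm)
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}, row {i + 2}: precip_mm {mm!r} is not a number"
            ) from None
        if pid in env:
            raise ValidationError(f"{path}, row {i + 2}: duplicate point_id '{pid}'")
        env[pid] = value
    return env


def write_environment(env: dict[str, float], path: str | Path) -> None:
    df = pd.DataFrame(
        {"point_id": list(env), "precip_mm": [_fmt(v) for v in env.values()]}
    )
    df.to_csv(path, index=False)


# -- calibration -------------------------------------------------------------


def write_calibration_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_calibration_table(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, ["point_id", "mean", "sd", "richness", "env_log"])
    df["point_id"] = df["point_id"].astype(str)
    return df


# -- fossil sites + GCM -------------------------------------------------------


def read_fossil_sites(path: str | Path) -> list[FossilSite]:
    df = _read_csv(path, ["site_id", "x", "y", "age_class", "species", "score"])
    sites = []
    for sid, sub in df.groupby("site_id", sort=False):
        ages = sub["age_class"].unique()
        if len(ages) != 1:
            raise ValidationError(f"{path}: site '{sid}' has multiple age classes {list(ages)}")
        occ = tuple(
            (str(sp), int(sc)) for sp, sc in zip(sub["species"], sub["score"])
        )
        sites.append(
            FossilSite(
                site_id=str(sid),
                x=float(sub["x"].iloc[0]),
                y=float(sub["y"].iloc[0]),
                age_class=str(ages[0]),
                occurrences=occ,
            )
        )
    return sites


def write_fossil_sites(sites: list[FossilSite], path: str | Path) -> None:
    rows = [
        (s.site_id, s.x, s.y, s.age_class, sp, score)
        for s in sites
        for sp, score in s.occurrences
    ]
    pd.DataFrame(
        rows, columns=["site_id", "x", "y", "age_class", "species", "score"]
    ).to_csv(path, index=False)


def read_gcm(path: str | Path) -> list[GCMValues]:
    df = _read_csv(path, ["site_id", "glacial_ccsm4_mm", "glacial_miroc_mm", "interglacial_mm"])
    return [
        GCMValues(
            site_id=str(r.site_id),
            glacial_model_values=(float(r.glacial_ccsm4_mm), float(r.glacial_miroc_mm)),
            interglacial_value=float(r.interglacial_mm),
        )
        for r in df.itertuples()
    ]


def write_gcm(gcms: list[GCMValues], path: str | Path) -> None:
    rows = [
        (g.site_id, _fmt(g.glacial_model_values[0]), _fmt(g.glacial_model_values[1]),
         _fmt(g.interglacial_value))
        for g in gcms
    ]
    pd.DataFrame(
        rows,
        columns=["site_id", "glacial_ccsm4_mm", "glacial_miroc_mm", "interglacial_mm"],
    ).to_csv(path, index=False)


# -- models / JSON ------------------------------------------------------------


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, allow_nan=False) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def save_models(models: ModelSet, path: str | Path, metadata: dict | None = None) -> None:
    payload = modelset_to_dict(models)
    if metadata:
        payload["metadata"] = metadata
    write_json(payload, path)


def load_models(path: str | Path) -> ModelSet:
    return modelset_from_dict(read_json(path))


# -- synthetic landscape bundle ----------------------------------------------


def write_landscape(landscape: SyntheticLandscape, out_dir: str | Path) -> None:
    """Write traits.csv, communities.csv, environment.csv, truth.json.

    Environment is stored in mm (the observation-scale schema); the log
    transform is reapplied at calibration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_traits(landscape.trait_table, out / "traits.csv")
    write_communities(landscape.points, landscape.community_lists, out / "communities.csv")
    env_mm = {pid: math.exp(v) for pid, v in landscape.env_log.items()}
    write_environment(env_mm, out / "environment.csv")
    truth = dict(landscape.truth)
    truth["n_points_total"] = landscape.n_points_total
    truth["n_points_filtered"] = landscape.n_points_filtered
    write_json(truth, out / "truth.json")


# -- ASCII-grid raster extraction ---------------------------------------------


class AsciiGrid:
    """A single-band ESRI ASCII grid: data array plus georeferencing."""

    def __init__(self, data: np.ndarray, xllcorner: float, yllcorner: float,
                 cellsize: float, nodata: float = -9999.0):
        self.data = np.asarray(data, dtype=float)  # row 0 is the TOP row
        self.xllcorner = float(xllcorner)
        self.yllcorner = float(yllcorner)
        self.cellsize = float(cellsize)
        self.nodata = float(nodata)

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]


def read_ascii_grid(path: str | Path) -> AsciiGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValidationError(
            f"{path}: data shape {data.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return AsciiGrid(
        data,
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(grid: AsciiGrid, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {_fmt(grid.xllcorner)}\n")
        fh.write(f"yllcorner {_fmt(grid.yllcorner)}\n")
        fh.write(f"cellsize {_fmt(grid.cellsize)}\n")
        fh.write(f"NODATA_value {_fmt(grid.nodata)}\n")
        for row in grid.data:
            fh.write(" ".join(_fmt(v) for v in row) + "\n")


def extract_env_at_points(
    grid: AsciiGrid | str | Path, points: list[tuple[float, float]]
) -> dict[tuple[float, float], float]:
    """Nearest-cell raster value at each (x, y) point; no interpolation.

    Out-of-bounds points and nodata cells are errors (listed in one message),
    never silently passed through.
    """
    if not isinstance(grid, AsciiGrid):
        grid = read_ascii_grid(grid)
    bad: list[tuple[float, float]] = []
    nodata_pts: list[tuple[float, float]] = []
    out: dict[tuple[float, float], float] = {}
    x_max = grid.xllcorner + grid.ncols * grid.cellsize
    y_max = grid.yllcorner + grid.nrows * grid.cellsize
    for x, y in points:
        if not (grid.xllcorner <= x <= x_max and grid.yllcorner <= y <= y_max):
            bad.append((x, y))
            continue
        col = min(int((x - grid.xllcorner) / grid.cellsize), grid.ncols - 1)
        row_from_bottom = min(int((y - grid.yllcorner) / grid.cellsize), grid.nrows - 1)
        value = float(grid.data[grid.nrows - 1 - row_from_bottom, col])
        if value == grid.nodata:
            nodata_pts.append((x, y))
            continue
        out[(x, y)] = value
    if bad:
        raise ValidationError(f"points outside raster bounds: {bad[:10]}")
    if nodata_pts:
        raise ValidationError(f"points on nodata cells: {nodata_pts[:10]}")
    return out
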