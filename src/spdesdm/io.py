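"""Plain-text readers and writers.

Raster layers are stored as ESRI ASCII grids (one file per layer) plus a
JSON manifest recording layer name, semantic class, units and scaling;
occurrence sets as CSV; polygons as GeoJSON; meshes and fit summaries as
JSON. Everything round-trips losslessly at float precision ~1e-7 or better.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .grids import GridGeometry
from .landscape import CovariateStack, OccurrenceSet
from .mesh import Mesh
from .model import PosteriorFit

_NODATA = -9999.0


def write_ascii_grid(path: Path, grid: GridGeometry, values: np.ndarray) -> None:
    if values.shape != grid.shape:
        raise ValueError("layer shape does not match grid")
    header = (
        f"ncols {grid.nx}\nnrows {grid.ny}\n"
        f"xllcorner {grid.x0!r}\nyllcorner {grid.y0!r}\n"
        f"cellsize {grid.resolution!r}\nNODATA_value {_NODATA}\n"
    )
    # ASCII grids store row 0 at the top (north); our arrays start south
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values[::-1], fmt="%.9g")


def read_ascii_grid(path: Path) -> tuple[GridGeometry, np.ndarray]:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh)
    grid = GridGeometry(
        hdr["xllcorner"], hdr["yllcorner"], hdr["cellsize"],
        int(hdr["ncols"]), int(hdr["nrows"]),
    )
    return grid, np.atleast_2d(values)[::-1]


def write_stack(stack: CovariateStack, directory: Path) -> Path:
    """One ASCII grid per layer + manifest.json; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "grid": {
            "x0": stack.grid.x0,
            "y0": stack.grid.y0,
            "resolution": stack.grid.resolution,
            "nx": stack.grid.nx,
            "ny": stack.grid.ny,
        },
        "layers": [],
    }
    for name, arr in stack.layers.items():
        fname = f"{name}.asc"
        write_ascii_grid(directory / fname, stack.grid, arr)
        manifest["layers"].append(
            {
                "name": name,
                "class": stack.classes[name],
                "units": stack.units[name],
                "file": fname,
                "scaling": list(stack.scaling[name]) if name in stack.scaling else None,
            }
        )
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_stack(manifest_path: Path, *, allow_regrid: bool = False) -> CovariateStack:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    g = manifest["grid"]
    grid = GridGeometry(g["x0"], g["y0"], g["resolution"], g["nx"], g["ny"])
    layers, classes, units, scaling = {}, {}, {}, {}
    for entry in manifest["layers"]:
        for fld in ("name", "class", "units", "file"):
            if fld not in entry or entry[fld] is None:
                raise ValueError(
                    f"manifest entry missing '{fld}' for layer "
                    f"'{entry.get('name', '<unnamed>')}'"
                )
        lgrid, vals = read_ascii_grid(manifest_path.parent / entry["file"])
        if lgrid != grid:
            if not allow_regrid:
                raise ValueError(
                    f"layer '{entry['name']}' grid does not match the manifest grid; "
                    "pass allow_regrid=True to resample by nearest neighbour"
                )
            vals = vals.ravel()[lgrid.cell_index(grid.cell_centers())].reshape(grid.shape)
        layers[entry["name"]] = vals
        classes[entry["name"]] = entry["class"]
        units[entry["name"]] = entry["units"]
        if entry.get("scaling"):
            scaling[entry["name"]] = tuple(entry["scaling"])
    return CovariateStack(grid=grid, layers=layers, classes=classes, units=units, scaling=scaling)


def write_occurrences(occ: OccurrenceSet, path: Path) -> None:
    occ.points.to_csv(path, index=False)


def read_occurrences(path: Path) -> OccurrenceSet:
    df = pd.read_csv(path)
    bad = df.index[~df["label"].isin([0, 1])]
    if len(bad):
        raise ValueError(f"label outside {{0,1}} at row {int(bad[0])}")
    return OccurrenceSet(df)


def write_polygons(polys: list, path: Path) -> None:
    gj = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"id": i}, "geometry": mapping(p)}
            for i, p in enumerate(polys)
        ],
    }
    Path(path).write_text(json.dumps(gj))


def read_polygons(path: Path) -> list:
    gj = json.loads(Path(path).read_text())
    return [shape(f["geometry"]) for f in gj["features"]]


def write_mesh(mesh: Mesh, path: Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "vertices": mesh.vertices.tolist(),
                "triangles": mesh.triangles.tolist(),
                "boundary": mesh.boundary.astype(int).tolist(),
            }
        )
    )


def read_mesh(path: Path) -> Mesh:
    d = json.loads(Path(path).read_text())
    return Mesh(
        np.array(d["vertices"], dtype=float),
        np.array(d["triangles"], dtype=int),
        np.array(d["boundary"], dtype=bool),
    )


def write_fit_summary(fit: PosteriorFit, path: Path) -> None:
    """JSON posterior summary: coefficients, hyperparameters, WAIC, field."""
    out = {
        "formula": fit.spec.formula,
        "covariates": list(fit.spec.covariates),
        "include_rf": fit.spec.include_rf,
        "include_nn": fit.spec.include_nn,
        "beta": fit.beta.round(10).to_dict(orient="index"),
        "hyperparameters": fit.hyperparameters,
        "waic": fit.waic,
        "p_waic": fit.p_waic,
        "lppd": fit.lppd,
        "log_marginal": fit.log_marginal,
        "iterations": fit.iterations,
        "seed": fit.seed,
        "method": fit.method,
        "field_mean": None if fit.field_mean is None else np.round(fit.field_mean, 10).tolist(),
        "field_sd": None if fit.field_sd is None else np.round(fit.field_sd, 10).tolist(),
        "scaling": fit.scaling,
    }
    Path(path).write_text(json.dumps(out, indent=1))
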