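"""Readers, writers, manifests and reporting.

Formats are deliberately plain: GeoJSON for the vector parts of an
urban model (building polygons, destination points, road centrelines),
ESRI ASCII grid for rasters (integer land-use codes or float fields),
CSV for metrics and JSON for run manifests.  All writes are atomic
(write to a temporary file in the target directory, then rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, mapping, shape

from evacsim.engine import EnsembleResult, summarise
from evacsim.urban import ROAD, CityParams, UrbanModel


def _atomic_write(path: Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_ascii_grid(
    path: str | Path,
    array: np.ndarray,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    cellsize: float = 1.0,
    nodata: float = -9999,
) -> None:
    """Write a raster as an ESRI ASCII grid (row 0 of the array = south)."""
    a = np.asarray(array)
    header = (
        f"ncols {a.shape[1]}\nnrows {a.shape[0]}\n"
        f"xllcorner {xllcorner}\nyllcorner {yllcorner}\n"
        f"cellsize {cellsize}\nNODATA_value {nodata}\n"
    )
    body = "\n".join(" ".join(str(v) for v in row) for row in np.flipud(a))
    _atomic_write(Path(path), header + body + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array with row 0 = south, header)."""
    lines = Path(path).read_text().splitlines()
    header: dict = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    ):
        key, val = lines[i].split()[:2]
        header[key.lower()] = float(val)
        i += 1
    data = np.loadtxt(lines[i:], ndmin=2)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid body does not match its declared shape")
    return np.flipud(data), header


def _feature_collection(geoms, props=None) -> dict:
    feats = []
    for k, g in enumerate(geoms):
        p = props[k] if props else {}
        feats.append({"type": "Feature", "geometry": mapping(g), "properties": p})
    return {"type": "FeatureCollection", "features": feats}


def write_urban(model: UrbanModel, outdir: str | Path) -> None:
    """Serialise an urban model: GeoJSON vectors + ASCII land-use raster + meta."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _atomic_write(out / "buildings.geojson", json.dumps(_feature_collection(model.buildings)))
    from shapely.geometry import Point

    _atomic_write(
        out / "destinations.geojson",
        json.dumps(_feature_collection([Point(xy) for xy in model.destinations])),
    )
    _atomic_write(out / "roads.geojson", json.dumps(_feature_collection(model.road_lines)))
    write_ascii_grid(
        out / "landuse.asc",
        model.landuse.astype(int),
        xllcorner=model.bounds[0],
        yllcorner=model.bounds[1],
        cellsize=model.resolution,
    )
    meta = {
        "bounds": list(model.bounds),
        "resolution": model.resolution,
        "coast_side": model.coast_side,
        "style": model.style,
        "road_width": model.params.road_width if model.params else None,
        "inundation_depth_fraction": (
            model.params.inundation_depth_fraction if model.params else 0.5
        ),
        "params": _params_dict(model.params) if model.params else None,
    }
    _atomic_write(out / "meta.json", json.dumps(meta, indent=2))


def _params_dict(p: CityParams) -> dict:
    return {
        k: getattr(p, k)
        for k in (
            "style", "extent", "resolution", "coast_side", "road_width",
            "street_spacing", "branch_count", "branch_angle",
            "building_coverage", "n_destinations", "inundation_depth_fraction", "seed",
        )
    }


def read_urban(indir: str | Path) -> UrbanModel:
    """Load an urban model written by :func:`write_urban`, validating invariants."""
    ind = Path(indir)
    for name in ("buildings.geojson", "destinations.geojson", "roads.geojson",
                 "landuse.asc", "meta.json"):
        if not (ind / name).exists():
            raise FileNotFoundError(f"missing urban model file: {name}")
    meta = json.loads((ind / "meta.json").read_text())
    landuse, header = read_ascii_grid(ind / "landuse.asc")
    bounds = tuple(meta["bounds"])
    res = float(meta["resolution"])
    if abs(header["cellsize"] - res) > 1e-9:
        raise ValueError("raster cell size disagrees with model metadata")
    nx = int(round((bounds[2] - bounds[0]) / res))
    ny = int(round((bounds[3] - bounds[1]) / res))
    if landuse.shape != (ny, nx):
        raise ValueError("raster bounds disagree with vector bounds")

    def load_geoms(name):
        fc = json.loads((ind / name).read_text())
        return [shape(f["geometry"]) for f in fc["features"]]

    buildings = load_geoms("buildings.geojson")
    dest_pts = load_geoms("destinations.geojson")
    roads = load_geoms("roads.geojson")
    params = CityParams(**meta["params"]) if meta.get("params") else None
    model = UrbanModel(
        bounds=bounds,
        resolution=res,
        landuse=landuse.astype(np.uint8),
        buildings=buildings,
        destinations=np.array([[p.x, p.y] for p in dest_pts]),
        road_lines=[LineString(r) for r in roads],
        coast_side=meta.get("coast_side", "S"),
        style=meta.get("style"),
        params=params,
    )
    model.validate()
    return model


def write_manifest(path: str | Path, config_snapshot: dict, master_seed: int,
                   run_seeds: list[int] | None = None) -> None:
    """JSON run manifest: everything needed to reproduce a run bit-for-bit."""
    from evacsim import __version__

    _atomic_write(
        Path(path),
        json.dumps(
            {
                "software": "evacsim",
                "version": __version__,
                "timestamp": datetime.now(timezone.utc).isoformat(),
                "master_seed": master_seed,
                "run_seeds": run_seeds,
                "config": config_snapshot,
            },
            indent=2,
            default=str,
        ),
    )


def report(ensembles: dict[str, EnsembleResult], outdir: str | Path) -> pd.DataFrame:
    """Summary table + box plot for a set of named ensembles.

    Box convention: median line, box at the quartiles (linear
    interpolation), whiskers at the most extreme data within 1.5 x IQR,
    fliers beyond.  Writes ``summary.csv`` and ``completion_box.png``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, ens in ensembles.items():
        s = summarise(ens.completions)
        s["ensemble"] = name
        rows.append(s)
    df = pd.DataFrame(rows).set_index("ensemble")
    df.drop(columns="fliers").to_csv(out / "summary.csv")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(ensembles), 4))
    ax.boxplot(
        [ens.completions for ens in ensembles.values()],
        tick_labels=list(ensembles),
        whis=1.5,
    )
    ax.set_ylabel("evacuation completion ratio")
    fig.tight_layout()
    fig.savefig(out / "completion_box.png", dpi=150)
    plt.close(fig)
    return df
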