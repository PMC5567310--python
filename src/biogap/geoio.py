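"""Plain-text geospatial I/O: GeoJSON feature collections, ESRI ASCII grids, occurrence CSVs.

All coordinates are planar kilometres on a synthetic extent; no CRS handling
is performed (or needed) here. Geometries are shapely objects.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

OCCURRENCE_COLUMNS = ["species_id", "x", "y", "year"]


def read_occurrences(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in OCCURRENCE_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence file {path} lacks columns {missing}")
    if "year" not in df.columns:
        df["year"] = pd.NA
    if not np.isfinite(df[["x", "y"]].to_numpy(float)).all():
        raise ValueError("non-finite occurrence coordinates")
    return df[OCCURRENCE_COLUMNS]


def write_occurrences(df: pd.DataFrame, path: str | Path) -> None:
    df[OCCURRENCE_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def write_geojson(
    geometries: Sequence[BaseGeometry],
    properties: Sequence[Mapping] | None,
    path: str | Path,
) -> None:
    """Write geometries + per-feature property dicts as a GeoJSON FeatureCollection."""
    props = properties if properties is not None else [{} for _ in geometries]
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": dict(p)}
        for g, p in zip(geometries, props, strict=True)
    ]
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload, sort_keys=True) + "\n")


def read_geojson(path: str | Path) -> tuple[list[BaseGeometry], list[dict]]:
    payload = json.loads(Path(path).read_text())
    geoms, props = [], []
    for feat in payload["features"]:
        geoms.append(shape(feat["geometry"]))
        props.append(feat.get("properties", {}) or {})
    return geoms, props


def write_ascii_grid(
    array: np.ndarray,
    path: str | Path,
    xllcorner: float,
    yllcorner: float,
    cellsize: float,
    nodata: float = -9999.0,
) -> None:
    """Write a 2-D array (row 0 = northernmost) as an ESRI ASCII grid."""
    arr = np.asarray(array, dtype=float)
    if arr.ndim != 2:
        raise ValueError("ASCII grids are 2-D")
    out = np.where(np.isfinite(arr), arr, nodata)
    header = (
        f"ncols {arr.shape[1]}\n"
        f"nrows {arr.shape[0]}\n"
        f"xllcorner {xllcorner:.6f}\n"
        f"yllcorner {yllcorner:.6f}\n"
        f"cellsize {cellsize:.6f}\n"
        f"NODATA_value {nodata:.1f}\n"
    )
    body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in out)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in {
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    }:
        key, val = lines[i].split()
        header[key.lower()] = float(val)
        i += 1
    arr = np.loadtxt(lines[i:], dtype=float)
    arr = arr.reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value")
    if nodata is not None:
        arr = np.where(arr == nodata, np.nan, arr)
    return arr, header


def points_array(x: Iterable[float], y: Iterable[float]) -> np.ndarray:
    """Vectorised shapely point construction."""
    return shapely.points(np.column_stack([np.asarray(x, float), np.asarray(y, float)]))
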