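"""Hexagonal gridding, point assignment, buffer/density measures and the
sampling-effort surface.

The grid uses flat-top hexagons whose *diameter* (corner-to-corner width)
defaults to 55 km, the approximate ground distance of 0.5 degrees of arc —
the sampling-unit size the endemism indices are defined on. All geometry is
planar (km / km^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, box
from shapely.strtree import STRtree

from .geoio import points_array

EPSILON = 1e-5  #: open-interval clamp used by the effort/endemism indices

DENSITY_BINS = [0.0, 0.01, 0.1, 1.0, 10.0]
DENSITY_LABELS = ["[0]", "(0,0.01]", "(0.01,0.1]", "(0.1,1]", "(1,10]", "(10,130+]"]


@dataclass(frozen=True)
class PAUnit:
    """A protected area: polygon + management category + designation year."""

    id: str
    polygon: Polygon
    category: str  # one of CATEGORIES
    year_designated: int
    biome_id: int | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown PA category {self.category!r}")
        if not self.polygon.is_valid:
            raise ValueError(f"PA {self.id}: invalid polygon")


CATEGORIES = ("strict", "sustainable", "indigenous")


@dataclass
class HexGrid:
    """Flat-top hexagonal tessellation of a rectangular extent.

    Cell ids are row-major (south-to-north rows, west-to-east within a row)
    and stable for a given extent + diameter.
    """

    extent: tuple[float, float, float, float]
    diameter: float
    polygons: np.ndarray = field(repr=False)  # shapely Polygon array
    centroids: np.ndarray = field(repr=False)  # (n, 2)
    _tree: STRtree = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.polygons)

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(len(self.polygons))

    def tree(self) -> STRtree:
        if self._tree is None:
            self._tree = STRtree(self.polygons)
        return self._tree

    def assign_points(self, x, y) -> np.ndarray:
        """Cell id for each point; boundary points go to the lowest touching id."""
        pts = points_array(x, y)
        pairs = self.tree().query(pts, predicate="intersects")
        cell_of = np.full(len(pts), -1, dtype=int)
        for p_idx, c_idx in zip(*pairs):
            if cell_of[p_idx] == -1 or c_idx < cell_of[p_idx]:
                cell_of[p_idx] = c_idx
        bad = np.flatnonzero(cell_of < 0)
        if bad.size:
            i = bad[0]
            raise ValueError(
                f"record {i} at ({np.asarray(x, float)[i]:.3f}, "
                f"{np.asarray(y, float)[i]:.3f}) falls outside the grid"
            )
        return cell_of

    def cells_intersecting(self, geometry) -> np.ndarray:
        """Ids of cells whose interior overlaps the geometry (positive area)."""
        cand = self.tree().query(geometry, predicate="intersects")
        keep = [
            int(c)
            for c in cand
            if shapely.intersection(self.polygons[c], geometry).area > 1e-12
        ]
        return np.array(sorted(keep), dtype=int)


def build_hex_grid(extent: tuple[float, float, float, float], diameter: float) -> HexGrid:
    """Tile ``extent`` with flat-top hexagons of corner-to-corner ``diameter``."""
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("empty extent")
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if diameter > 2 * max(xmax - xmin, ymax - ymin):
        raise ValueError("hexagon diameter exceeds the extent dimensions")
    R = diameter / 2.0
    dy = np.sqrt(3.0) * R
    angles = np.deg2rad(np.arange(0, 360, 60))
    ux, uy = R * np.cos(angles), R * np.sin(angles)

    cells = []
    col = -1
    while True:
        cx = xmin + col * 1.5 * R
        if cx - R > xmax:
            break
        y_off = (dy / 2.0) if (col % 2) else 0.0
        row = -1
        while True:
            cy = ymin + row * dy + y_off
            if cy - dy / 2.0 > ymax:
                break
            if cx + R >= xmin and cy + dy / 2.0 >= ymin:
                cells.append((cy, cx, Polygon(zip(cx + ux, cy + uy))))
            row += 1
        col += 1

    extent_box = box(*extent)
    kept = [
        (cy, cx, poly)
        for cy, cx, poly in cells
        if shapely.intersection(poly, extent_box).area > 1e-12
    ]
    kept.sort(key=lambda t: (round(t[0], 9), round(t[1], 9)))
    polys = np.array([p for _, _, p in kept], dtype=object)
    cents = np.array([(cx, cy) for cy, cx, _ in kept], dtype=float)
    return HexGrid(extent=extent, diameter=diameter, polygons=polys, centroids=cents)


def assign_to_cells(
    occurrences: pd.DataFrame, grid: HexGrid
) -> tuple[dict[str, frozenset[int]], pd.Series]:
    """Map records to hexagons.

    Returns (species -> occupied cell-id set, per-cell record counts indexed
    by cell id). Every record is assigned to exactly one cell.
    """
    cell_of = grid.assign_points(occurrences["x"].to_numpy(), occurrences["y"].to_numpy())
    df = occurrences.assign(cell=cell_of)
    ranges = {
        sp: frozenset(int(c) for c in grp["cell"].unique())
        for sp, grp in df.groupby("species_id", sort=True)
    }
    counts = df.groupby("cell").size()
    counts.index.name = "cell_id"
    return ranges, counts


def sampled_area_fraction(
    pa: PAUnit | Polygon, occurrences: pd.DataFrame, radius: float = 1.0
) -> float:
    """Share of a PA's area within ``radius`` km of any occurrence record.

    The 1-km default reflects the typical maximum distance between a
    collection event and its recorded coordinate.
    """
    polygon = pa.polygon if isinstance(pa, PAUnit) else pa
    if radius <= 0:
        raise ValueError("radius must be positive")
    if polygon.area <= 0:
        raise ValueError("zero-area protected area")
    if len(occurrences) == 0:
        return 0.0
    pts = points_array(occurrences["x"], occurrences["y"])
    # only records near the PA can contribute to the buffered union
    near = shapely.dwithin(pts, polygon, radius)
    if not near.any():
        return 0.0
    buffers = shapely.buffer(pts[near], radius, quad_segs=32)
    covered = shapely.intersection(shapely.union_all(buffers), polygon)
    return float(covered.area / polygon.area)


def record_density(occurrences: pd.DataFrame, region: Polygon) -> float:
    """Records per km^2 inside ``region``."""
    if region.area <= 0:
        raise ValueError("region must have positive area")
    if len(occurrences) == 0:
        return 0.0
    pts = points_array(occurrences["x"], occurrences["y"])
    inside = shapely.covers(region, pts)
    return float(inside.sum() / region.area)


def density_class(density: float) -> str:
    """Ordered density bin label; bins follow decade steps up to the
    empirical ceiling of ~130 records per km^2."""
    if density < 0:
        raise ValueError("density must be nonnegative")
    if density == 0:
        return DENSITY_LABELS[0]
    idx = int(np.searchsorted(DENSITY_BINS[1:], density, side="left"))
    return DENSITY_LABELS[idx + 1]


@dataclass
class EffortSurface:
    """Sampling-effort estimates from 50-km disc record counts.

    ``raw`` effort at a record is the count of records (any species) within
    ``radius``, divided by the disc area. Species effort is the mean over the
    species' records, normalised by the maximum across species and clamped
    to the open interval (EPSILON, 1 - EPSILON) — the correction index is
    undefined at 0 and 1 exactly.
    """

    radius: float
    per_record_raw: np.ndarray
    species_raw: pd.Series
    species_effort: pd.Series  # normalised, clamped
    cell_effort: pd.Series | None = None


def effort_surface(
    occurrences: pd.DataFrame,
    radius: float = 50.0,
    grid: HexGrid | None = None,
    epsilon: float = EPSILON,
) -> EffortSurface:
    if len(occurrences) == 0:
        raise ValueError("effort surface needs at least one occurrence")
    xy = occurrences[["x", "y"]].to_numpy(float)
    tree = cKDTree(xy)
    counts = np.array([len(n) for n in tree.query_ball_point(xy, r=radius)])
    disc_area = np.pi * radius**2
    raw = counts / disc_area
    species_raw = (
        pd.Series(raw, index=occurrences["species_id"].to_numpy())
        .groupby(level=0)
        .mean()
        .sort_index()
    )
    norm = species_raw / species_raw.max()
    species_effort = norm.clip(lower=epsilon, upper=1.0 - epsilon)

    cell_effort = None
    if grid is not None:
        ccounts = np.array(
            [len(n) for n in tree.query_ball_point(grid.centroids, r=radius)]
        )
        craw = ccounts / disc_area
        cmax = craw.max()
        if cmax > 0:
            craw = craw / cmax
        cell_effort = pd.Series(
            np.clip(craw, epsilon, 1.0 - epsilon), index=grid.cell_ids
        )
    return EffortSurface(
        radius=radius,
        per_record_raw=raw,
        species_raw=species_raw,
        species_effort=species_effort,
        cell_effort=cell_effort,
    )


def pa_density_table(
    pas: Sequence[PAUnit], occurrences: pd.DataFrame, buffer_radius: float = 1.0
) -> pd.DataFrame:
    """Per-PA record density, density class and 1-km-buffer sampled fraction."""
    rows = []
    for pa in pas:
        dens = record_density(occurrences, pa.polygon)
        rows.append(
            {
                "pa_id": pa.id,
                "category": pa.category,
                "year": pa.year_designated,
                "area_km2": pa.polygon.area,
                "density": dens,
                "density_class": density_class(dens),
                "sampled_fraction": sampled_area_fraction(
                    pa, occurrences, radius=buffer_radius
                ),
            }
        )
    return pd.DataFrame(rows)
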