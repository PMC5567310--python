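"""Synthetic landscapes with known ground truth.

The generator emulates the statistical structure a national occurrence
database exhibits, without any real geography: spatially clustered
collection effort (a few intense hotspots over a uniform floor), species
with heavy-tailed range sizes and record counts (many species with fewer
than 15 records, a rare tail beyond 150), three protected-area categories
designated between 1903 and 2016, a biome partition with uneven PA
coverage, 21 spatially autocorrelated environmental layers, and a random
unit-branch-length phylogeny over the species. Because ranges, protection
fractions and the generating tree are all retained as ground truth, every
downstream estimate can be checked against what the world actually
contains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, box
from shapely.ops import voronoi_diagram

from . import phylo
from .geoio import write_geojson, write_occurrences
from .sdm import EnvStack
from .spatial_core import CATEGORIES, PAUnit


class InfeasibleGeometryError(ValueError):
    """Requested protected areas cannot fit in the extent."""


class ScenarioTargetError(ValueError):
    """A scenario's protection target is unreachable under the PA layout."""


@dataclass
class WorldConfig:
    """Knobs of the synthetic world; defaults are the study conditions.

    The extent is a planar 500x500 km rectangle; record counts follow a
    log-normal law (median ~8, sigma 1.4) truncated at 1, giving many
    species under 15 records and an occasional tail past 150; effort is a
    mixture of Gaussian hotspots over a uniform floor; 21 environmental
    layers (19 climate-like + 2 terrain-like) at 5-km resolution.
    """

    extent: tuple[float, float, float, float] = (0.0, 0.0, 500.0, 500.0)
    n_biomes: int = 6
    n_pas_per_category: tuple[int, int, int] = (6, 6, 6)
    pa_year_range: tuple[int, int] = (1903, 2016)
    n_species: int = 80
    records_median: float = 8.0
    records_sigma: float = 1.4
    effort_hotspots: int = 5
    hotspot_intensity: float = 9.0
    hotspot_sd: float = 40.0
    n_env_layers: int = 21
    env_cellsize: float = 5.0
    range_radius_log_mean: float = np.log(35.0)
    range_radius_log_sigma: float = 0.5
    full_extent_ranges: bool = False  # diagnostic worlds: every range = extent
    seed: int = 0

    def __post_init__(self):
        xmin, ymin, xmax, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("extent must have positive area")
        for name in ("n_biomes", "n_species", "n_env_layers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if any(n < 0 for n in self.n_pas_per_category):
            raise ValueError("PA counts must be nonnegative")


@dataclass
class WorldTruth:
    true_range: dict[str, shapely.Geometry]
    true_fraction_inside_pa: dict[str, float]
    true_tree: "phylo.dendropy.Tree"
    effort_raster: np.ndarray
    species_outside_pa: list[str] | None = None


@dataclass
class World:
    config: WorldConfig
    occurrences: pd.DataFrame
    pas: list[PAUnit]
    biomes: list[tuple[int, shapely.Geometry]]
    env: EnvStack
    tree: "phylo.dendropy.Tree"
    truth: WorldTruth

    def to_files(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_occurrences(self.occurrences, d / "occurrences.csv")
        write_geojson(
            [pa.polygon for pa in self.pas],
            [
                {
                    "id": pa.id,
                    "category": pa.category,
                    "year": pa.year_designated,
                    "biome": pa.biome_id,
                }
                for pa in self.pas
            ],
            d / "pas.geojson",
        )
        write_geojson(
            [g for _, g in self.biomes],
            [{"biome_id": i} for i, _ in self.biomes],
            d / "biomes.geojson",
        )
        self.env.write(d)
        (d / "tree.nwk").write_text(phylo.write_newick(self.tree) + "\n")
        truth = {
            "true_fraction_inside_pa": {
                k: round(v, 9)
                for k, v in sorted(self.truth.true_fraction_inside_pa.items())
            },
            "species_outside_pa": self.truth.species_outside_pa,
        }
        (d / "truth.json").write_text(json.dumps(truth, sort_keys=True, indent=1))


# ---------------------------------------------------------------------------
# building blocks


def sample_record_counts(
    rng: np.random.Generator, n: int, median: float = 8.0, sigma: float = 1.4
) -> np.ndarray:
    """Heavy-tailed per-species record counts: rounded log-normal, min 1."""
    raw = rng.lognormal(mean=np.log(median), sigma=sigma, size=n)
    return np.maximum(1, np.round(raw)).astype(int)


def _grid_coords(config: WorldConfig):
    xmin, ymin, xmax, ymax = config.extent
    nc = int(np.ceil((xmax - xmin) / config.env_cellsize))
    nr = int(np.ceil((ymax - ymin) / config.env_cellsize))
    xs = xmin + (np.arange(nc) + 0.5) * config.env_cellsize
    ys = ymin + (nr - 1 - np.arange(nr) + 0.5) * config.env_cellsize
    return nr, nc, xs, ys


def make_env_stack(config: WorldConfig, rng: np.random.Generator) -> EnvStack:
    """Spatially autocorrelated layers; two carry broad geographic gradients
    (temperature-like), the last two are terrain analogues (elevation and its
    local slope)."""
    nr, nc, xs, ys = _grid_coords(config)
    gx, gy = np.meshgrid(
        (xs - xs.mean()) / max(np.ptp(xs), 1e-9),
        (ys - ys.mean()) / max(np.ptp(ys), 1e-9),
    )
    layers = []
    for i in range(config.n_env_layers):
        noise = gaussian_filter(rng.standard_normal((nr, nc)), sigma=6, mode="nearest")
        if i == 0:
            layer = 2.0 * gy + noise
        elif i == 1:
            layer = 2.0 * gx + noise
        elif i == config.n_env_layers - 2:  # elevation analogue
            layer = gaussian_filter(
                rng.standard_normal((nr, nc)), sigma=10, mode="nearest"
            ) + 0.5 * (gx + gy)
        elif i == config.n_env_layers - 1:  # slope analogue
            dyy, dxx = np.gradient(layers[-1])
            layer = np.hypot(dxx, dyy)
        else:
            layer = noise
        sd = layer.std()
        layers.append((layer - layer.mean()) / (sd if sd > 0 else 1.0))
    names = [f"bio{i + 1:02d}" for i in range(config.n_env_layers - 2)]
    names += ["elev", "slope"]
    return EnvStack(
        data=np.stack(layers),
        names=names,
        xmin=config.extent[0],
        ymin=config.extent[1],
        cellsize=config.env_cellsize,
    )


def make_effort_raster(config: WorldConfig, rng: np.random.Generator) -> np.ndarray:
    """Sampling-effort surface in (0, 1]: Gaussian hotspots + uniform floor."""
    nr, nc, xs, ys = _grid_coords(config)
    gx, gy = np.meshgrid(xs, ys)
    surface = np.ones((nr, nc))
    xmin, ymin, xmax, ymax = config.extent
    for _ in range(config.effort_hotspots):
        hx = rng.uniform(xmin, xmax)
        hy = rng.uniform(ymin, ymax)
        d2 = (gx - hx) ** 2 + (gy - hy) ** 2
        surface += config.hotspot_intensity * np.exp(-d2 / (2 * config.hotspot_sd**2))
    return surface / surface.max()


def make_biomes(
    config: WorldConfig, rng: np.random.Generator
) -> list[tuple[int, shapely.Geometry]]:
    """Voronoi partition of the extent from random biome seed points."""
    xmin, ymin, xmax, ymax = config.extent
    extent_box = box(*config.extent)
    if config.n_biomes == 1:
        return [(0, extent_box)]
    seeds = [
        Point(rng.uniform(xmin, xmax), rng.uniform(ymin, ymax))
        for _ in range(config.n_biomes)
    ]
    regions = voronoi_diagram(
        shapely.geometrycollections([shapely.points(p.x, p.y) for p in seeds]),
        envelope=extent_box,
    )
    out = []
    for i, seed_pt in enumerate(seeds):
        region = next(
            g for g in regions.geoms if g.covers(seed_pt)
        ).intersection(extent_box)
        out.append((i, region))
    return out


def make_pas(
    config: WorldConfig,
    rng: np.random.Generator,
    biomes: list[tuple[int, shapely.Geometry]],
) -> list[PAUnit]:
    """Rectangular protected areas with random size, category and year."""
    xmin, ymin, xmax, ymax = config.extent
    w_ext, h_ext = xmax - xmin, ymax - ymin
    pas: list[PAUnit] = []
    total_area = 0.0
    y0, y1 = config.pa_year_range
    for cat, n_cat in zip(CATEGORIES, config.n_pas_per_category):
        for i in range(n_cat):
            w = rng.uniform(0.05, 0.18) * w_ext
            h = rng.uniform(0.05, 0.18) * h_ext
            x = rng.uniform(xmin, xmax - w)
            y = rng.uniform(ymin, ymax - h)
            poly = box(x, y, x + w, y + h)
            total_area += poly.area
            centroid = poly.centroid
            biome_id = next(
                (bid for bid, g in biomes if g.covers(centroid)), None
            )
            pas.append(
                PAUnit(
                    id=f"{cat}_{i:02d}",
                    polygon=poly,
                    category=cat,
                    year_designated=int(rng.integers(y0, y1 + 1)),
                    biome_id=biome_id,
                )
            )
    if total_area > 0.6 * w_ext * h_ext:
        raise InfeasibleGeometryError(
            f"requested PAs cover {total_area:.0f} km2, more than 60% of the extent"
        )
    return pas


def _sample_range(
    config: WorldConfig, rng: np.random.Generator
) -> shapely.Geometry:
    xmin, ymin, xmax, ymax = config.extent
    extent_box = box(*config.extent)
    if config.full_extent_ranges:
        return extent_box
    n_centers = rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1])
    radius = float(
        np.clip(
            rng.lognormal(config.range_radius_log_mean, config.range_radius_log_sigma),
            10.0,
            120.0,
        )
    )
    cx = rng.uniform(xmin, xmax)
    cy = rng.uniform(ymin, ymax)
    discs = [Point(cx, cy).buffer(radius, quad_segs=16)]
    for _ in range(n_centers - 1):
        ox = cx + rng.normal(0, 1.5 * radius)
        oy = cy + rng.normal(0, 1.5 * radius)
        discs.append(Point(ox, oy).buffer(radius * rng.uniform(0.4, 1.0), quad_segs=16))
    rng_poly = shapely.union_all(discs).intersection(extent_box)
    if rng_poly.area <= 0:  # pathological clip; fall back to the first disc
        rng_poly = discs[0].intersection(extent_box)
    return rng_poly


def _effort_at(
    effort: np.ndarray, config: WorldConfig, x: np.ndarray, y: np.ndarray
) -> np.ndarray:
    nr, nc = effort.shape
    xmin, ymin = config.extent[0], config.extent[1]
    col = np.clip(((x - xmin) / config.env_cellsize).astype(int), 0, nc - 1)
    row = np.clip((nr - 1 - (y - ymin) / config.env_cellsize).astype(int), 0, nr - 1)
    return effort[row, col]


def _sample_points_in(
    polygon: shapely.Geometry,
    n: int,
    rng: np.random.Generator,
    effort: np.ndarray | None,
    config: WorldConfig,
    max_rounds: int = 500,
) -> np.ndarray:
    """Uniform points in a polygon, thinned by the effort surface when given."""
    xmin, ymin, xmax, ymax = polygon.bounds
    got: list[np.ndarray] = []
    n_got = 0
    for round_i in range(max_rounds):
        m = max(32, 4 * (n - n_got))
        x = rng.uniform(xmin, xmax, m)
        y = rng.uniform(ymin, ymax, m)
        inside = shapely.covers(polygon, shapely.points(np.column_stack([x, y])))
        x, y = x[inside], y[inside]
        if effort is not None and len(x):
            keep = rng.random(len(x)) < _effort_at(effort, config, x, y)
            x, y = x[keep], y[keep]
        if len(x):
            got.append(np.column_stack([x, y]))
            n_got += len(x)
        if n_got >= n:
            break
    else:
        # effort floor too low to fill the quota; top up uniformly in-range
        while n_got < n:
            x = rng.uniform(xmin, xmax, 256)
            y = rng.uniform(ymin, ymax, 256)
            inside = shapely.covers(
                polygon, shapely.points(np.column_stack([x, y]))
            )
            if inside.any():
                got.append(np.column_stack([x[inside], y[inside]]))
                n_got += int(inside.sum())
    return np.vstack(got)[:n]


def random_unit_tree(labels: list[str], rng: np.random.Generator):
    """Random binary topology by successive joins; unit branch lengths."""
    items = [lbl for lbl in labels]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        items.append(f"({a},{b})")
    tree = phylo.read_newick(items[0] + ";")
    return phylo.unit_branch_lengths(tree)


# ---------------------------------------------------------------------------
# world assembly


def generate_world(config: WorldConfig) -> World:
    rng = np.random.default_rng(config.seed)
    biomes = make_biomes(config, rng)
    env = make_env_stack(config, rng)
    effort = make_effort_raster(config, rng)
    pas = make_pas(config, rng, biomes)
    species_ids = [f"sp{i:04d}" for i in range(config.n_species)]
    counts = sample_record_counts(
        rng, config.n_species, config.records_median, config.records_sigma
    )
    ranges = {sp: _sample_range(config, rng) for sp in species_ids}
    occ = _draw_occurrences(species_ids, counts, ranges, effort, config, rng)
    tree = random_unit_tree(species_ids, rng)
    truth = _build_truth(ranges, pas, tree, effort)
    return World(
        config=config,
        occurrences=occ,
        pas=pas,
        biomes=biomes,
        env=env,
        tree=tree,
        truth=truth,
    )


def _draw_occurrences(species_ids, counts, ranges, effort, config, rng):
    rows = []
    for sp, n in zip(species_ids, counts):
        pts = _sample_points_in(ranges[sp], int(n), rng, effort, config)
        years = rng.integers(1950, 2017, size=len(pts))
        for (x, y), yr in zip(pts, years):
            rows.append((sp, float(x), float(y), int(yr)))
    return pd.DataFrame(rows, columns=["species_id", "x", "y", "year"])


def _build_truth(ranges, pas, tree, effort) -> WorldTruth:
    pa_union = shapely.union_all([pa.polygon for pa in pas]) if pas else None
    fractions = {}
    for sp, rng_poly in ranges.items():
        if pa_union is None or pa_union.is_empty:
            fractions[sp] = 0.0
        else:
            fractions[sp] = float(
                rng_poly.intersection(pa_union).area / rng_poly.area
            )
    return WorldTruth(
        true_range=dict(ranges),
        true_fraction_inside_pa=fractions,
        true_tree=tree,
        effort_raster=effort,
    )


def scenario_gap(config: WorldConfig, target_outside_fraction: float) -> World:
    """A world in which a known fraction of species lies wholly outside PAs.

    ``round(target * n_species)`` species get ranges disjoint from every PA
    (so none of their records can be protected); the rest get ranges that
    overlap a PA and have their first record drawn inside that overlap, so
    record-based protection accounting reproduces the range-based truth
    exactly. Raises ScenarioTargetError when the PA layout leaves no room.
    """
    if not (0.0 < target_outside_fraction < 1.0):
        raise ValueError("target fraction must lie in (0, 1)")
    rng = np.random.default_rng(config.seed)
    biomes = make_biomes(config, rng)
    env = make_env_stack(config, rng)
    effort = make_effort_raster(config, rng)
    pas = make_pas(config, rng, biomes)
    if not pas:
        raise ScenarioTargetError("scenario requires at least one protected area")
    pa_union = shapely.union_all([pa.polygon for pa in pas])

    n_out = int(round(target_outside_fraction * config.n_species))
    species_ids = [f"sp{i:04d}" for i in range(config.n_species)]
    outside = set(rng.choice(config.n_species, size=n_out, replace=False).tolist())
    counts = sample_record_counts(
        rng, config.n_species, config.records_median, config.records_sigma
    )

    ranges: dict[str, shapely.Geometry] = {}
    rows = []
    for idx, (sp, n_rec) in enumerate(zip(species_ids, counts)):
        want_outside = idx in outside
        poly = _place_range(config, rng, pa_union, want_outside, sp)
        ranges[sp] = poly
        pts: list[np.ndarray] = []
        n_rec = int(n_rec)
        if not want_outside:
            overlap = poly.intersection(pa_union)
            pts.append(_sample_points_in(overlap, 1, rng, None, config))
            n_rec -= 1
        if n_rec > 0:
            pts.append(_sample_points_in(poly, n_rec, rng, effort, config))
        xy = np.vstack(pts)
        years = rng.integers(1950, 2017, size=len(xy))
        for (x, y), yr in zip(xy, years):
            rows.append((sp, float(x), float(y), int(yr)))
    occ = pd.DataFrame(rows, columns=["species_id", "x", "y", "year"])
    tree = random_unit_tree(species_ids, rng)
    truth = _build_truth(ranges, pas, tree, effort)
    truth.species_outside_pa = sorted(
        species_ids[i] for i in outside
    )
    return World(
        config=config,
        occurrences=occ,
        pas=pas,
        biomes=biomes,
        env=env,
        tree=tree,
        truth=truth,
    )


def _place_range(config, rng, pa_union, want_outside: bool, sp: str):
    xmin, ymin, xmax, ymax = config.extent
    extent_box = box(*config.extent)
    radius = float(
        np.clip(
            rng.lognormal(config.range_radius_log_mean, config.range_radius_log_sigma),
            10.0,
            120.0,
        )
    )
    for attempt in range(400):
        if attempt and attempt % 50 == 0:
            radius = max(5.0, 0.7 * radius)  # shrink to fit into gaps
        cx, cy = rng.uniform(xmin, xmax), rng.uniform(ymin, ymax)
        poly = Point(cx, cy).buffer(radius, quad_segs=16).intersection(extent_box)
        if poly.area <= 0:
            continue
        hits = poly.intersects(pa_union)
        if want_outside and not hits:
            return poly
        if not want_outside and hits and poly.intersection(pa_union).area > 1e-6:
            return poly
    raise ScenarioTargetError(
        f"could not place species {sp} {'outside' if want_outside else 'inside'}"
        " the PA layout after 400 attempts; the target fraction appears"
        " unreachable for this extent/PA configuration"
    )
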