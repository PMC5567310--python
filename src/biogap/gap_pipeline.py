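"""Protection accounting across biodiversity dimensions.

Combines the spatial, endemism, phylogenetic and SDM layers into a gap
report: how many species, how much lineage length, and what share of the
(phylogenetic) weighted endemism totals fall outside the protected-area
network — overall, per PA category, per biome, and cumulatively through
time as the network grew.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.stats import kruskal, mannwhitneyu

from . import endemism as endemism_mod
from . import phylo, sdm
from .spatial_core import (
    CATEGORIES,
    HexGrid,
    PAUnit,
    build_hex_grid,
    effort_surface,
    assign_to_cells,
    pa_density_table,
)
from .synthetic_data import World, WorldConfig, generate_world

log = logging.getLogger(__name__)

DEFAULT_EPOCHS = [(1903, 1950), (1951, 1980), (1981, 1990), (1991, 2000), (2001, 2016)]
UNPROTECTED = "unprotected"


@dataclass
class PipelineConfig:
    world: WorldConfig = field(default_factory=WorldConfig)
    hex_diameter: float = 55.0
    effort_radius: float = 50.0
    sampled_buffer_radius: float = 1.0
    epochs: list[tuple[int, int]] = field(default_factory=lambda: list(DEFAULT_EPOCHS))
    run_sdm: bool = False
    native_veg_removal: float = 0.2  # fraction of cells stripped of native vegetation
    sdm_algorithms: tuple[str, ...] = sdm.ALGORITHMS


# ---------------------------------------------------------------------------
# stratification


def _category_unions(pas: Sequence[PAUnit]) -> dict[str, shapely.Geometry]:
    return {
        cat: shapely.union_all([p.polygon for p in pas if p.category == cat])
        for cat in CATEGORIES
    }


def classify_points(x, y, pas: Sequence[PAUnit]) -> np.ndarray:
    """Stratum label per point; overlaps resolve strict > sustainable >
    indigenous (most restrictive designation wins)."""
    from .geoio import points_array

    pts = points_array(x, y)
    labels = np.full(len(pts), UNPROTECTED, dtype=object)
    unions = _category_unions(pas)
    unassigned = np.ones(len(pts), dtype=bool)
    for cat in CATEGORIES:  # precedence order
        geom = unions[cat]
        if geom.is_empty:
            continue
        hit = unassigned & shapely.covers(geom, pts)
        labels[hit] = cat
        unassigned &= ~hit
    return labels


def classify_cells(grid: HexGrid, pas: Sequence[PAUnit]) -> np.ndarray:
    """Stratum label per hexagon (positive-area overlap, same precedence)."""
    labels = np.full(len(grid), UNPROTECTED, dtype=object)
    unions = _category_unions(pas)
    for cat in reversed(CATEGORIES):  # apply low precedence first, overwrite later
        geom = unions[cat]
        if geom.is_empty:
            continue
        labels[grid.cells_intersecting(geom)] = cat
    return labels


# ---------------------------------------------------------------------------
# core accounting


def _partition_pct_outside(values: pd.Series, inside_cells: set[int]) -> float:
    total = float(values.sum())
    if total == 0:
        return 100.0
    outside = float(values[~values.index.isin(inside_cells)].sum())
    return 100.0 * outside / total


def protection_proportions(
    species_ranges: Mapping[str, frozenset[int]],
    endem: endemism_mod.EndemismTable,
    tree,
    grid: HexGrid,
    occurrences: pd.DataFrame,
    pas: Sequence[PAUnit],
) -> dict:
    """Outside-percentages for the four biodiversity dimensions.

    Species are protected when at least one record falls in a PA polygon;
    WE and PWE, being cell-valued, are partitioned over PA-overlapping
    hexagons; lineages by whether a branch's range touches a protected cell.
    """
    labels = classify_points(
        occurrences["x"].to_numpy(), occurrences["y"].to_numpy(), pas
    )
    occ = occurrences.assign(stratum=labels)
    n_species = occ["species_id"].nunique()
    inside_sp = set(occ.loc[occ["stratum"] != UNPROTECTED, "species_id"])
    pa_union = (
        shapely.union_all([p.polygon for p in pas])
        if pas
        else shapely.Polygon()
    )
    pa_cells = (
        set(grid.cells_intersecting(pa_union).tolist())
        if not pa_union.is_empty
        else set()
    )

    pwe_cells = phylo.pwe(tree, species_ranges)
    lp = phylo.lineage_protection(tree, species_ranges, pa_cells)

    core = {
        "n_species": int(n_species),
        "n_species_inside": len(inside_sp),
        "pct_species_outside": 100.0 * (n_species - len(inside_sp)) / n_species,
        "pct_lineage_length_outside": 100.0 * (1.0 - lp.length_proportion),
        "pct_lineage_count_outside": 100.0 * (1.0 - lp.count_proportion),
        "pct_we_sum_outside": _partition_pct_outside(endem.cells["we"], pa_cells),
        "pct_we_corrected_outside": _partition_pct_outside(
            endem.cells["we_corrected"], pa_cells
        ),
        "pct_pwe_sum_outside": _partition_pct_outside(pwe_cells, pa_cells),
    }
    by_category = {}
    for cat in CATEGORIES:
        sp_cat = set(occ.loc[occ["stratum"] == cat, "species_id"])
        by_category[cat] = {
            "n_species_inside": len(sp_cat),
            "pct_species_inside": 100.0 * len(sp_cat) / n_species,
        }
    return {"all": core, "by_category": by_category, "pa_cells": sorted(pa_cells)}


def biome_proportions(
    species_ranges, endem, tree, grid, occurrences, pas, biomes
) -> dict:
    """The same four-dimension accounting restricted to each biome."""
    out = {}
    cent_x, cent_y = grid.centroids[:, 0], grid.centroids[:, 1]
    pa_union = shapely.union_all([p.polygon for p in pas]) if pas else None
    pa_cells = (
        set(grid.cells_intersecting(pa_union).tolist())
        if pa_union is not None and not pa_union.is_empty
        else set()
    )
    pwe_cells = phylo.pwe(tree, species_ranges)
    labels = classify_points(
        occurrences["x"].to_numpy(), occurrences["y"].to_numpy(), pas
    )
    from .geoio import points_array

    occ_pts = points_array(occurrences["x"], occurrences["y"])
    for biome_id, geom in biomes:
        in_biome = shapely.covers(geom, occ_pts)
        occ_b = occurrences[in_biome]
        if occ_b.empty:
            continue
        sp_b = set(occ_b["species_id"])
        inside_b = set(occ_b.loc[labels[in_biome] != UNPROTECTED, "species_id"])
        cells_b = set(
            int(c)
            for c in grid.cell_ids[shapely.covers(geom, points_array(cent_x, cent_y))]
        )
        ranges_b = {
            sp: frozenset(cs & cells_b)
            for sp, cs in species_ranges.items()
            if cs & cells_b
        }
        lp = phylo.lineage_protection(tree, ranges_b, pa_cells & cells_b)
        we_b = endem.cells.loc[endem.cells.index.isin(cells_b), "we"]
        pwe_b = pwe_cells[pwe_cells.index.isin(cells_b)]
        out[int(biome_id)] = {
            "n_species": len(sp_b),
            "pct_species_outside": 100.0 * (len(sp_b) - len(inside_b)) / len(sp_b),
            "pct_lineage_length_outside": 100.0 * (1.0 - lp.length_proportion),
            "pct_we_sum_outside": _partition_pct_outside(we_b, pa_cells & cells_b),
            "pct_pwe_sum_outside": _partition_pct_outside(pwe_b, pa_cells & cells_b),
        }
    return out


# ---------------------------------------------------------------------------
# rank statistics on hexagon samples


def inside_outside_tests(cell_table: pd.DataFrame) -> dict:
    """Kruskal-Wallis on record density across strata (hexagons as sampling
    units) and Mann-Whitney on cell WE inside vs outside PAs."""
    out: dict = {}
    groups = [
        g["density"].to_numpy()
        for _, g in cell_table.groupby("stratum")
        if len(g) >= 2
    ]
    if len(groups) >= 2:
        if np.ptp(np.concatenate(groups)) == 0:
            out["kw_density"] = {"H": 0.0, "p": 1.0, "method": "degenerate"}
        else:
            h, p = kruskal(*groups)
            out["kw_density"] = {
                "H": float(h),
                "p": float(p),
                "method": "chi-square approximation, tie-corrected",
            }
    inside = cell_table.loc[cell_table["stratum"] != UNPROTECTED, "we"].to_numpy()
    outside = cell_table.loc[cell_table["stratum"] == UNPROTECTED, "we"].to_numpy()
    if len(inside) >= 2 and len(outside) >= 2:
        method = "exact" if min(len(inside), len(outside)) < 8 and not (
            np.ptp(np.r_[inside, outside]) == 0
        ) else "asymptotic"
        u, p = mannwhitneyu(inside, outside, alternative="two-sided", method=method)
        out["mw_we"] = {"U": float(u), "p": float(p), "method": method}
    return out


# ---------------------------------------------------------------------------
# accumulation through time


def accumulation_curves(
    pas: Sequence[PAUnit],
    species_ranges: Mapping[str, frozenset[int]],
    endem: endemism_mod.EndemismTable,
    tree,
    grid: HexGrid,
    occurrences: pd.DataFrame,
    epochs: Sequence[tuple[int, int]] = tuple(DEFAULT_EPOCHS),
) -> dict:
    """Cumulative protected species / WE / PWE / lineage length as PAs are
    added in designation order, with per-epoch slopes.

    Slopes are reported in degrees of the accumulation curve drawn on
    normalised axes: years mapped to 0-100 across the full period, each
    curve to percent of its final (all-PA) value; the per-epoch slope is the
    arctangent of a least-squares linear fit within the epoch.
    """
    if any(pa.year_designated is None for pa in pas):
        raise ValueError("every PA needs a designation year")
    from .geoio import points_array

    pts = points_array(occurrences["x"], occurrences["y"])
    per_pa = []
    for pa in sorted(pas, key=lambda p: (p.year_designated, p.id)):
        sp = set(occurrences.loc[shapely.covers(pa.polygon, pts), "species_id"])
        cells = set(grid.cells_intersecting(pa.polygon).tolist())
        per_pa.append((pa.year_designated, sp, cells))

    pwe_cells = phylo.pwe(tree, species_ranges)
    year_lo = min(e[0] for e in epochs)
    year_hi = max(e[1] for e in epochs)
    years = sorted({y for y, _, _ in per_pa})
    series = []
    sp_acc: set = set()
    cell_acc: set = set()
    for year in years:
        for y, sp, cells in per_pa:
            if y == year:
                sp_acc |= sp
                cell_acc |= cells
        lp = phylo.lineage_protection(tree, species_ranges, cell_acc)
        series.append(
            {
                "year": int(year),
                "species": len(sp_acc),
                "we": float(endem.cells.loc[endem.cells.index.isin(cell_acc), "we"].sum()),
                "pwe": float(pwe_cells[pwe_cells.index.isin(cell_acc)].sum()),
                "lineage_length": lp.length_proportion * lp.total_length,
            }
        )

    dims = ["species", "we", "pwe", "lineage_length"]
    finals = {d: (series[-1][d] if series else 0.0) for d in dims}
    yearly = {d: np.zeros(year_hi - year_lo + 1) for d in dims}
    grid_years = np.arange(year_lo, year_hi + 1)
    for rec in series:  # forward-fill the step function
        mask = grid_years >= rec["year"]
        for d in dims:
            yearly[d][mask] = rec[d]

    span = year_hi - year_lo
    slopes = {d: {} for d in dims}
    for d in dims:
        y_pct = (
            100.0 * yearly[d] / finals[d] if finals[d] > 0 else np.zeros_like(yearly[d])
        )
        x_norm = 100.0 * (grid_years - year_lo) / span
        for lo, hi in epochs:
            sel = (grid_years >= lo) & (grid_years <= hi)
            slope = float(np.polyfit(x_norm[sel], y_pct[sel], 1)[0])
            slopes[d][f"{lo}-{hi}"] = float(np.degrees(np.arctan(slope)))
    return {"series": series, "final": finals, "slopes_degrees": slopes}


# ---------------------------------------------------------------------------
# SDM stage


def sdm_stage(world: World, cfg: PipelineConfig, seed: int) -> dict:
    """Fit the SDM ensemble for adequately sampled species and measure how
    much of each predicted range the PA network covers."""
    rng = np.random.default_rng(seed)
    pca = sdm.pca_env(world.env)
    axes = pca.axes
    pa_mask = sdm.rasterize([p.polygon for p in world.pas], axes)
    veg = rng.random(axes.shape) >= cfg.native_veg_removal
    counts = world.occurrences.groupby("species_id").size()
    rows, skipped = [], []
    for k, (sp, n) in enumerate(counts.items()):
        if n <= sdm.MIN_PRESENCES:
            skipped.append({"species_id": sp, "reason": f"only {n} records"})
            continue
        occ = world.occurrences[world.occurrences["species_id"] == sp]
        xy = occ[["x", "y"]].to_numpy(float)
        try:
            bg = sdm.sample_pseudo_absences(axes, xy, seed=seed + k)
        except sdm.SDMError as exc:
            skipped.append({"species_id": sp, "reason": str(exc)})
            continue
        for alg in cfg.sdm_algorithms:
            try:
                fit = sdm.fit_sdm(alg, xy, axes, pseudo_absences_xy=bg)
                sdm.apply_threshold(fit, xy, axes)
                sdm.auc_pseudoabsence(fit, xy, bg, axes)
                pct = (
                    sdm.representativeness(fit.binary_range, pa_mask, veg)
                    if fit.kept
                    else None
                )
            except sdm.SDMError as exc:
                skipped.append(
                    {"species_id": sp, "algorithm": alg, "reason": str(exc)}
                )
                continue
            rows.append(
                {
                    "species_id": sp,
                    "algorithm": alg,
                    "group": f"group_{k % 3}",
                    "auc": fit.auc,
                    "threshold": fit.threshold,
                    "kept": bool(fit.kept),
                    "pct_inside_pa": pct,
                }
            )
    results = pd.DataFrame(
        rows,
        columns=[
            "species_id", "algorithm", "group", "auc", "threshold", "kept",
            "pct_inside_pa",
        ],
    )
    summary = sdm.sdm_summary(results) if len(results) else {"summary": None, "tests": {}}
    return {
        "results": results,
        "summary": summary,
        "skipped": skipped,
        "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
    }


# ---------------------------------------------------------------------------
# orchestration


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj) if isinstance(obj, set)] if isinstance(
            obj, set
        ) else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    return obj


@dataclass
class GapReport:
    report: dict

    def to_json(self) -> str:
        return json.dumps(_jsonable(self.report), sort_keys=True, indent=1)


def run_pipeline(
    cfg: PipelineConfig, world: World | None = None, outdir: str | Path | None = None
) -> GapReport:
    """End-to-end gap analysis on a synthetic (or supplied) world.

    Deterministic: the same config + seed yields a byte-identical report.
    The SDM stage is isolated per species — a failing fit is logged and
    skipped without aborting the occurrence-based accounting.
    """
    if world is None:
        world = generate_world(cfg.world)
    grid = build_hex_grid(cfg.world.extent, cfg.hex_diameter)
    ranges, cell_counts = assign_to_cells(world.occurrences, grid)
    record_counts = world.occurrences.groupby("species_id").size().to_dict()
    effort = effort_surface(world.occurrences, radius=cfg.effort_radius, grid=grid)
    endem = endemism_mod.endemism_table(
        ranges, record_counts, effort.species_effort, cell_ids=grid.cell_ids
    )

    cell_areas = np.array(
        [
            shapely.intersection(p, shapely.box(*cfg.world.extent)).area
            for p in grid.polygons
        ]
    )
    counts_full = cell_counts.reindex(grid.cell_ids, fill_value=0)
    cell_table = pd.DataFrame(
        {
            "cell_id": grid.cell_ids,
            "stratum": classify_cells(grid, world.pas),
            "density": counts_full.to_numpy() / np.maximum(cell_areas, 1e-9),
            "we": endem.cells["we"].reindex(grid.cell_ids, fill_value=0.0).to_numpy(),
        }
    )

    props = protection_proportions(
        ranges, endem, world.tree, grid, world.occurrences, world.pas
    )
    report = {
        "config": {
            "seed": cfg.world.seed,
            "n_species": cfg.world.n_species,
            "hex_diameter_km": cfg.hex_diameter,
            "effort_radius_km": cfg.effort_radius,
            "n_hex_cells": len(grid),
        },
        "protection": props["all"],
        "by_category": props["by_category"],
        "by_biome": biome_proportions(
            ranges, endem, world.tree, grid, world.occurrences, world.pas, world.biomes
        ),
        "tests": inside_outside_tests(cell_table),
        "accumulation": accumulation_curves(
            world.pas, ranges, endem, world.tree, grid, world.occurrences, cfg.epochs
        ),
        "pa_table": pa_density_table(
            world.pas, world.occurrences, cfg.sampled_buffer_radius
        ),
    }
    if cfg.run_sdm:
        stage = sdm_stage(world, cfg, seed=cfg.world.seed + 10_000)
        report["sdm"] = {
            "summary": stage["summary"]["summary"],
            "tests": stage["summary"]["tests"],
            "n_modelled": int(stage["results"]["species_id"].nunique())
            if len(stage["results"])
            else 0,
            "n_skipped": len(stage["skipped"]),
        }
        report["_sdm_results"] = stage["results"]

    out = GapReport(report=report)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(out.to_json())
        report["pa_table"].to_csv(outdir / "pa_density.csv", index=False)
        endem.species.to_csv(outdir / "endemism.csv")
        endem.cells.to_csv(outdir / "cell_endemism.csv")
        cell_table.to_csv(outdir / "cell_table.csv", index=False)
        if cfg.run_sdm and "_sdm_results" in report:
            report["_sdm_results"].to_csv(outdir / "sdm_results.csv", index=False)
    return out
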