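import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from biogap import PipelineConfig, WorldConfig, run_pipeline
from biogap.gap_pipeline import (
    UNPROTECTED,
    accumulation_curves,
    classify_cells,
    classify_points,
    inside_outside_tests,
    protection_proportions,
)
from biogap.spatial_core import PAUnit, build_hex_grid


def make_pas(specs):
    return [
        PAUnit(f"p{i}", box(*b), cat, year)
        for i, (b, cat, year) in enumerate(specs)
    ]


class TestClassify:
    def test_point_strata(self):
        pas = make_pas(
            [
                ((0, 0, 10, 10), "strict", 1950),
                ((20, 0, 30, 10), "indigenous", 1990),
            ]
        )
        labels = classify_points([5, 25, 50], [5, 5, 5], pas)
        assert labels.tolist() == ["strict", "indigenous", UNPROTECTED]

    def test_overlap_resolved_by_precedence(self):
        pas = make_pas(
            [
                ((0, 0, 10, 10), "sustainable", 1950),
                ((0, 0, 10, 10), "strict", 1990),
                ((0, 0, 10, 10), "indigenous", 1990),
            ]
        )
        assert classify_points([5], [5], pas).tolist() == ["strict"]

    def test_labels_partition_the_input(self, rng):
        pas = make_pas([((10, 10, 60, 60), "sustainable", 1970)])
        labels = classify_points(rng.uniform(0, 100, 200), rng.uniform(0, 100, 200), pas)
        assert len(labels) == 200
        assert set(labels) <= {"sustainable", UNPROTECTED}

    def test_cell_classification_by_overlap(self):
        grid = build_hex_grid((0, 0, 100, 100), 30)
        pas = make_pas([((0, 0, 40, 40), "strict", 1950)])
        labels = classify_cells(grid, pas)
        assert (labels == "strict").sum() >= 1
        assert (labels == UNPROTECTED).sum() >= 1


class TestProtectionProportions:
    def test_full_coverage_means_nothing_outside(self, demo_bundle):
        w = demo_bundle["world"]
        pas = make_pas([((w.config.extent), "strict", 1950)])
        props = protection_proportions(
            demo_bundle["ranges"], demo_bundle["endem"], w.tree,
            demo_bundle["grid"], w.occurrences, pas,
        )["all"]
        for key in (
            "pct_species_outside", "pct_lineage_length_outside",
            "pct_we_sum_outside", "pct_pwe_sum_outside",
        ):
            assert props[key] == pytest.approx(0.0, abs=1e-9)

    def test_no_pas_means_everything_outside(self, demo_bundle):
        w = demo_bundle["world"]
        props = protection_proportions(
            demo_bundle["ranges"], demo_bundle["endem"], w.tree,
            demo_bundle["grid"], w.occurrences, [],
        )["all"]
        for key in (
            "pct_species_outside", "pct_lineage_length_outside",
            "pct_we_sum_outside", "pct_pwe_sum_outside",
        ):
            assert props[key] == pytest.approx(100.0)

    def test_we_partition_conserves_total(self, demo_bundle):
        w = demo_bundle["world"]
        endem = demo_bundle["endem"]
        props = protection_proportions(
            demo_bundle["ranges"], endem, w.tree, demo_bundle["grid"],
            w.occurrences, w.pas,
        )
        outside_pct = props["all"]["pct_we_sum_outside"]
        pa_cells = set(props["pa_cells"])
        inside = endem.cells.loc[endem.cells.index.isin(pa_cells), "we"].sum()
        total = endem.cells["we"].sum()
        assert outside_pct + 100.0 * inside / total == pytest.approx(100.0, abs=1e-9)


class TestInsideOutsideTests:
    def table(self, inside_we, outside_we):
        rows = [
            {"stratum": "strict", "we": v, "density": v} for v in inside_we
        ] + [{"stratum": UNPROTECTED, "we": v, "density": v} for v in outside_we]
        return pd.DataFrame(rows)

    def test_identical_samples_not_significant(self):
        out = inside_outside_tests(self.table([5, 5, 5, 5], [5, 5, 5, 5]))
        assert out["kw_density"]["H"] == pytest.approx(0.0)
        assert out["kw_density"]["p"] == pytest.approx(1.0)

    def test_complete_separation_u_zero(self):
        out = inside_outside_tests(self.table([1, 2, 3], [10, 11, 12]))
        # U counts inside-over-outside wins: none
        assert out["mw_we"]["U"] == 0.0

    def test_permutation_null_rejection_rate(self, rng):
        data = rng.normal(size=40)
        rejections = 0
        n_perm = 1000
        for _ in range(n_perm):
            perm = rng.permutation(data)
            out = inside_outside_tests(self.table(perm[:20], perm[20:]))
            rejections += out["mw_we"]["p"] < 0.05
        assert rejections / n_perm == pytest.approx(0.05, abs=0.02)


class TestAccumulation:
    def run(self, demo_bundle, pas):
        w = demo_bundle["world"]
        return accumulation_curves(
            pas, demo_bundle["ranges"], demo_bundle["endem"], w.tree,
            demo_bundle["grid"], w.occurrences,
        )

    def test_curves_monotone_and_end_at_static_totals(self, demo_bundle):
        w = demo_bundle["world"]
        acc = self.run(demo_bundle, w.pas)
        for dim in ("species", "we", "pwe", "lineage_length"):
            vals = [rec[dim] for rec in acc["series"]]
            assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))
        props = protection_proportions(
            demo_bundle["ranges"], demo_bundle["endem"], w.tree,
            demo_bundle["grid"], w.occurrences, w.pas,
        )
        assert acc["final"]["species"] == props["all"]["n_species_inside"]
        total_we = demo_bundle["endem"].cells["we"].sum()
        expected_inside_we = total_we * (
            1 - props["all"]["pct_we_sum_outside"] / 100.0
        )
        assert acc["final"]["we"] == pytest.approx(expected_inside_we, abs=1e-9)

    def test_single_epoch_world_has_one_positive_slope(self, demo_bundle):
        w = demo_bundle["world"]
        pas = [
            PAUnit(p.id, p.polygon, p.category, 1995, p.biome_id) for p in w.pas
        ]
        acc = self.run(demo_bundle, pas)
        slopes = acc["slopes_degrees"]["species"]
        assert slopes["1991-2000"] > 0
        for epoch in ("1903-1950", "1951-1980", "1981-1990", "2001-2016"):
            assert slopes[epoch] == pytest.approx(0.0, abs=1e-9)


class TestRunPipeline:
    def test_deterministic_report(self, tmp_path):
        cfg = PipelineConfig(world=WorldConfig(seed=21, n_species=15))
        a = run_pipeline(cfg, outdir=tmp_path / "a").to_json()
        b = run_pipeline(cfg, outdir=tmp_path / "b").to_json()
        assert a == b
        assert (tmp_path / "a/report.json").read_bytes() == (
            tmp_path / "b/report.json"
        ).read_bytes()

    def test_empty_pa_set_reports_everything_outside(self):
        cfg = PipelineConfig(
            world=WorldConfig(seed=8, n_species=10, n_pas_per_category=(0, 0, 0))
        )
        rep = run_pipeline(cfg).report
        assert rep["protection"]["pct_species_outside"] == 100.0
        assert rep["protection"]["pct_we_sum_outside"] == 100.0
        assert rep["protection"]["pct_pwe_sum_outside"] == 100.0

    def test_partition_invariants_on_random_worlds(self):
        for seed in range(3):
            cfg = PipelineConfig(world=WorldConfig(seed=seed, n_species=15))
            rep = run_pipeline(cfg).report
            p = rep["protection"]
            assert 0 <= p["pct_species_outside"] <= 100
            assert 0 <= p["pct_we_sum_outside"] <= 100
            assert 0 <= p["pct_pwe_sum_outside"] <= 100
            assert 0 <= p["pct_lineage_length_outside"] <= 100
            n_in = sum(
                rep["by_category"][c]["n_species_inside"]
                for c in ("strict", "sustainable", "indigenous")
            )
            # a species may hold records in several categories, so the
            # category counts bound the distinct protected-species count
            assert n_in >= p["n_species_inside"]
            assert all(
                rep["by_category"][c]["n_species_inside"] <= p["n_species_inside"]
                for c in ("strict", "sustainable", "indigenous")
            )

    def test_sdm_stage_isolated_failures(self):
        cfg = PipelineConfig(
            world=WorldConfig(seed=2, n_species=12), run_sdm=True
        )
        rep = run_pipeline(cfg).report
        assert "sdm" in rep
        assert rep["protection"]["n_species"] == 12
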