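import numpy as np
import pytest

from biogap import WorldConfig, generate_world, phylo
from biogap.endemism import endemism_table
from biogap.spatial_core import assign_to_cells, build_hex_grid, effort_surface


@pytest.fixture(scope="session")
def toy_tree():
    """Unit-branch ((A,B),C)."""
    return phylo.unit_branch_lengths(phylo.read_newick("((A,B),C);"))


@pytest.fixture(scope="session")
def toy_ranges():
    return {
        "A": frozenset({1}),
        "B": frozenset({1, 2}),
        "C": frozenset({2, 3}),
    }


@pytest.fixture(scope="session")
def demo_world():
    return generate_world(WorldConfig(seed=11, n_species=40))


@pytest.fixture(scope="session")
def demo_bundle(demo_world):
    """World + grid + derived tables shared across read-only tests."""
    grid = build_hex_grid(demo_world.config.extent, 55.0)
    ranges, cell_counts = assign_to_cells(demo_world.occurrences, grid)
    record_counts = demo_world.occurrences.groupby("species_id").size().to_dict()
    effort = effort_surface(demo_world.occurrences, radius=50.0, grid=grid)
    endem = endemism_table(
        ranges, record_counts, effort.species_effort, cell_ids=grid.cell_ids
    )
    return {
        "world": demo_world,
        "grid": grid,
        "ranges": ranges,
        "cell_counts": cell_counts,
        "record_counts": record_counts,
        "effort": effort,
        "endem": endem,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
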