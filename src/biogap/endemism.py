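"""Weighted endemism (WE) and its sampling-effort correction.

A species' endemism weight is the inverse of its range size in occupied
hexagons, so single-hexagon species carry the maximum weight and a cell's WE
is the sum of the weights of its species. Because record density varies
enormously across space, the raw index conflates narrow ranges with poor
sampling; the corrected index shrinks a species' weight when its apparent
endemism could be a sampling artefact:

    corrected = (A*B) / ((A*B) + ((1-A)*(1-C)))

with A the raw weight, B = A times the species' normalised sampling effort,
and C an increasing function of the species' record count (1e-5 at a single
record, 0.999 at 150 or more). All three terms live strictly inside (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .spatial_core import EPSILON

C_MIN = 1e-5
C_MAX = 0.999
C_SATURATION = 150  # record count at which C saturates


def we_per_species(range_size: int | np.ndarray, epsilon: float = EPSILON):
    """A = 1/range_size, clamped into the open interval (eps, 1-eps)."""
    rs = np.asarray(range_size)
    if np.any(rs < 1) or not np.issubdtype(rs.dtype, np.integer):
        raise ValueError("range_size must be a positive integer cell count")
    a = np.clip(1.0 / rs, epsilon, 1.0 - epsilon)
    return float(a) if np.isscalar(range_size) else a


def cell_we(species_in_cell, range_sizes: Mapping[str, int]) -> float:
    """Raw weighted endemism of one cell: sum of 1/range over present species."""
    return float(sum(1.0 / range_sizes[s] for s in species_in_cell))


def c_from_records(n_records: int | np.ndarray):
    """Record-count confidence term C of the correction.

    Linear from 1e-5 at n=1 to 0.999 at n=150; constant above — the
    frequency distribution of records per species saturates near 150.
    """
    n = np.asarray(n_records)
    if np.any(n < 1) or not np.issubdtype(n.dtype, np.integer):
        raise ValueError("n_records must be a positive integer")
    c = C_MIN + (np.minimum(n, C_SATURATION) - 1) * (C_MAX - C_MIN) / (C_SATURATION - 1)
    return float(c) if np.isscalar(n_records) else c


def corrected_we(A, B, C):
    """Effort-corrected weighted endemism; every argument strictly in (0,1)."""
    A, B, C = np.asarray(A, float), np.asarray(B, float), np.asarray(C, float)
    for name, v in (("A", A), ("B", B), ("C", C)):
        if np.any(v <= 0.0) or np.any(v >= 1.0):
            raise ValueError(f"{name} must lie strictly inside (0, 1); clamp upstream")
    num = A * B
    out = num / (num + (1.0 - A) * (1.0 - C))
    return float(out) if out.ndim == 0 else out


@dataclass
class EndemismTable:
    """Per-species and per-cell endemism, raw and effort-corrected."""

    species: pd.DataFrame  # index species_id; range_size, n_records, A, effort, B, C, we_corrected
    cells: pd.DataFrame  # index cell_id; we, we_corrected

    @property
    def total_we(self) -> float:
        return float(self.cells["we"].sum())


def endemism_table(
    species_ranges: Mapping[str, frozenset[int]],
    record_counts: Mapping[str, int],
    species_effort: pd.Series,
    cell_ids=None,
    epsilon: float = EPSILON,
) -> EndemismTable:
    """Assemble the endemism table from hexagon ranges, record counts and
    the normalised sampling-effort per species.

    Cell-level raw WE uses the unclamped 1/range weights so the cell sums
    conserve the species count exactly; the corrected cell value is the sum
    of the per-species corrected weights over species present in the cell.
    """
    sp_ids = sorted(species_ranges)
    rs = np.array([len(species_ranges[s]) for s in sp_ids], dtype=int)
    nrec = np.array([int(record_counts[s]) for s in sp_ids], dtype=int)
    eff = np.clip(
        species_effort.reindex(sp_ids).to_numpy(float), epsilon, 1.0 - epsilon
    )
    if np.any(~np.isfinite(eff)):
        raise ValueError("missing effort value for some species")
    A = we_per_species(rs, epsilon=epsilon)
    B = A * eff
    C = c_from_records(nrec)
    wcorr = corrected_we(A, B, C)
    species = pd.DataFrame(
        {
            "range_size": rs,
            "n_records": nrec,
            "A": A,
            "effort": eff,
            "B": B,
            "C": C,
            "we_corrected": wcorr,
        },
        index=pd.Index(sp_ids, name="species_id"),
    )

    all_cells = sorted(set().union(*species_ranges.values())) if sp_ids else []
    if cell_ids is not None:
        all_cells = sorted(set(int(c) for c in cell_ids) | set(all_cells))
    raw = pd.Series(0.0, index=pd.Index(all_cells, name="cell_id"))
    corr = raw.copy()
    for s, a_raw, wc in zip(sp_ids, 1.0 / rs, wcorr):
        idx = list(species_ranges[s])
        raw[idx] += a_raw
        corr[idx] += wc
    cells = pd.DataFrame({"we": raw, "we_corrected": corr})
    return EndemismTable(species=species, cells=cells)
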