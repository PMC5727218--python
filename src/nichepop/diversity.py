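"""Per-cell Shannon diversity of a stack of suitability surfaces.

Given K suitability surfaces s_1..s_K on a common grid (one per taxon or
haplotype), each cell's diversity is the Shannon index

    H' = -sum_i p_i ln p_i,        p_i = s_i / sum_j s_j

with 0*ln 0 := 0 and natural logarithms, so 0 <= H' <= ln K with the
maximum attained when all surfaces are equal at the cell.  Per-cell
normalization is the default because independently fitted suitability
surfaces are not jointly normalized; an un-normalized mode (p_i = s_i as
given) is kept for sensitivity analysis and recorded in the map's metadata.
Cells whose total suitability falls below ``min_total`` are masked as
signal-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nichepop.enm import SuitabilityMap

__all__ = ["DiversityMap", "shannon_map", "diversity_difference"]


@dataclass
class DiversityMap:
    """Per-cell Shannon H' on an EnvGrid footprint."""

    values: np.ndarray  # H', NaN where masked
    mask: np.ndarray  # True where masked (input mask OR low signal)
    xllcorner: float
    yllcorner: float
    cellsize: float
    taxa: list[str]
    normalized_per_cell: bool
    min_total: float
    low_signal_cells: int = 0

    @property
    def unmasked_values(self) -> np.ndarray:
        return self.values[~self.mask]


def shannon_map(
    surfaces: list[SuitabilityMap],
    taxa: list[str] | None = None,
    normalize_per_cell: bool = True,
    min_total: float = 1e-12,
) -> DiversityMap:
    """Shannon H' per cell across >= 2 suitability surfaces on one grid."""
    if len(surfaces) < 2:
        raise ValueError("Shannon diversity needs at least 2 surfaces")
    ref = surfaces[0]
    for s in surfaces[1:]:
        if not ref.same_footprint(s):
            raise ValueError("suitability surfaces are on different grids/masks")
    taxa = list(taxa) if taxa is not None else [f"taxon{i}" for i in range(len(surfaces))]
    if len(taxa) != len(surfaces):
        raise ValueError("taxa list length mismatch")

    stack = np.stack([s.values for s in surfaces])  # (K, rows, cols)
    base_mask = ref.mask
    with np.errstate(invalid="ignore"):
        total = np.nansum(np.where(base_mask, np.nan, stack), axis=0)
    low = (~base_mask) & (total < min_total)
    mask = base_mask | low

    p = np.where(mask, np.nan, stack)
    if normalize_per_cell:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = p / total
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -np.nansum(terms, axis=0)
    h = np.where(mask, np.nan, h)
    return DiversityMap(
        values=h,
        mask=mask,
        xllcorner=ref.xllcorner,
        yllcorner=ref.yllcorner,
        cellsize=ref.cellsize,
        taxa=taxa,
        normalized_per_cell=normalize_per_cell,
        min_total=min_total,
        low_signal_cells=int(low.sum()),
    )


def diversity_difference(current: DiversityMap, scenario: DiversityMap) -> tuple[np.ndarray, dict]:
    """Cellwise scenario - current H' and an impoverishment summary.

    Both maps must share grid, taxa list and normalization mode.  Cells
    masked in the scenario but not in the current map (e.g. all-taxa loss)
    are excluded from the difference and counted separately as "lost".
    The summary reports the fractions of commonly unmasked cells where the
    scenario is poorer/richer than the current map.
    """
    if current.values.shape != scenario.values.shape or (
        current.xllcorner,
        current.yllcorner,
        current.cellsize,
    ) != (scenario.xllcorner, scenario.yllcorner, scenario.cellsize):
        raise ValueError("diversity maps are on different grids")
    if current.taxa != scenario.taxa:
        raise ValueError("diversity maps use different taxa lists")
    if current.normalized_per_cell != scenario.normalized_per_cell:
        raise ValueError("diversity maps use different normalization modes")

    both = ~current.mask & ~scenario.mask
    lost = ~current.mask & scenario.mask
    diff = np.where(both, scenario.values - current.values, np.nan)
    n = int(both.sum())
    summary = {
        "n_cells_compared": n,
        "impoverished_fraction": float((diff[both] < 0).sum() / n) if n else float("nan"),
        "enriched_fraction": float((diff[both] > 0).sum() / n) if n else float("nan"),
        "lost_cells": int(lost.sum()),
        "mean_difference": float(np.nanmean(diff)) if n else float("nan"),
    }
    return diff, summary
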