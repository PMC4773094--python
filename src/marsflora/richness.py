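"""Stacked biodiversity surfaces: species richness, range-size rarity,
map correlations, area summaries, quintile classes and mask overlap.

Richness is the cellwise count of species whose binary range includes the
cell.  Range-size rarity up-weights restricted species: each species present
in a cell contributes the reciprocal of its range size (in prediction-grid
cells), so every species with a non-empty range contributes exactly 1 to the
map total — a conservation identity used as a correctness check.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np

from .grids import Raster
from .thresholds import RangeMap

__all__ = [
    "stack_richness",
    "rarity_weighted",
    "richness_correlation",
    "area_above",
    "quintile_classes",
    "mask_overlap_stats",
]


def _check_shared_grid(maps: Sequence[RangeMap]) -> None:
    if not maps:
        return
    ref = maps[0].presence.spec
    for m in maps[1:]:
        if m.presence.spec != ref:
            raise ValueError("range maps are not on a shared grid")


def stack_richness(
    maps: Sequence[RangeMap],
    species_filter: Iterable[str] | None = None,
) -> Raster:
    """Cellwise count of species present, optionally restricted to a group.

    Cells that are nodata in every constituent map stay nodata; elsewhere
    nodata in an individual map counts as absence for that species.
    An empty filter yields an all-zero map on the shared grid.
    """
    _check_shared_grid(maps)
    if not maps:
        raise ValueError("no range maps given")
    spec = maps[0].presence.spec
    if species_filter is not None:
        allowed = set(species_filter)
        use = [m for m in maps if m.species_id in allowed]
    else:
        use = list(maps)
    counts = np.zeros(spec.shape)
    any_valid = np.zeros(spec.shape, dtype=bool)
    for m in use:
        v = m.presence.values
        ok = np.isfinite(v)
        counts[ok] += v[ok]
        any_valid |= ok
    if use:
        counts[~any_valid] = np.nan
    return Raster(spec, counts)


def rarity_weighted(maps: Sequence[RangeMap]) -> Raster:
    """Range-size-rarity surface: cellwise sum of 1/range_cells over species.

    Species with empty ranges are skipped with a warning (their reciprocal is
    undefined).  The global total equals the number of contributing species.
    """
    _check_shared_grid(maps)
    if not maps:
        raise ValueError("no range maps given")
    spec = maps[0].presence.spec
    weights = np.zeros(spec.shape)
    any_valid = np.zeros(spec.shape, dtype=bool)
    n_used = 0
    for m in maps:
        cells = m.range_cells
        v = m.presence.values
        ok = np.isfinite(v)
        any_valid |= ok
        if cells == 0:
            warnings.warn(f"species {m.species_id!r} has an empty range; "
                          "skipped in rarity weighting", stacklevel=2)
            continue
        weights[ok] += v[ok] / cells
        n_used += 1
    weights[~any_valid] = np.nan
    return Raster(spec, weights)


def richness_correlation(a: Raster, b: Raster) -> float:
    """Pearson correlation of two maps over their jointly valid cells.

    Zeros are included (the common valid domain is the comparison domain).
    Returns NaN with a warning when either map is constant on that domain.
    """
    if a.spec != b.spec:
        raise ValueError("maps are not on a shared grid")
    av, bv = a.values.ravel(), b.values.ravel()
    ok = np.isfinite(av) & np.isfinite(bv)
    av, bv = av[ok], bv[ok]
    if len(av) < 2 or av.std() == 0 or bv.std() == 0:
        warnings.warn("correlation undefined: a map is constant over the "
                      "common valid domain", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(av, bv)[0, 1])


def area_above(map_: Raster, count_threshold: float, cell_km2: float) -> float:
    """Area (km^2) of cells with value strictly above ``count_threshold``."""
    if cell_km2 <= 0:
        raise ValueError("cell_km2 must be positive")
    v = map_.values
    return float(np.nansum(v > count_threshold) * cell_km2)


def quintile_classes(map_: Raster) -> Raster:
    """Class raster splitting non-zero cells into five equal-count classes.

    Non-zero valid cells are ranked ascending (ties broken by row-major cell
    index, a stable rank) and split into five as-equal-as-possible blocks;
    class 1 is the lowest fifth, class 5 the highest.  Zero cells stay class
    0, nodata stays nodata.  When all non-zero values are equal the split is
    degenerate (classes follow cell order) and a warning is emitted.
    """
    v = map_.values.ravel()
    finite = np.isfinite(v)
    nz = finite & (v != 0)
    idx = np.flatnonzero(nz)
    if len(idx) < 5:
        raise ValueError("quintile classing needs at least 5 non-zero cells")
    vals = v[idx]
    if np.all(vals == vals[0]):
        warnings.warn("all non-zero cells share one value; quintile classes "
                      "are degenerate", stacklevel=2)
    order = np.argsort(vals, kind="stable")  # stable: ties keep cell order
    classes = np.zeros(len(v))
    boundaries = np.linspace(0, len(idx), 6).round().astype(int)
    for k in range(5):
        block = idx[order[boundaries[k]:boundaries[k + 1]]]
        classes[block] = k + 1
    classes[~finite] = np.nan
    return Raster(map_.spec, classes.reshape(map_.spec.shape))


def mask_overlap_stats(map_: Raster, mask: Raster, top_classes: int = 1) -> float:
    """Fraction of mask cells falling in the top quintile classes of a map.

    ``mask`` is binary (1 inside the region of interest).  The map is
    quintile-classed first; the statistic is the share of valid mask cells
    whose class is among the ``top_classes`` highest (class 0 cells count in
    the denominator — a mask over unpredicted terrain scores 0).
    """
    if map_.spec != mask.spec:
        raise ValueError("map and mask are not on a shared grid")
    classed = quintile_classes(map_)
    mv = mask.values.ravel()
    cv = classed.values.ravel()
    sel = np.isfinite(mv) & (mv > 0) & np.isfinite(cv)
    if not sel.any():
        raise ValueError("mask selects no valid cells")
    return float(np.mean(cv[sel] >= 6 - top_classes))
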