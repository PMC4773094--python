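"""Independent-survey validation of binary range maps.

Presence-only data allows two kinds of check: the inclusion proportion (what
fraction of an independent survey's presence points for a species fall inside
its modeled range) and sensitivity/specificity against inventory
pseudo-absences — the training points of the other modeled species.  The
specificity so computed tracks modeled range size rather than true negatives
(every species shares nearly the same pseudo-absence pool), which is why the
inclusion proportion against a second survey is the primary check and the
minimum-record sweep asks how data volume drives it.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .survey import SurveyTable
from .thresholds import RangeMap

__all__ = [
    "inclusion_proportion",
    "sensitivity_specificity",
    "min_record_sweep",
    "validation_report",
]


def inclusion_proportion(range_map: RangeMap, points) -> float:
    """Fraction of independent presence points inside the presence cells.

    Points landing on nodata cells are excluded from the denominator (their
    count is warned about).  Undefined (NaN) when no valid point remains.
    """
    frame = getattr(points, "frame", points)
    ind = range_map.contains_points(frame["x"].to_numpy(float),
                                    frame["y"].to_numpy(float))
    ok = np.isfinite(ind)
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"{n_bad} independent point(s) on nodata cells excluded",
                      stacklevel=2)
    if not ok.any():
        warnings.warn("no valid independent points; inclusion undefined",
                      stacklevel=2)
        return float("nan")
    return float(np.mean(ind[ok] >= 1))


def sensitivity_specificity(
    range_map: RangeMap, presence_points, pseudoabsence_points
) -> tuple[float, float]:
    """Sensitivity and specificity of a range map against point sets.

    sensitivity = presences inside the range / valid presences;
    specificity = pseudo-absences outside the range / valid pseudo-absences.
    """
    def _frac_inside(points) -> float:
        frame = getattr(points, "frame", points)
        ind = range_map.contains_points(frame["x"].to_numpy(float),
                                        frame["y"].to_numpy(float))
        ind = ind[np.isfinite(ind)]
        if len(ind) == 0:
            return float("nan")
        return float(np.mean(ind >= 1))

    sens = _frac_inside(presence_points)
    frac_in_abs = _frac_inside(pseudoabsence_points)
    return sens, 1.0 - frac_in_abs


def min_record_sweep(
    inclusions: pd.DataFrame,
    record_counts: Mapping[str, int] | pd.Series,
    cut_list: Sequence[int] = (3, 5, 7, 10),
) -> pd.DataFrame:
    """Mean inclusion proportion per method over species subsets with >= c
    training records, for each cutoff c.

    ``inclusions`` is species x method (NaN entries ignored).  Cells whose
    subset is empty are NaN.  Species are equally weighted.
    """
    counts = pd.Series(record_counts)
    rows = {}
    for c in cut_list:
        keep = [sp for sp in inclusions.index if counts.get(sp, 0) >= c]
        if keep:
            rows[c] = inclusions.loc[keep].mean(skipna=True)
        else:
            rows[c] = pd.Series(np.nan, index=inclusions.columns)
    out = pd.DataFrame(rows).T
    out.index.name = "min_records"
    return out


def validation_report(
    range_maps: Mapping[str, Mapping[str, RangeMap]],
    independent: SurveyTable,
    train: SurveyTable,
    cut_list: Sequence[int] = (3, 5, 7, 10),
    common_max_records: int | None = None,
) -> dict:
    """Full scorecard of range maps against an independent survey.

    ``range_maps`` maps species_id -> method -> RangeMap.  Independent points
    of species absent from the model are skipped (their ids are returned).
    Outputs: the per-species inclusion table, species-weighted and
    point-weighted group means (all / endangered / endemic), the minimum-
    record sweep, and per-method mean sensitivity/specificity computed with
    the training points as presences and the other species' training points
    as inventory pseudo-absences.
    """
    methods = sorted({m for per in range_maps.values() for m in per})
    modeled = set(range_maps)
    skipped = sorted(set(independent.species_ids) - modeled)

    incl_rows: dict[str, dict[str, float]] = {}
    n_points: dict[str, int] = {}
    for sp in sorted(modeled & set(independent.species_ids)):
        pts = independent.for_species(sp)
        n_points[sp] = len(pts)
        incl_rows[sp] = {
            meth: inclusion_proportion(range_maps[sp][meth], pts)
            for meth in methods if meth in range_maps[sp]
        }
    inclusions = pd.DataFrame.from_dict(incl_rows, orient="index").reindex(columns=methods)

    flags = train.group_flags()
    counts = train.record_counts()

    def _group_mean(species: list[str]) -> pd.Series:
        if not species:
            return pd.Series(np.nan, index=methods)
        return inclusions.loc[species].mean(skipna=True)

    scored = list(inclusions.index)
    groups = {
        "all": scored,
        "endangered": [sp for sp in scored
                       if sp in flags.index and flags.loc[sp, "endangered"]],
        "endemic": [sp for sp in scored
                    if sp in flags.index and flags.loc[sp, "endemic"]],
    }
    if common_max_records is not None:
        groups["common"] = [sp for sp in scored
                            if counts.get(sp, 0) >= common_max_records]
    group_means = pd.DataFrame({g: _group_mean(sps) for g, sps in groups.items()}).T

    pts_w = n_points
    weights = pd.Series(pts_w).reindex(inclusions.index).fillna(0)
    pw = {}
    for meth in methods:
        col = inclusions[meth]
        ok = col.notna() & (weights > 0)
        pw[meth] = float(np.average(col[ok], weights=weights[ok])) if ok.any() else np.nan
    point_weighted = pd.Series(pw)

    sweep = min_record_sweep(inclusions, counts, cut_list)

    sens_spec = {}
    for meth in methods:
        s_list, p_list = [], []
        for sp in scored:
            if meth not in range_maps[sp]:
                continue
            own = train.for_species(sp)
            others = train.frame[train.frame["species_id"] != sp]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sens, spec = sensitivity_specificity(range_maps[sp][meth], own, others)
            if np.isfinite(sens):
                s_list.append(sens)
            if np.isfinite(spec):
                p_list.append(spec)
        sens_spec[meth] = {
            "mean_sensitivity": float(np.mean(s_list)) if s_list else np.nan,
            "mean_specificity": float(np.mean(p_list)) if p_list else np.nan,
        }

    return {
        "inclusions": inclusions,
        "group_means": group_means,
        "point_weighted_means": point_weighted,
        "sweep": sweep,
        "sens_spec": pd.DataFrame(sens_spec).T,
        "skipped_species": skipped,
        "n_independent_points": pd.Series(n_points),
    }
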