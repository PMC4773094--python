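"""Presence-only survey tables: reading, counting, distance and
pseudoreplication summaries.

A survey table holds one row per occurrence point of a single species, with
optional endangered/endemic flags.  Surveys here are presence-only: there are
no absence records, which is why downstream modeling relies on inventory
pseudo-absences (the points of the other modeled species).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import haversine_distances

EARTH_RADIUS_KM = 6371.0088
#: 30 arc-seconds, the lattice of the global bioclimatic grids (~1 km).
BIOCLIM_CELL_DEG = 1.0 / 120.0

DEFAULT_COLUMNS = {
    "species": "species",
    "x": "x",
    "y": "y",
    "endangered": "endangered",
    "endemic": "endemic",
}

__all__ = [
    "SurveyTable",
    "read_survey_csv",
    "count_species_with_min_records",
    "count_species_with_exact_records",
    "pairwise_distance_summary",
    "duplicate_cell_report",
    "species_summary",
    "BIOCLIM_CELL_DEG",
    "EARTH_RADIUS_KM",
]


@dataclass
class SurveyTable:
    """Ordered presence-only occurrence records of one survey.

    ``frame`` columns: species_id, x, y, endangered, endemic, source.
    ``source`` is uniform within one table ("train" or "independent").
    """

    frame: pd.DataFrame
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if len(self.frame) == 0:
            raise ValueError("a survey table must contain at least one record")
        sources = self.frame["source"].unique()
        if len(sources) > 1:
            raise ValueError(f"mixed sources within one table: {sources}")
        if not np.isfinite(self.frame[["x", "y"]].to_numpy()).all():
            raise ValueError("survey coordinates must be finite")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def source(self) -> str:
        return self.frame["source"].iloc[0]

    @property
    def species_ids(self) -> list[str]:
        return sorted(self.frame["species_id"].unique())

    @property
    def n_species(self) -> int:
        return self.frame["species_id"].nunique()

    def record_counts(self) -> pd.Series:
        return self.frame["species_id"].value_counts()

    def for_species(self, species_id: str) -> pd.DataFrame:
        return self.frame[self.frame["species_id"] == species_id]

    def group_flags(self) -> pd.DataFrame:
        """Per-species endangered/endemic flags (any record flagged counts)."""
        return self.frame.groupby("species_id")[["endangered", "endemic"]].any()

    def to_csv(self, path: str | Path) -> None:
        cols = ["species_id", "x", "y", "endangered", "endemic", "source"]
        self.frame[cols].rename(columns={"species_id": "species"}).to_csv(path, index=False)


def read_survey_csv(
    path: str | Path,
    source: str = "train",
    columns: dict[str, str] | None = None,
    crs: str = "EPSG:4326",
) -> SurveyTable:
    """Read an occurrence CSV into a :class:`SurveyTable`.

    ``columns`` maps the logical names (species, x, y, endangered, endemic)
    to the file's header names; flag columns absent from the file default to
    False.  A non-numeric coordinate raises with the offending line number.
    """
    if source not in ("train", "independent"):
        raise ValueError("source must be 'train' or 'independent'")
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, dtype=str)
    if len(raw) == 0:
        raise ValueError(f"{path}: no data rows")
    for key in ("species", "x", "y"):
        if colmap[key] not in raw.columns:
            raise ValueError(f"{path}: missing required column {colmap[key]!r}")

    out = pd.DataFrame(index=raw.index)
    out["species_id"] = raw[colmap["species"]].astype(str).str.strip()
    if (out["species_id"] == "").any():
        bad = int(out.index[out["species_id"] == ""][0]) + 2  # header + 1-based
        raise ValueError(f"{path}: empty species name at line {bad}")
    for key in ("x", "y"):
        vals = pd.to_numeric(raw[colmap[key]], errors="coerce")
        if vals.isna().any():
            bad = int(vals.index[vals.isna()][0]) + 2
        elif not np.isfinite(vals).all():
            bad = int(vals.index[~np.isfinite(vals)][0]) + 2
        else:
            bad = None
        if bad is not None:
            raise ValueError(f"{path}: bad {key!r} coordinate at line {bad}")
        out[key] = vals.astype(float)
    for key in ("endangered", "endemic"):
        col = colmap[key]
        if col in raw.columns:
            out[key] = (
                raw[col].fillna("0").astype(str).str.strip().str.lower()
                .isin(("1", "true", "t", "yes", "y"))
            )
        else:
            out[key] = False
    out["source"] = source
    return SurveyTable(out, crs=crs)


def count_species_with_min_records(table: SurveyTable, min_n: int) -> int:
    """Number of distinct species with at least ``min_n`` records."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    return int((table.record_counts() >= min_n).sum())


def count_species_with_exact_records(table: SurveyTable, n: int) -> int:
    """Number of distinct species with exactly ``n`` records."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return int((table.record_counts() == n).sum())


def _pairwise_km(points: np.ndarray, metric: str) -> np.ndarray:
    """Condensed upper-triangle pairwise distances in kilometers."""
    if metric == "haversine":
        rad = np.radians(points[:, ::-1])  # (lat, lon) order
        d = haversine_distances(rad) * EARTH_RADIUS_KM
    elif metric == "planar":
        diff = points[:, None, :] - points[None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=-1)) / 1000.0  # meters -> km
    else:
        raise ValueError(f"unknown metric {metric!r}")
    iu = np.triu_indices(len(points), k=1)
    return d[iu]


def pairwise_distance_summary(
    table: SurveyTable, metric: str = "haversine"
) -> tuple[pd.DataFrame, dict]:
    """Per-species minimum and mean pairwise point distance, in km.

    Returns a per-species frame (species with fewer than two records get NaN
    distance fields) and a study-wide summary holding the across-species
    averages of the per-species minimum and mean, taken over species with at
    least two records.
    """
    if metric == "planar" and table.crs.upper() in ("EPSG:4326", "WGS84"):
        warnings.warn("planar distances on geographic coordinates are an "
                      "approximation", stacklevel=2)
    rows = []
    for sp, grp in table.frame.groupby("species_id"):
        pts = grp[["x", "y"]].to_numpy(dtype=float)
        if len(pts) < 2:
            rows.append((sp, len(pts), np.nan, np.nan))
            continue
        d = _pairwise_km(pts, metric)
        rows.append((sp, len(pts), float(d.min()), float(d.mean())))
    per_species = pd.DataFrame(
        rows, columns=["species_id", "n_records", "min_pairwise_km", "mean_pairwise_km"]
    ).set_index("species_id")
    multi = per_species.dropna(subset=["min_pairwise_km"])
    summary = {
        "n_species": len(per_species),
        "n_species_multi_record": len(multi),
        "avg_min_pairwise_km": float(multi["min_pairwise_km"].mean()) if len(multi) else float("nan"),
        "avg_mean_pairwise_km": float(multi["mean_pairwise_km"].mean()) if len(multi) else float("nan"),
        "metric": metric,
    }
    return per_species, summary


def duplicate_cell_report(
    table: SurveyTable, cell_deg: float = BIOCLIM_CELL_DEG
) -> tuple[pd.DataFrame, dict]:
    """Pseudoreplication report: per species, how many grid cells of the
    ``cell_deg`` lattice contain two or more of its points.

    Cells are half-open intervals ``[k*cell_deg, (k+1)*cell_deg)`` anchored at
    0 degrees, matching the 30 arc-second global lattice when ``cell_deg`` is
    1/120.  The summary counts species with and without any duplicated cell.
    """
    if cell_deg <= 0:
        raise ValueError("cell_deg must be positive")
    rows = []
    for sp, grp in table.frame.groupby("species_id"):
        ix = np.floor(grp["x"].to_numpy() / cell_deg).astype(np.int64)
        iy = np.floor(grp["y"].to_numpy() / cell_deg).astype(np.int64)
        cells = pd.Series(zip(ix, iy)).value_counts()
        n_dup = int((cells >= 2).sum())
        rows.append((sp, len(grp), n_dup))
    per_species = pd.DataFrame(
        rows, columns=["species_id", "n_records", "n_duplicate_cells"]
    ).set_index("species_id")
    summary = {
        "n_species_with_duplicates": int((per_species["n_duplicate_cells"] > 0).sum()),
        "n_species_without_duplicates": int((per_species["n_duplicate_cells"] == 0).sum()),
        "cell_deg": cell_deg,
    }
    return per_species, summary


def species_summary(
    table: SurveyTable,
    metric: str = "haversine",
    cell_deg: float = BIOCLIM_CELL_DEG,
) -> tuple[pd.DataFrame, dict]:
    """Combined per-species summary: record counts, pairwise distances and
    duplicate-cell counts, plus the study-wide aggregates of each."""
    dist, dist_summary = pairwise_distance_summary(table, metric=metric)
    dup, dup_summary = duplicate_cell_report(table, cell_deg=cell_deg)
    combined = dist.join(dup["n_duplicate_cells"])
    summary = {**dist_summary, **dup_summary}
    return combined, summary
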