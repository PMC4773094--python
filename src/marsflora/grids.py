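"""Raster grid data model, plain-text grid IO, resampling and point extraction.

All rasters share one fixed layout convention: row-major from the upper-left
corner, square cells, values located at cell centers.  Cell ``(r, c)`` covers
the half-open square

    x in [x_origin + c*s,  x_origin + (c+1)*s)
    y in (y_origin - (r+1)*s,  y_origin - r*s]

so a point exactly on a shared edge belongs to the higher-index cell.
Missing data is represented internally as NaN; a numeric nodata sentinel is
used only when reading/writing ESRI ASCII grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from skimage.measure import block_reduce

__all__ = [
    "GridSpec",
    "Raster",
    "PredictorStack",
    "read_ascii_grid",
    "write_ascii_grid",
    "bilinear_resample",
    "aggregate_to",
    "extract_at_points",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular square-celled grid.

    ``x_origin``/``y_origin`` are the coordinates of the *upper-left corner*
    of the upper-left cell (not its center).  ``cell_size`` is in map units
    (degrees for geographic CRS, meters for projected).
    """

    x_origin: float
    y_origin: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def x_max(self) -> float:
        return self.x_origin + self.n_cols * self.cell_size

    @property
    def y_min(self) -> float:
        return self.y_origin - self.n_rows * self.cell_size

    def x_centers(self) -> np.ndarray:
        return self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.y_origin - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_of(self, x, y):
        """Row/column indices of the cells containing points ``(x, y)``.

        Half-open convention: boundary points go to the higher-index cell.
        Returns integer arrays; indices may fall outside the grid (callers
        check with :meth:`contains`).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        c = np.floor((x - self.x_origin) / self.cell_size).astype(int)
        r = np.floor((self.y_origin - y) / self.cell_size).astype(int)
        # top edge (y == y_origin) is inside row 0 by the closed-top convention
        r = np.where(np.isclose(y, self.y_origin), 0, r)
        return r, c

    def contains(self, r, c) -> np.ndarray:
        r = np.asarray(r)
        c = np.asarray(c)
        return (r >= 0) & (r < self.n_rows) & (c >= 0) & (c < self.n_cols)


@dataclass
class Raster:
    """A single-band raster: a :class:`GridSpec` plus a float value lattice.

    NaN encodes nodata.  The lattice shape must match the spec.
    """

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"value lattice shape {self.values.shape} does not match "
                f"grid spec shape {self.spec.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def sample_at(self, x, y) -> np.ndarray:
        """Value of the cell containing each point; NaN outside the grid."""
        r, c = self.spec.cell_of(x, y)
        inside = self.spec.contains(r, c)
        out = np.full(np.shape(r), np.nan, dtype=float)
        rr = np.atleast_1d(r)[np.atleast_1d(inside)]
        cc = np.atleast_1d(c)[np.atleast_1d(inside)]
        vals = self.values[rr, cc]
        if np.ndim(r) == 0:
            return vals[0] if inside else np.nan
        out[inside] = vals
        return out

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(self.spec, values)


class PredictorStack:
    """Named co-registered rasters sharing a single :class:`GridSpec`."""

    def __init__(self, layers: Mapping[str, Raster]):
        if not layers:
            raise ValueError("a predictor stack needs at least one layer")
        specs = {id(next(iter(layers.values())).spec)}
        ref = next(iter(layers.values())).spec
        for name, rast in layers.items():
            if rast.spec != ref:
                raise ValueError(f"layer {name!r} is not on the shared grid")
        self.layers: dict[str, Raster] = dict(layers)
        self.spec: GridSpec = ref

    def __getitem__(self, name: str) -> Raster:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __iter__(self):
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @classmethod
    def from_arrays(cls, spec: GridSpec, arrays: Mapping[str, np.ndarray]) -> "PredictorStack":
        return cls({name: Raster(spec, arr) for name, arr in arrays.items()})

    def subset(self, names: Iterable[str]) -> "PredictorStack":
        names = list(names)
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return PredictorStack({n: self.layers[n] for n in names})

    def as_table(self) -> pd.DataFrame:
        """Flattened cell-by-layer table (row-major cell order)."""
        return pd.DataFrame(
            {name: rast.values.ravel() for name, rast in self.layers.items()}
        )


# ---------------------------------------------------------------------------
# ESRI ASCII grid IO

def read_ascii_grid(path: str | Path, crs: str = "EPSG:4326") -> Raster:
    """Read an ESRI ASCII grid (.asc).  Accepts xllcorner or xllcenter."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        x0, yll = header["xllcorner"], header["yllcorner"]
    else:
        x0 = header["xllcenter"] - cell / 2
        yll = header["yllcenter"] - cell / 2
    nodata = header.get("nodata_value")
    values = np.asarray(data, dtype=float).reshape(nrows, ncols)
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    spec = GridSpec(x0, yll + nrows * cell, cell, nrows, ncols, crs)
    return Raster(spec, values)


def write_ascii_grid(raster: Raster, path: str | Path, nodata: float = -9999.0) -> None:
    spec = raster.spec
    vals = np.where(raster.valid_mask, raster.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.x_origin!r}\n")
        fh.write(f"yllcorner {spec.y_min!r}\n")
        fh.write(f"cellsize {spec.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        np.savetxt(fh, vals, fmt="%.10g")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Resampling, aggregation, extraction

def bilinear_resample(src: Raster, target: GridSpec) -> Raster:
    """Resample ``src`` onto ``target`` by bilinear interpolation of the four
    surrounding source cell-center values.

    Nodata propagates: a target cell is NaN whenever any contributing source
    neighbor is NaN.  Target centers outside the source *center* lattice are
    clamped to the nearest valid row/column of centers (edge policy).
    """
    if src.spec.crs != target.crs:
        raise ValueError("source raster and target grid must share a CRS")
    s = src.spec
    if (target.x_origin >= s.x_max or target.x_origin + target.n_cols * target.cell_size <= s.x_origin
            or target.y_origin <= s.y_min or target.y_origin - target.n_rows * target.cell_size >= s.y_origin):
        raise ValueError("target extent is disjoint from the source raster")

    xs = s.x_centers()
    ys = s.y_centers()[::-1]  # ascending for the interpolator
    interp = RegularGridInterpolator(
        (ys, xs), src.values[::-1, :], method="linear",
        bounds_error=False, fill_value=None,
    )
    tx = np.clip(target.x_centers(), xs[0], xs[-1])
    ty = np.clip(target.y_centers(), ys[0], ys[-1])
    yy, xx = np.meshgrid(ty, tx, indexing="ij")
    out = interp(np.column_stack([yy.ravel(), xx.ravel()])).reshape(target.shape)
    return Raster(target, out)


def aggregate_to(src: Raster, factor: int) -> Raster:
    """Block-mean aggregation by an integer ``factor`` (nodata-aware).

    Each output cell is the mean of the valid values in its factor x factor
    window; a window with no valid value is nodata.  Ragged edges (dimensions
    not divisible by ``factor``) aggregate over the partial window.
    """
    if factor < 1:
        raise ValueError("aggregation factor must be >= 1")
    if factor == 1:
        return Raster(src.spec, src.values.copy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN blocks
        out = block_reduce(src.values, (factor, factor), np.nanmean, cval=np.nan)
    s = src.spec
    spec = GridSpec(s.x_origin, s.y_origin, s.cell_size * factor,
                    out.shape[0], out.shape[1], s.crs)
    return Raster(spec, out)


def extract_at_points(stack: PredictorStack, points) -> tuple[pd.DataFrame, np.ndarray]:
    """Extract the containing-cell value of every layer at every point.

    ``points`` is anything with ``x``/``y`` columns (a SurveyTable's frame or
    a plain DataFrame).  Returns ``(X, valid)`` where ``X`` has one row per
    point and one column per layer, and ``valid`` flags rows whose point is
    inside the grid with all layers finite.  Invalid rows are retained in X
    (as NaN) so indices line up with the input; callers exclude them from
    modeling.  Raises if every point falls outside the stack extent.
    """
    frame = getattr(points, "frame", points)
    x = frame["x"].to_numpy(dtype=float)
    y = frame["y"].to_numpy(dtype=float)
    cols = {}
    for name, rast in stack.layers.items():
        cols[name] = rast.sample_at(x, y)
    X = pd.DataFrame(cols, index=frame.index)
    valid = np.isfinite(X.to_numpy()).all(axis=1)
    r, c = stack.spec.cell_of(x, y)
    inside = stack.spec.contains(r, c)
    if not inside.any():
        raise ValueError("all points fall outside the predictor stack extent")
    n_dropped = int((~valid).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} point(s) outside the grid or on nodata cells "
                      "excluded from modeling", stacklevel=2)
    return X, valid
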