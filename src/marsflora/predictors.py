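"""Environmental predictor preparation: terrain derivatives from a DEM and
PCA-based screening of correlated predictor sets.

Terrain follows the common GIS conventions: slope and aspect from Horn's 3x3
weighted finite differences, aspect as the downslope azimuth in degrees
clockwise from geographic north, and curvature as the discrete Laplacian.
Northness defaults to sin(aspect); cos(aspect) is available for users who
prefer the conventional definition.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .grids import GridSpec, PredictorStack, Raster

__all__ = ["derive_terrain", "pca_screen"]

#: Meters per degree of latitude / of longitude at the equator (spherical).
_M_PER_DEG_LAT = 111_320.0

# Horn's eight-neighbor weights for d z / d x (east positive) and
# d z / d y (north positive), row index increasing southward.
_KX = np.array([[-1, 0, 1],
                [-2, 0, 2],
                [-1, 0, 1]], dtype=float) / 8.0
_KY = np.array([[1, 2, 1],
                [0, 0, 0],
                [-1, -2, -1]], dtype=float) / 8.0
_LAPLACE = np.array([[0, 1, 0],
                     [1, -4, 1],
                     [0, 1, 0]], dtype=float)


def _is_geographic(crs: str) -> bool:
    return crs.upper() in ("EPSG:4326", "WGS84", "CRS84", "OGC:CRS84")


def derive_terrain(dem: Raster, northness: str = "sin") -> PredictorStack:
    """Derive slope, aspect, curvature and northness from a DEM.

    Returns a stack with layers ``elevation``, ``slope`` (degrees), ``aspect``
    (degrees clockwise from north in [0, 360), downslope direction),
    ``curvature`` (Laplacian, 1/length units) and ``northness``.  Border cells
    and cells with any nodata neighbor are nodata.  Perfectly flat
    neighborhoods get slope 0 and aspect 0.

    ``northness`` selects the transform: ``"sin"`` (sine of aspect, an
    east-west axis in practice but used as-is by some studies) or ``"cos"``
    (cosine of aspect, the conventional north-south exposure).
    """
    if northness not in ("sin", "cos"):
        raise ValueError("northness must be 'sin' or 'cos'")
    z = dem.values
    s = dem.spec.cell_size
    # NaN propagates through the convolution, which is exactly the
    # any-nodata-neighbor rule we want.
    dzdx = ndimage.correlate(z, _KX, mode="constant", cval=np.nan)
    dzdy = ndimage.correlate(z, _KY, mode="constant", cval=np.nan)
    lap = ndimage.correlate(z, _LAPLACE, mode="constant", cval=np.nan)

    if _is_geographic(dem.spec.crs):
        # degree cells: convert gradient denominators to meters, row by row
        lat = dem.spec.y_centers()[:, None]
        dx_m = s * _M_PER_DEG_LAT * np.cos(np.radians(lat))
        dy_m = s * _M_PER_DEG_LAT
        dzdx = dzdx / dx_m
        dzdy = dzdy / dy_m
        lap = lap / (dx_m * dy_m)
    else:
        dzdx = dzdx / s
        dzdy = dzdy / s
        lap = lap / (s * s)

    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    # downslope vector is -(grad); azimuth measured clockwise from north
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    flat = (dzdx == 0) & (dzdy == 0)
    aspect = np.where(flat, 0.0, aspect)
    aspect = np.where(np.isfinite(slope), aspect, np.nan)

    trans = np.sin if northness == "sin" else np.cos
    north = trans(np.radians(aspect))

    spec = dem.spec
    return PredictorStack.from_arrays(spec, {
        "elevation": z.copy(),
        "slope": slope,
        "aspect": aspect,
        "curvature": lap,
        "northness": north,
    })


def pca_screen(
    stack: PredictorStack,
    keep: int,
    r_max: float = 0.85,
) -> list[str]:
    """Select ``keep`` weakly-correlated predictors guided by a PCA.

    All layers are standardized over their jointly valid cells and a PCA of
    the correlation matrix is computed.  Components are visited in order of
    decreasing explained variance; from each, the not-yet-selected variable
    with the largest absolute loading is taken, skipping any variable whose
    absolute Pearson correlation with an already-selected one exceeds
    ``r_max``.  Visits cycle through the components until ``keep`` variables
    are found or no candidate remains.

    Constant layers are excluded with a warning.  Returns the selected names
    in selection order; the list is shorter than ``keep`` only when the
    correlation cap leaves too few admissible variables.
    """
    names = stack.names
    if keep > len(names):
        raise ValueError(f"keep={keep} exceeds the {len(names)} layers available")
    table = stack.as_table()
    valid = np.isfinite(table.to_numpy()).all(axis=1)
    data = table.loc[valid]

    usable = []
    for name in names:
        if data[name].std(ddof=0) == 0:
            warnings.warn(f"constant layer {name!r} excluded from screening",
                          stacklevel=2)
        else:
            usable.append(name)
    if not usable:
        raise ValueError("no non-constant layers to screen")

    X = data[usable].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    corr = (X.T @ X) / len(X)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    loadings = eigvec[:, order]  # column j = j-th principal component

    selected: list[int] = []
    progressed = True
    while len(selected) < keep and progressed:
        progressed = False
        for comp in range(loadings.shape[1]):
            if len(selected) >= keep:
                break
            ranked = np.argsort(-np.abs(loadings[:, comp]))
            for var in ranked:
                if var in selected:
                    continue
                if any(abs(corr[var, s]) > r_max for s in selected):
                    continue
                selected.append(int(var))
                progressed = True
                break
    return [usable[i] for i in selected]
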