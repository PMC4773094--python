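"""Probability-to-range conversion under four cutoff rules.

Presence-only surveys give no absences, so the cutoffs here are either
data-driven — statistics (mean, median, one standard deviation) of the
modeled probabilities extracted at the species' own presence points — or
accuracy-based: the threshold maximizing sensitivity + specificity (max SSS)
against inventory pseudo-absences, i.e. the occurrence points of the other
concurrently modeled species.

The one-standard-deviation rule is a two-sided band [mean - sd, mean + sd]:
cells with probabilities *within* one standard deviation of the mean are
presence, which deliberately includes some cells below the mean and excludes
cells far above it.  A config switch (``upper_open``) converts it to the
one-sided p >= mean - sd reading.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .grids import Raster

METHODS = ("mean", "median", "sd_band", "max_sss")

__all__ = ["ThresholdSet", "RangeMap", "thresholds_from_presences",
           "max_sss_threshold", "apply_cutoff", "METHODS"]


@dataclass
class ThresholdSet:
    """Per-species cutoff statistics.

    mean/median/sd are of the modeled probabilities at the species' own
    presence points (sample SD, n-1 denominator); band endpoints are
    mean +/- sd, stored unclamped.  ``max_sss_t`` may be None until computed.
    """

    species_id: str
    mean_p: float
    median_p: float
    sd_p: float
    band_low: float
    band_high: float
    max_sss_t: float | None = None
    n_points: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class RangeMap:
    """Binary presence raster for one species under one cutoff method."""

    species_id: str
    method: str
    presence: Raster  # 1 = presence, 0 = absence, NaN = nodata
    threshold: float | tuple[float, float]

    @property
    def range_cells(self) -> int:
        return int(np.nansum(self.presence.values))

    def range_km2(self, cell_km2: float) -> float:
        return self.range_cells * cell_km2

    def contains_points(self, x, y) -> np.ndarray:
        """Presence indicator at point locations (NaN outside / nodata)."""
        return self.presence.sample_at(x, y)


def thresholds_from_presences(
    surface: Raster, presence_points, ddof: int = 1, species_id: str = ""
) -> ThresholdSet:
    """Data-driven threshold statistics from a species' own presence points.

    ``presence_points`` is anything with x/y columns, or a 1-D array of
    already-extracted probabilities.  Needs at least two valid values (a
    species with two records still gets an SD, from two values).
    """
    probs = _extract_probs(surface, presence_points)
    probs = probs[np.isfinite(probs)]
    if len(probs) < 2:
        raise ValueError(
            f"species {species_id or '?'}: fewer than two valid presence "
            "probabilities; data-driven thresholds undefined"
        )
    mean_p = float(np.mean(probs))
    sd_p = float(np.std(probs, ddof=ddof))
    return ThresholdSet(
        species_id=species_id,
        mean_p=mean_p,
        median_p=float(np.median(probs)),
        sd_p=sd_p,
        band_low=mean_p - sd_p,
        band_high=mean_p + sd_p,
        n_points=len(probs),
    )


def _extract_probs(surface: Raster, points) -> np.ndarray:
    if isinstance(points, np.ndarray) or (
        hasattr(points, "__len__") and not hasattr(points, "frame")
        and not hasattr(points, "columns")
    ):
        return np.asarray(points, dtype=float)
    frame = getattr(points, "frame", points)
    return surface.sample_at(frame["x"].to_numpy(float), frame["y"].to_numpy(float))


def max_sss_threshold(
    presence_probs: np.ndarray, pseudoabsence_probs: np.ndarray
) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the distinct observed probabilities of both classes (the
    optimum of the step function sens+spec lies at an observed value).
    Presence rule is p >= t; sensitivity = fraction of presences at or above
    t, specificity = fraction of pseudo-absences below t.  Ties take the
    smallest t.  Returns (threshold, sensitivity, specificity).
    """
    pres = np.asarray(presence_probs, dtype=float)
    absn = np.asarray(pseudoabsence_probs, dtype=float)
    pres = pres[np.isfinite(pres)]
    absn = absn[np.isfinite(absn)]
    if len(pres) == 0 or len(absn) == 0:
        raise ValueError("both presence and pseudo-absence probabilities are required")
    candidates = np.unique(np.concatenate([pres, absn]))
    pres_s = np.sort(pres)
    absn_s = np.sort(absn)
    # vectorized counts of p >= t via searchsorted on sorted arrays
    sens = 1.0 - np.searchsorted(pres_s, candidates, side="left") / len(pres_s)
    spec = np.searchsorted(absn_s, candidates, side="left") / len(absn_s)
    total = sens + spec
    best = int(np.argmax(total))  # argmax returns the first (smallest t) among ties
    return float(candidates[best]), float(sens[best]), float(spec[best])


def apply_cutoff(surface: Raster, ts: ThresholdSet, method: str) -> RangeMap:
    """Binary range map from a probability surface under one cutoff rule.

    mean / median / max_sss: presence where p >= threshold.  sd_band:
    presence where band_low <= p <= band_high (the literal two-sided band);
    set ``upper_open`` via :func:`apply_cutoff_band` semantics by calling
    with method='sd_band' after widening band_high to 1.  Nodata stays nodata.
    """
    p = surface.values
    if method in ("mean", "median", "max_sss"):
        if method == "mean":
            t = ts.mean_p
        elif method == "median":
            t = ts.median_p
        else:
            if ts.max_sss_t is None:
                raise ValueError("max_sss threshold has not been computed")
            t = ts.max_sss_t
        presence = np.where(np.isfinite(p), (p >= t).astype(float), np.nan)
        thr: float | tuple[float, float] = float(t)
    elif method == "sd_band":
        lo, hi = ts.band_low, ts.band_high
        presence = np.where(np.isfinite(p),
                            ((p >= lo) & (p <= hi)).astype(float), np.nan)
        thr = (float(lo), float(hi))
    else:
        raise ValueError(f"unknown cutoff method {method!r}; expected one of {METHODS}")
    return RangeMap(ts.species_id, method, Raster(surface.spec, presence), thr)


def sd_band_one_sided(ts: ThresholdSet) -> ThresholdSet:
    """Variant of the SD rule with the upper side open (p >= mean - sd)."""
    out = ThresholdSet(**ts.as_dict())
    out.band_high = np.inf
    return out
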