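"""Canned desk-scale experiments on synthetic virtual species.

These are the package's standing study designs: self-contained, seeded runs
that measure how well the pipeline recovers known truth.  They are used by
the test suite and the results-reproduction script, and are handy as
templates for custom benchmarks.

Two regimes are used deliberately:

* ``knot_recovery`` uses a community with *shared* environmental thresholds
  and sharp (near-step) responses, the regime the multi-response model is
  built for: the handful of true knots is identifiable from the pooled
  signal, and the true range (p >= 0.5) has well-defined plateaus.  Knot
  identification is scored under the basis search's own regression contract
  (noiseless piecewise-linear responses); range recovery is scored end to
  end on the presence-only pipeline.
* ``inclusion_sweep_trend`` uses the generator defaults (independent species,
  log-uniform 2-69 records) to ask the data-volume question: does the
  inclusion of independent survey points in modeled ranges improve as the
  minimum-record cutoff rises?
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import mars, thresholds, validation
from .grids import PredictorStack, extract_at_points
from .mars import _candidate_knots
from .simulate import make_landscape, make_survey, random_species_specs

__all__ = ["knot_recovery", "inclusion_sweep_trend", "fit_synthetic_community"]


def fit_synthetic_community(
    seed: int,
    n_rows: int = 100,
    n_cols: int = 100,
    n_species: int = 20,
    n_train: int | None = None,
    n_independent: int = 20,
    n_predictors: int = 3,
    correlation: float = 0.3,
    max_terms: int = 21,
    shared_knots: bool = False,
    coefficient_scale: float = 4.0,
    prevalence_range: tuple[float, float] = (0.10, 0.35),
):
    """Simulate a community, fit the model, and return the working objects.

    Returns a dict with the landscape (environmental layers only), surveys,
    truth bundle, design matrix, response matrix and fitted model.
    """
    stack = make_landscape(seed, n_rows, n_cols, n_predictors, correlation)
    env = stack.subset([n for n in stack.names if n != "dem"])
    specs = random_species_specs(
        env, n_species, seed + 1, n_train=n_train, n_independent=n_independent,
        shared_knots=shared_knots, coefficient_scale=coefficient_scale,
        prevalence_range=prevalence_range)
    train, indep, truth = make_survey(specs, env)
    X_all, valid = extract_at_points(env, train)
    Y = mars.build_response_matrix(train, min_records=2)
    rows = Y.index[valid[Y.index]]
    X, Yf = X_all.loc[rows], Y.loc[rows]
    model = mars.fit_mars(X, Yf, max_terms=max_terms)
    return {"stack": env, "train": train, "independent": indep, "truth": truth,
            "X": X, "Y": Yf, "model": model}


def _range_maps_for(model, stack, train, methods=("mean", "median", "sd_band", "max_sss")):
    """Per-species range maps under each cutoff, from a fitted model."""
    surfaces = {sp: mars.predict_probability(model, stack, sp)
                for sp in model.species_ids}
    range_maps: dict[str, dict[str, thresholds.RangeMap]] = {}
    ts_all: dict[str, thresholds.ThresholdSet] = {}
    for sp in model.species_ids:
        g = train.for_species(sp)
        pres = surfaces[sp].sample_at(g["x"].to_numpy(float), g["y"].to_numpy(float))
        ts = thresholds.thresholds_from_presences(surfaces[sp], pres, species_id=sp)
        others = train.frame[train.frame["species_id"] != sp]
        pseudo = surfaces[sp].sample_at(others["x"].to_numpy(float),
                                        others["y"].to_numpy(float))
        ts.max_sss_t, _, _ = thresholds.max_sss_threshold(pres, pseudo)
        ts_all[sp] = ts
        range_maps[sp] = {m: thresholds.apply_cutoff(surfaces[sp], ts, m)
                          for m in methods}
    return surfaces, ts_all, range_maps


def knot_recovery(
    seed: int,
    n_rows: int = 200,
    n_cols: int = 200,
    n_species: int = 20,
    n_train: int = 50,
    coefficient_scale: float = 14.0,
    prevalence_range: tuple[float, float] = (0.25, 0.45),
) -> dict:
    """Parameter recovery on a shared-threshold community.

    Measures (a) ``max_knot_index_error``: over the community's true knots,
    the worst distance — counted in candidate-grid steps — between a true
    knot and the nearest knot selected by the forward pass when fitting the
    *noiseless* piecewise-linear responses (each species' true linear
    predictor at the pooled survey points); and (b) ``mean_jaccard_sd_band``:
    the mean Jaccard overlap between each species' one-SD-band range map from
    the full presence-only fit and its true range (true probability >= 0.5).
    """
    res = fit_synthetic_community(
        seed, n_rows=n_rows, n_cols=n_cols, n_species=n_species,
        n_train=n_train, shared_knots=True,
        coefficient_scale=coefficient_scale, prevalence_range=prevalence_range)
    X, truth, train, env = res["X"], res["truth"], res["train"], res["stack"]

    # (a) knot identification under the noiseless regression contract
    cols = {}
    for sid, tr in truth.items():
        sp = tr["spec"]
        eta = np.full(len(X), sp.intercept)
        for var, effs in sp.effects.items():
            for knot, sign, c in effs:
                eta = eta + c * np.maximum(0.0, sign * (X[var].to_numpy() - knot))
        cols[sid] = eta
    Y_noiseless = pd.DataFrame(cols, index=X.index)
    terms = mars.fit_forward(X, Y_noiseless, max_terms=21)
    selected: dict[str, list[float]] = {}
    for t in terms:
        h = t.hinges[0]
        selected.setdefault(h.variable, []).append(h.knot)

    true_knots: dict[str, float] = {}
    for tr in truth.values():
        for var, effs in tr["spec"].effects.items():
            true_knots[var] = effs[0][0]
    index_errors = []
    for var, knot in true_knots.items():
        cands = _candidate_knots(X[var].to_numpy(), 50, 3)
        ti = int(np.searchsorted(cands, knot))
        errs = []
        for k in selected.get(var, []):
            ki = int(np.argmin(np.abs(cands - k)))
            errs.append(min(abs(ki - ti), abs(ki - (ti - 1))))
        index_errors.append(min(errs) if errs else np.inf)

    # (b) end-to-end range recovery under the one-SD band
    model = res["model"]
    _, _, range_maps = _range_maps_for(model, env, train, methods=("sd_band",))
    jaccards = []
    for sp in model.species_ids:
        pred = range_maps[sp]["sd_band"].presence.values >= 1
        tru = truth[sp]["range"].values >= 1
        union = (pred | tru).sum()
        jaccards.append((pred & tru).sum() / union if union else np.nan)
    return {
        "max_knot_index_error": float(max(index_errors)),
        "knot_index_errors": index_errors,
        "mean_jaccard_sd_band": float(np.nanmean(jaccards)),
        "n_species": len(model.species_ids),
        "n_terms": len(model.terms),
    }


def inclusion_sweep_trend(
    seeds,
    n_rows: int = 100,
    n_cols: int = 100,
    n_species: int = 20,
    n_independent: int = 25,
    cut_list=(3, 5, 7, 10),
) -> dict:
    """Replicated minimum-record sweep of independent-data inclusion.

    For each seed, a community with the generator's default log-uniform
    record-count spread is simulated, fitted and thresholded under all four
    cutoffs, and the species-weighted mean inclusion proportion is computed
    for the species subsets with >= c training records.  Returns the sweep
    table averaged over seeds plus the per-method worst decrease along the
    cutoff axis (0 when the trend is monotone non-decreasing).
    """
    tables = []
    for seed in seeds:
        res = fit_synthetic_community(
            seed, n_rows=n_rows, n_cols=n_cols, n_species=n_species,
            n_independent=n_independent)
        _, _, range_maps = _range_maps_for(res["model"], res["stack"], res["train"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = validation.validation_report(
                range_maps, res["independent"], res["train"], cut_list=cut_list)
        tables.append(report["sweep"])
    mean_sweep = sum(tables) / len(tables)
    worst_drop = {}
    for meth in mean_sweep.columns:
        diffs = np.diff(mean_sweep[meth].to_numpy())
        worst_drop[meth] = float(max(0.0, -np.nanmin(diffs)) if len(diffs) else 0.0)
    return {"mean_sweep": mean_sweep, "worst_drop": worst_drop,
            "n_replicates": len(tables)}
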