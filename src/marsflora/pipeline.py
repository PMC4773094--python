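"""End-to-end orchestration: simulate -> prep -> fit -> predict -> threshold
-> richness -> validate, from one config, with one global seed.

The global seed fans out to per-stage seeds by fixed offsets so a single
number reproduces the whole run byte-for-byte.  Every stage writes its
artifacts under the output directory and the run ends with a manifest
(settings, per-stage outputs, sha256 checksums, timings).
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mars, richness, simulate, thresholds, validation
from .grids import PredictorStack, aggregate_to, extract_at_points, write_ascii_grid
from .predictors import derive_terrain
from .survey import SurveyTable, read_survey_csv, species_summary

__all__ = ["RunConfig", "run_pipeline"]

# stage-seed offsets (global seed + offset)
_SEED_LANDSCAPE = 0
_SEED_SPECIES = 1


@dataclass
class RunConfig:
    """Settings of one pipeline run.  See the demo YAML in examples/."""

    out_dir: str = "marsflora_run"
    seed: int = 0
    # simulation (used when no survey path is given)
    n_rows: int = 100
    n_cols: int = 100
    n_predictors: int = 4
    correlation: float = 0.3
    n_species: int = 20
    n_train: int | None = None
    n_independent: int = 20
    # optional real inputs
    survey_path: str | None = None
    independent_path: str | None = None
    # model knobs
    min_records: int = 2
    max_terms: int | None = None
    degree: int = 1
    penalty: float = 2.0
    # prediction / thresholding
    aggregate_factor: int = 1
    methods: tuple[str, ...] = ("mean", "median", "sd_band", "max_sss")
    richness_method: str = "sd_band"
    cut_list: tuple[int, ...] = (3, 5, 7, 10)
    cell_km2: float = 0.86  # ~30 arc-second cell at mid-latitudes

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        for key in ("methods", "cut_list"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order and return the manifest (also written to
    ``<out_dir>/manifest.json``).  A stage failure aborts with the stage
    named; artifacts of completed stages are retained."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"settings": asdict(config), "stages": {}}
    t_all = time.perf_counter()
    stage = "simulate"
    try:
        # -- simulate / load ------------------------------------------------
        t0 = time.perf_counter()
        stack = simulate.make_landscape(
            config.seed + _SEED_LANDSCAPE, config.n_rows, config.n_cols,
            config.n_predictors, config.correlation)
        truth = None
        if config.survey_path:
            train = read_survey_csv(config.survey_path, source="train")
            if not config.independent_path:
                raise KeyError("config key 'independent_path' is required "
                               "when 'survey_path' is given")
            indep = read_survey_csv(config.independent_path, source="independent")
        else:
            specs = simulate.random_species_specs(
                stack, config.n_species, config.seed + _SEED_SPECIES,
                n_train=config.n_train, n_independent=config.n_independent)
            train, indep, truth = simulate.make_survey(specs, stack)
            train.to_csv(out / "train.csv")
            indep.to_csv(out / "independent.csv")
        _finish(manifest, stage, t0, [out / "train.csv", out / "independent.csv"]
                if truth is not None else [])

        # -- prep -----------------------------------------------------------
        stage = "prep"
        t0 = time.perf_counter()
        layers = dict(stack.layers)
        if "dem" in layers:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                terrain = derive_terrain(layers.pop("dem"))
            layers["elevation"] = terrain["elevation"]
            layers["northness"] = terrain["northness"]
        model_stack = PredictorStack(layers)
        summary, study = species_summary(train)
        summary.to_csv(out / "survey_summary.csv")
        (out / "survey_summary.json").write_text(json.dumps(study, indent=1))
        X_all, valid = extract_at_points(model_stack, train)
        _finish(manifest, stage, t0,
                [out / "survey_summary.csv", out / "survey_summary.json"])

        # -- fit ------------------------------------------------------------
        stage = "fit"
        t0 = time.perf_counter()
        Y = mars.build_response_matrix(train, config.min_records)
        rows = Y.index[valid[Y.index]]
        X = X_all.loc[rows]
        Yf = Y.loc[rows]
        model = mars.fit_mars(X, Yf, max_terms=config.max_terms,
                              degree=config.degree, penalty=config.penalty)
        model.to_json(out / "model.json")
        diag = mars.deviance_diagnostics(model, X, Yf)
        diag["per_species"].to_csv(out / "fit_per_species.csv")
        diag["per_variable"].to_csv(out / "fit_per_variable.csv")
        _finish(manifest, stage, t0, [out / "model.json",
                                      out / "fit_per_species.csv",
                                      out / "fit_per_variable.csv"])

        # -- predict --------------------------------------------------------
        stage = "predict"
        t0 = time.perf_counter()
        pred_stack = model_stack
        if config.aggregate_factor > 1:
            pred_stack = PredictorStack({
                name: aggregate_to(r, config.aggregate_factor)
                for name, r in model_stack.layers.items()})
        surf_dir = out / "surfaces"
        surf_dir.mkdir(exist_ok=True)
        surfaces = {}
        for sp in model.species_ids:
            surfaces[sp] = mars.predict_probability(model, pred_stack, sp)
        for sp in model.species_ids[:5]:  # a few on disk as samples
            write_ascii_grid(surfaces[sp], surf_dir / f"{sp}.asc")
        _finish(manifest, stage, t0, sorted(surf_dir.glob("*.asc")))

        # -- threshold ------------------------------------------------------
        stage = "threshold"
        t0 = time.perf_counter()
        range_maps: dict[str, dict[str, thresholds.RangeMap]] = {}
        ts_rows = []
        by_sp = {sp: train.for_species(sp) for sp in model.species_ids}
        pres_probs = {
            sp: surfaces[sp].sample_at(g["x"].to_numpy(float), g["y"].to_numpy(float))
            for sp, g in by_sp.items()}
        for sp in model.species_ids:
            ts = thresholds.thresholds_from_presences(
                surfaces[sp], pres_probs[sp], species_id=sp)
            others = train.frame[train.frame["species_id"] != sp]
            pseudo = surfaces[sp].sample_at(others["x"].to_numpy(float),
                                            others["y"].to_numpy(float))
            ts.max_sss_t, _, _ = thresholds.max_sss_threshold(pres_probs[sp], pseudo)
            ts_rows.append(ts.as_dict())
            range_maps[sp] = {m: thresholds.apply_cutoff(surfaces[sp], ts, m)
                              for m in config.methods}
        pd.DataFrame(ts_rows).to_csv(out / "thresholds.csv", index=False)
        _finish(manifest, stage, t0, [out / "thresholds.csv"])

        # -- richness -------------------------------------------------------
        stage = "richness"
        t0 = time.perf_counter()
        meth = config.richness_method
        maps = [range_maps[sp][meth] for sp in model.species_ids]
        rich_all = richness.stack_richness(maps)
        flags = train.group_flags()
        ee = [sp for sp in model.species_ids
              if sp in flags.index and (flags.loc[sp, "endangered"]
                                        or flags.loc[sp, "endemic"])]
        rich_ee = richness.stack_richness(maps, species_filter=ee)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rare = richness.rarity_weighted(maps)
            corr = {
                "all_vs_endangered_endemic": richness.richness_correlation(rich_all, rich_ee),
                "endangered_endemic_vs_rarity": richness.richness_correlation(rich_ee, rare),
                "all_vs_rarity": richness.richness_correlation(rich_all, rare),
            }
        cell_km2 = config.cell_km2 * config.aggregate_factor ** 2
        summary = {
            "method": meth,
            "max_richness": float(np.nanmax(rich_all.values)),
            "max_richness_endangered_endemic": float(np.nanmax(rich_ee.values)),
            "n_species_stacked": len(maps),
            "n_endangered_endemic": len(ee),
            "area_above_half_km2": richness.area_above(
                rich_all, len(maps) / 2, cell_km2),
            "correlations": corr,
        }
        write_ascii_grid(rich_all, out / "richness_all.asc")
        write_ascii_grid(rich_ee, out / "richness_endangered_endemic.asc")
        write_ascii_grid(rare, out / "rarity.asc")
        (out / "richness_summary.json").write_text(json.dumps(summary, indent=1))
        _finish(manifest, stage, t0, [out / "richness_all.asc",
                                      out / "richness_endangered_endemic.asc",
                                      out / "rarity.asc",
                                      out / "richness_summary.json"])

        # -- validate -------------------------------------------------------
        stage = "validate"
        t0 = time.perf_counter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = validation.validation_report(
                range_maps, indep, train, cut_list=config.cut_list)
        report["inclusions"].to_csv(out / "validation_inclusions.csv")
        report["sweep"].to_csv(out / "validation_sweep.csv")
        summary = {
            "group_means": report["group_means"].round(6).to_dict(),
            "point_weighted_means": report["point_weighted_means"].round(6).to_dict(),
            "sweep": report["sweep"].round(6).to_dict(),
            "sens_spec": report["sens_spec"].round(6).to_dict(),
            "skipped_species": report["skipped_species"],
        }
        (out / "validation_summary.json").write_text(json.dumps(summary, indent=1))
        _finish(manifest, stage, t0, [out / "validation_inclusions.csv",
                                      out / "validation_sweep.csv",
                                      out / "validation_summary.json"])
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["total_seconds"] = round(time.perf_counter() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _finish(manifest: dict, stage: str, t0: float, outputs: list[Path]) -> None:
    manifest["stages"][stage] = {
        "seconds": round(time.perf_counter() - t0, 3),
        "outputs": {str(p): _sha256(p) for p in outputs if Path(p).exists()},
    }
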