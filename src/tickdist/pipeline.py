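"""End-to-end study orchestration.

One run handles one species: thin occurrences, load the per-period layer
stacks, screen variables, fit replicate models, evaluate, classify the
suitability maps, project the four future periods, difference them against
near-current, and report centroid shifts — all driven by one config and a
single root seed, with a machine-readable manifest for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tickdist.centroid import habitat_centroid, shift
from tickdist.env_layers import EnvStack, PERIOD_LABELS, read_layer, stack_layers, extract_at_points
from tickdist.evaluation import (
    EvalReport, SplitSpec, auc, jackknife_importance, percent_contribution,
    response_curve, split_presences,
)
from tickdist.maxent import FitConfig, fit_from_tables, predict, sample_background, score_points
from tickdist.occurrences import read_occurrences, thin_occurrences
from tickdist.suitability import SuitabilityMap, area_km2, change_map, jenks_breaks
from tickdist.variable_selection import pearson_matrix, select_variables

log = logging.getLogger("tickdist")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one species run needs."""

    species: str
    occurrence_csv: str
    stack_dirs: dict[str, str]  # period label -> directory of rasters
    out_dir: str
    cell_km: float = 10.0
    selection_threshold: float = 0.9
    n_replicates: int = 10
    seed: int = 0
    fit: FitConfig = field(default_factory=FitConfig)
    jackknife_knots: int = 5  # lighter hinge basis for the many jackknife fits
    run_jackknife: bool = True

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise PipelineError("replicate count must be >= 1")
        if "near-current" not in self.stack_dirs:
            raise PipelineError("stack_dirs must include the near-current period")
        for period in self.stack_dirs:
            if period not in PERIOD_LABELS:
                raise PipelineError(f"unknown period label {period!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        fit = FitConfig(**doc.pop("fit", {}))
        if "feature_classes" in doc:
            fit.feature_classes = tuple(doc.pop("feature_classes"))
        return cls(fit=fit, **doc)


def _load_stack(directory: str | Path, period: str) -> EnvStack:
    directory = Path(directory)
    paths = sorted(directory.glob("*.asc")) + sorted(directory.glob("*.tif"))
    if not paths:
        raise PipelineError(f"no rasters found in {directory}")
    layers = [read_layer(p) for p in paths]
    return stack_layers(layers, period=period)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full study for one species; returns the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "species": cfg.species,
        "seed": cfg.seed,
        "config": {
            "cell_km": cfg.cell_km,
            "selection_threshold": cfg.selection_threshold,
            "n_replicates": cfg.n_replicates,
            "fit": {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(cfg.fit).items()},
        },
        "stages": {},
        "outputs": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path),
        }

    # -- stage 1: occurrences ------------------------------------------------
    stage = "occurrences"
    try:
        occ_raw = read_occurrences(cfg.occurrence_csv, cfg.species)
        occ = thin_occurrences(occ_raw, cell_km=cfg.cell_km)
    except Exception as e:
        raise PipelineError(f"stage {stage!r} failed: {e}") from e
    log.info("%s: %d raw -> %d thinned (%d malformed dropped)",
             stage, len(occ_raw), len(occ), occ_raw.n_dropped)
    occ.to_csv(out / "occurrences_thinned.csv")
    record("occurrences_thinned", out / "occurrences_thinned.csv")
    manifest["stages"][stage] = {
        "n_raw": len(occ_raw), "n_thinned": len(occ), "n_dropped": occ_raw.n_dropped,
    }

    # -- stage 2: environment stacks -----------------------------------------
    stage = "env_layers"
    try:
        stacks = {p: _load_stack(d, p) for p, d in cfg.stack_dirs.items()}
        current = stacks["near-current"]
        background = sample_background(current, cfg.fit.n_background,
                                       seed=_derive_seed(cfg.seed, 1))
        presence_table = extract_at_points(current, occ)
    except Exception as e:
        raise PipelineError(f"stage {stage!r} failed: {e}") from e
    variables = current.names
    manifest["stages"][stage] = {
        "periods": list(stacks),
        "n_layers": len(variables),
        "n_valid_cells": int(current.mask.sum()),
        "n_background": len(background),
        "n_presence_on_grid": len(presence_table),
    }

    # -- stage 3: variable screening ------------------------------------------
    stage = "variable_selection"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prelim = fit_from_tables(presence_table, background, cfg.fit, variables)
        contributions_all = percent_contribution(prelim)
        corr = pearson_matrix(
            pd.concat([presence_table[variables], background[variables]],
                      ignore_index=True),
            variables,
        )
        selection = select_variables(corr, contributions_all,
                                     threshold=cfg.selection_threshold)
    except Exception as e:
        raise PipelineError(f"stage {stage!r} failed: {e}") from e
    kept = selection.kept
    log.info("%s: kept %d of %d variables", stage, len(kept), len(variables))
    selection.to_csv(out / "variable_selection.csv", contributions_all)
    record("variable_selection", out / "variable_selection.csv")
    manifest["stages"][stage] = {
        "kept": kept,
        "dropped": [[d, p, r] for d, p, r in selection.dropped],
    }

    # -- stage 4: replicate fits ----------------------------------------------
    stage = "maxent_replicates"
    try:
        report = EvalReport()
        mean_maps: dict[str, np.ndarray] = {}
        for rep in range(cfg.n_replicates):
            train, test = split_presences(
                occ, SplitSpec(seed=_derive_seed(cfg.seed, 2), replicate_id=rep))
            rng = np.random.default_rng([_derive_seed(cfg.seed, 3), rep])
            boot_idx = rng.integers(0, len(train), size=len(train))
            boot = type(train)(species=train.species,
                               records=[train.records[i] for i in boot_idx])
            train_table = extract_at_points(current, boot)
            test_table = extract_at_points(current, test)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_from_tables(train_table, background, cfg.fit, kept)
            p_train = score_points(model, train_table, transform="raw")
            p_test = score_points(model, test_table, transform="raw")
            b_scores = score_points(model, background, transform="raw")
            report.auc_train.append(auc(p_train, b_scores))
            report.auc_test.append(auc(p_test, b_scores))
            for period, st in stacks.items():
                smap = predict(model, st.subset(kept),
                               transform=cfg.fit.output_transform, clamp=True)
                acc = mean_maps.setdefault(period, np.zeros_like(smap.continuous))
                acc += np.where(st.mask, smap.continuous, 0.0)
        for period in mean_maps:
            mean_maps[period] /= cfg.n_replicates
    except Exception as e:
        raise PipelineError(f"stage {stage!r} failed: {e}") from e
    manifest["stages"][stage] = {
        "n_replicates": cfg.n_replicates,
        "auc_train": report.auc_train,
        "auc_test": report.auc_test,
        "mean_auc_train": report.mean_auc_train,
        "mean_auc_test": report.mean_auc_test,
        "rating": report.rating,
    }

    # -- stage 5: final model + evaluation extras -----------------------------
    stage = "evaluation"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final = fit_from_tables(presence_table, background, cfg.fit, kept)
        final.save(out / "model.json")
        record("model", out / "model.json")
        report.contributions = percent_contribution(final)
        if cfg.run_jackknife and len(kept) >= 2:
            jk_cfg = FitConfig(**{**asdict(cfg.fit), "hinge_knots": cfg.jackknife_knots})
            report.jackknife = jackknife_importance(
                presence_table, background, kept, jk_cfg)
        for v in kept:
            report.response_curves[v] = response_curve(final, v)
            report.response_curves[v].to_csv(out / f"response_{v}.csv", index=False)
            record(f"response_{v}", out / f"response_{v}.csv")
        report.replicate_frame().to_csv(out / "replicate_auc.csv", index=False)
        record("replicate_auc", out / "replicate_auc.csv")
        eval_doc = {
            "mean_auc_train": report.mean_auc_train,
            "mean_auc_test": report.mean_auc_test,
            "rating": report.rating,
            "contributions": report.contributions,
            "jackknife": report.jackknife,
        }
        (out / "evaluation.json").write_text(json.dumps(eval_doc, indent=1))
        record("evaluation", out / "evaluation.json")
    except Exception as e:
        raise PipelineError(f"stage {stage!r} failed: {e}") from e
    manifest["stages"][stage] = eval_doc

    # -- stage 6: classification, areas, change, centroids --------------------
    stage = "suitability"
    try:
        geom = current.geometry
        maps: dict[str, SuitabilityMap] = {}
        for period, st in stacks.items():
            maps[period] = SuitabilityMap(
                continuous=np.where(st.mask, mean_maps[period], np.nan),
                geometry=geom, mask=st.mask, period=period)
        breaks = jenks_breaks(maps["near-current"].continuous[current.mask], k=4,
                              seed=_derive_seed(cfg.seed, 4))
        areas = {}
        for period, smap in maps.items():
            smap.apply_breaks(breaks)
            tag = period.replace("-", "_")
            smap.write(out / f"suitability_{tag}.asc", "continuous")
            smap.write(out / f"classes_{tag}.asc", "classes")
            record(f"suitability_{tag}", out / f"suitability_{tag}.asc")
            record(f"classes_{tag}", out / f"classes_{tag}.asc")
            areas[period] = area_km2(smap.binary, geom)
        changes = {}
        shifts = {}
        cur_map = maps["near-current"]
        cur_centroid = habitat_centroid(cur_map.binary, geom)
        for period in [p for p in PERIOD_LABELS[1:] if p in maps]:
            cm = change_map(cur_map, maps[period])
            changes[period] = {"gain_km2": cm.gain_km2, "loss_km2": cm.loss_km2,
                               "counts": cm.counts()}
            fut_centroid = habitat_centroid(maps[period].binary, geom)
            rep = shift(cur_centroid, fut_centroid)
            shifts[period] = {
                "from": [cur_centroid.lon, cur_centroid.lat],
                "to": [fut_centroid.lon, fut_centroid.lat],
                "distance_km": rep.distance_km,
                "bearing_deg": rep.bearing_deg,
                "cardinal": rep.cardinal,
                "delta_lon": rep.delta_lon,
                "delta_lat": rep.delta_lat,
            }
            rep.write_geojson(out / f"shift_{period.replace('-', '_')}.geojson")
            record(f"shift_{period.replace('-', '_')}",
                   out / f"shift_{period.replace('-', '_')}.geojson")
        area_rows = [{"species": cfg.species, "period": p, "area_km2": a}
                     for p, a in areas.items()]
        pd.DataFrame(area_rows).to_csv(out / "areas.csv", index=False)
        record("areas", out / "areas.csv")
    except Exception as e:
        raise PipelineError(f"stage {stage!r} failed: {e}") from e
    manifest["stages"][stage] = {
        "breaks": list(breaks),
        "areas_km2": areas,
        "changes": changes,
        "centroid_shifts": shifts,
    }

    import tickdist

    manifest["version"] = tickdist.__version__
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _derive_seed(root: int, stage: int) -> int:
    # deterministic per-stage seed below 2**31
    return (root * 1_000_003 + stage * 7919) % (2**31 - 1)
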