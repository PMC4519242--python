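"""End-to-end orchestration: synth → features → hydro → telemetry → fit →
cv → importance → sensitivity → map.

``run_all`` executes the nine stages in dependency order on a synthetic
landscape (or on user-supplied input files where paths are given), writes
every intermediate artifact plus a manifest with a config fingerprint and
the headline metrics, and is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import box

from . import io as pio
from . import mapping as pmap
from . import model as pmodel
from . import sensitivity as psens
from . import synth as psynth
from . import telemetry as ptel
from .cover import EdgeRules
from .features import assemble_features
from .hydrology import SeasonConfig, seasonal_depth
from .model import ModelConfig
from .synth import SyntheticConfig
from .telemetry import FilterRules

logger = logging.getLogger(__name__)

STAGES = (
    "synth",
    "features",
    "hydro",
    "telemetry",
    "fit",
    "cv",
    "importance",
    "sensitivity",
    "map",
)


def _jsonable(o):
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: str = "pantherscape_run"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    filter_rules: FilterRules = field(default_factory=FilterRules)
    season: SeasonConfig | None = None
    strata: dict = field(default_factory=lambda: dict(psens.DEFAULT_STRATA))
    k_folds: int = 10
    n_importance_permutations: int = 10
    density_per_100km2: float = 2.80
    # optional overrides: read these files instead of generating
    gauges_path: str | None = None
    telemetry_path: str | None = None

    def __post_init__(self) -> None:
        # one seed governs the whole run
        self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed)
        self.model = dataclasses.replace(self.model, seed=self.seed)
        if self.season is None:
            self.season = SeasonConfig(
                start_year=self.synthetic.start_year, end_year=self.synthetic.end_year
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "synthetic" in raw:
            kwargs["synthetic"] = SyntheticConfig(**raw.pop("synthetic"))
        if "model" in raw:
            kwargs["model"] = ModelConfig(**raw.pop("model"))
        if "filter_rules" in raw:
            fr = raw.pop("filter_rules")
            for key in ("window_start", "window_end"):
                if key in fr:
                    fr[key] = pd.Timestamp(fr[key])
            kwargs["filter_rules"] = FilterRules(**fr)
        if "season" in raw:
            kwargs["season"] = SeasonConfig(**raw.pop("season"))
        kwargs.update(raw)
        return cls(**kwargs)

    def fingerprint(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (frozenset, set)):
                return sorted(o)
            if isinstance(o, pd.Timestamp):
                return str(o)
            return str(o)

        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # where results land is not part of the run identity
        blob = json.dumps(payload, default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_fingerprint": config.fingerprint(),
        "seed": config.seed,
        "stages": {},
        "metrics": {},
    }
    timings: dict[str, float] = {}
    state: dict = {}

    for stage in STAGES:
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, out, state, manifest)
        except Exception as exc:  # noqa: BLE001 — abort names the stage
            raise StageError(stage, exc) from exc
        timings[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", stage, timings[stage])

    result_blob = json.dumps(manifest["metrics"], sort_keys=True, default=_jsonable)
    manifest["result_hash"] = hashlib.sha256(result_blob.encode()).hexdigest()[:16]
    manifest["timings_s"] = timings  # excluded from the result hash
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    return manifest


# --- stage implementations -------------------------------------------------


def _stage_synth(config: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    sc = config.synthetic
    layer = psynth.generate_cover(sc)
    elevation, gauges, depth_truth = psynth.generate_hydrology(sc)
    blocks, roads = psynth.generate_anthropogenic(sc)
    pio.write_cover(out / "cover.geojson", layer)
    elevation.write(out / "elevation.asc")
    pio.write_gauges(out / "gauges.csv", gauges)
    pio.write_blocks(out / "blocks.geojson", blocks)
    pio.write_roads(out / "roads.geojson", roads)
    state.update(
        layer=layer, elevation=elevation, gauges=gauges, blocks=blocks, roads=roads,
        depth_truth=depth_truth,
    )
    manifest["stages"]["synth"] = {
        "cover_polygons": len(layer),
        "gauges": len(gauges),
        "blocks": len(blocks),
        "roads": len(roads),
    }


def _stage_features(config: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    grid = config.synthetic.grid
    table = assemble_features(
        grid, state["layer"], state["blocks"], state["roads"], EdgeRules()
    )
    state["grid"] = grid
    state["table"] = table
    manifest["stages"]["features"] = {"cells": len(table)}


def _stage_hydro(config: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    gauges = state["gauges"]
    if config.gauges_path is not None:
        gauges = pio.read_gauges(config.gauges_path)
    depths = seasonal_depth(
        gauges, state["elevation"], state["grid"], config.season
    )
    table = state["table"].join(depths)
    state["table"] = table
    manifest["stages"]["hydro"] = {
        "dry_depth_range_m": [float(depths["dry_depth"].min()), float(depths["dry_depth"].max())],
        "wet_depth_range_m": [float(depths["wet_depth"].min()), float(depths["wet_depth"].max())],
    }


def _stage_telemetry(config: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    grid, table = state["grid"], state["table"]
    if config.telemetry_path is not None:
        fixes = pio.read_telemetry(config.telemetry_path)
        truth = None
    else:
        fixes, truth = psynth.simulate_telemetry(config.synthetic, table)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth.as_dict(), fh)
    pio.write_telemetry(out / "telemetry.csv", fixes)
    xmin, ymin, xmax, ymax = grid.bounds
    study_area = box(xmin, ymin, xmax, ymax)
    kept, counts = ptel.filter_fixes(fixes, config.filter_rules, study_area)
    home_ranges = [
        ptel.mcp_home_range(sub) for _, sub in kept.groupby("animal_id", sort=True)
    ]
    table["presence"] = ptel.label_presence(grid, kept)
    state.update(fixes=kept, truth=truth, home_ranges=home_ranges, table=table)
    pio.write_features(out / "features.csv", table)
    manifest["stages"]["telemetry"] = {
        "animals": int(counts.size),
        "fixes": int(len(kept)),
        "presence_cells": int(table["presence"].sum()),
        "prevalence": float(table["presence"].mean()),
    }


def _stage_fit(config: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    table = state["table"]
    fitted = pmodel.fit(table, config.model)
    thr = pmodel.select_threshold(fitted.labels.to_numpy(), fitted.oob_P.to_numpy())
    table["P"] = fitted.oob_P
    reports = {
        "resubstitution": pmodel.accuracy_metrics(
            fitted.labels, fitted.resub_P, thr.threshold, mode="resubstitution"
        ),
        "out_of_bag": pmodel.accuracy_metrics(
            fitted.labels, fitted.oob_P, thr.threshold, mode="out_of_bag"
        ),
    }
    state.update(model=fitted, threshold=thr, reports=reports)
    manifest["metrics"]["threshold"] = thr.threshold
    manifest["metrics"]["accuracy"] = {k: r.as_dict() for k, r in reports.items()}
    manifest["stages"]["fit"] = {"threshold": thr.threshold}


def _stage_cv(config: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    result = pmodel.cross_validate(state["table"], config.model, k=config.k_folds)
    state["cv"] = result
    manifest["metrics"]["accuracy"]["cv"] = result["pooled"].as_dict()
    manifest["metrics"]["accuracy"]["cv_per_fold_mean"] = result["per_fold_mean"]
    manifest["stages"]["cv"] = {"k": config.k_folds}
    with open(out / "accuracy.json", "w") as fh:
        json.dump(manifest["metrics"]["accuracy"], fh, indent=2, default=_jsonable)


def _stage_importance(config: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    imp = pmodel.variable_importance(
        state["model"], state["table"], n_permutations=config.n_importance_permutations
    )
    imp.to_csv(out / "importance.csv")
    state["importance"] = imp
    manifest["metrics"]["importance_top5"] = list(imp.index[:5])
    manifest["stages"]["importance"] = {"top": imp.index[0]}


def _stage_sensitivity(config: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    table, fitted = state["table"], state["model"]
    strata = psens.build_strata(table, fitted, config.strata)
    curves = []
    for covariate in fitted.feature_names:
        curves.extend(psens.sweep(fitted, strata, table, covariate))
    effects = psens.report_effects(curves)
    psens.curves_to_frame(curves).to_csv(out / "curves.csv", index=False)
    effects.to_csv(out / "effects.csv", index=False)
    psens.plot_curves(curves, out / "curves.png")
    state["curves"] = curves
    state["effects"] = effects
    dry = effects[(effects["covariate"] == "dry_depth")]
    manifest["metrics"]["depth_effect"] = dry.to_dict("records")
    manifest["stages"]["sensitivity"] = {"curves": len(curves)}


def _stage_map(config: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    table, grid = state["table"], state["grid"]
    hmap = pmap.classify_map(table, state["threshold"].threshold)
    # synthetic comparison zones: west/east halves of the landscape
    xmin, ymin, xmax, ymax = grid.bounds
    zones = {
        "west": box(xmin, ymin, (xmin + xmax) / 2, ymax),
        "east": box((xmin + xmax) / 2, ymin, xmax, ymax),
    }
    zsum = pmap.zone_summary(hmap, zones, grid)
    zsum.to_csv(out / "zone_summary.csv", index=False)
    hmap.table.reset_index().to_csv(out / "habitat_map.csv", index=False)
    per_animal, hr_summary = ptel.home_range_P(state["home_ranges"], table, grid)
    per_animal.to_csv(out / "home_range_P.csv", index=False)
    pio.write_home_ranges(out / "home_ranges.geojson", state["home_ranges"])
    manifest["metrics"]["habitat_km2"] = hmap.habitat_km2
    manifest["metrics"]["capacity_adults"] = pmap.capacity(
        hmap.habitat_km2, config.density_per_100km2
    )
    manifest["metrics"]["home_range_P"] = hr_summary
    manifest["stages"]["map"] = {"habitat_km2": hmap.habitat_km2}


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "features": _stage_features,
    "hydro": _stage_hydro,
    "telemetry": _stage_telemetry,
    "fit": _stage_fit,
    "cv": _stage_cv,
    "importance": _stage_importance,
    "sensitivity": _stage_sensitivity,
    "map": _stage_map,
}
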