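"""Run configuration and the end-to-end pipeline.

Stages: simulate -> build-scenarios -> hydroperiod -> quality runs ->
sensitivity grid -> report.  Every artifact directory carries a manifest
with the config hash and seed so a run is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import codebook as cb
from .analysis import FILTERS, ModelRun, report, sensitivity_grid, table3_presets
from .codebook import GROUPS
from .hydro import DsweScene, dry_threat
from .quality import QualityParams
from .raster import read_raster, write_raster
from .scenarios import SCENARIOS
from .synthetic import (
    LandscapeConfig,
    PondingModel,
    SyntheticWatershed,
    generate_dswe_series,
    generate_landscape,
    table1_preset,
)

log = logging.getLogger("potholescape")


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    preset_id: int | None = None
    codebook_path: str | None = None
    scenarios: tuple[str, ...] = SCENARIOS
    groups: tuple[str, ...] = GROUPS
    method: str = "presence_absence"
    shoreline: bool = True
    sensitivity: bool = True
    figure: bool = False
    outdir: str = "run_output"
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups {sorted(bad)}; expected subset of {GROUPS}")
        bad = set(self.scenarios) - set(SCENARIOS)
        if bad:
            raise ValueError(f"unknown scenarios {sorted(bad)}")
        if self.preset_id is not None:
            self.landscape = table1_preset(self.preset_id, seed=self.seed)
        elif self.landscape.seed != self.seed:
            self.landscape = dataclasses.replace(self.landscape, seed=self.seed)
        if self.codebook_path is not None and not Path(self.codebook_path).exists():
            raise FileNotFoundError(f"codebook file not found: {self.codebook_path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        landscape = LandscapeConfig(**doc.pop("landscape", {}) or {})
        scalars = {k: v for k, v in doc.items()}
        if "scenarios" in scalars:
            scalars["scenarios"] = tuple(scalars["scenarios"])
        if "groups" in scalars:
            scalars["groups"] = tuple(scalars["groups"])
        return cls(landscape=landscape, **scalars)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "landscape": dataclasses.asdict(self.landscape),
                "preset_id": self.preset_id,
                "codebook": self.codebook_path,
                "scenarios": list(self.scenarios),
                "groups": list(self.groups),
                "method": self.method,
                "shoreline": self.shoreline,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# scene-stack serialization (multi-file TIFF + date-indexed CSV manifest)


def write_scenes(scenes: list[DsweScene], outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(scenes):
        codes = f"scene_{i:03d}_codes.tif"
        cloud = f"scene_{i:03d}_cloud.tif"
        write_raster(s.codes, outdir / codes)
        write_raster(s.cloud, outdir / cloud)
        rows.append({"path": codes, "cloud_path": cloud, "date": s.date.isoformat()})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_scenes(manifest: str | Path) -> list[DsweScene]:
    manifest = Path(manifest)
    base = manifest.parent
    rows = pd.read_csv(manifest)
    return [
        DsweScene(
            date=_dt.date.fromisoformat(str(r["date"])),
            codes=read_raster(base / r["path"]),
            cloud=read_raster(base / r["cloud_path"]),
        )
        for _, r in rows.iterrows()
    ]


# --------------------------------------------------------------------------
# the pipeline


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write all artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name):
        log.info("stage %s", name)

    try:
        stage("simulate")
        watershed = generate_landscape(config.landscape)
        artifacts["landscape"] = watershed.write(outdir / "landscape")
        ponding = PondingModel.from_watershed(watershed, seed=config.seed)
        scenes = generate_dswe_series(watershed, ponding)
        artifacts["scenes"] = write_scenes(scenes, outdir / "scenes")
    except Exception as e:
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e

    book = (
        cb.Codebook.from_yaml(config.codebook_path)
        if config.codebook_path
        else cb.default_codebook()
    )
    run = ModelRun(
        watershed=watershed,
        scenes=scenes,
        method=config.method,
        codebook=book,
        params=QualityParams(),
    )

    try:
        stage("build-scenarios")
        for scenario in config.scenarios:
            shorelines = (
                [True, False]
                if scenario in ("wqw", "drain_mod_wqw") and "shorebird" in config.groups
                else [config.shoreline]
            )
            for sl in shorelines:
                smap = run.scenario_map(scenario, sl)
                tag = scenario + ("" if sl else "_no_shoreline")
                artifacts[f"lulc_{tag}"] = write_raster(
                    smap.lulc, outdir / "scenarios" / f"lulc_{tag}.tif"
                )
                (outdir / "scenarios" / f"lulc_{tag}.json").write_text(
                    json.dumps(
                        {"scenario": scenario, "shoreline": sl, "steps": smap.provenance},
                        indent=1,
                    )
                )
    except Exception as e:
        raise RuntimeError(f"stage 'build-scenarios' failed: {e}") from e

    try:
        stage("hydroperiod")
        windows = sorted({("apr_may" if g == "shorebird" else "mar_apr") for g in config.groups})
        activity_rows = []
        for window in windows:
            hp = run.dry(window)
            artifacts[f"dry_{window}"] = write_raster(
                hp.dry, outdir / "hydroperiod" / f"dry_{config.method}_{window}.tif"
            )
            for pid, active in sorted(run.activity(window).items()):
                activity_rows.append({"patch_id": pid, "window": window, "active": active})
        pd.DataFrame(activity_rows, columns=["patch_id", "window", "active"]).to_csv(
            outdir / "hydroperiod" / "activity.csv", index=False
        )
        artifacts["activity"] = outdir / "hydroperiod" / "activity.csv"
    except Exception as e:
        raise RuntimeError(f"stage 'hydroperiod' failed: {e}") from e

    results = {}
    score_rows = []
    try:
        stage("run")
        for group in config.groups:
            for scenario in config.scenarios:
                shorelines = (
                    [True, False]
                    if group == "shorebird" and scenario in ("wqw", "drain_mod_wqw")
                    else [True]
                )
                for sl in shorelines:
                    for filt in FILTERS:
                        res = run.evaluate(group, scenario, filt, sl)
                        results[(group, scenario, filt, sl)] = res
                        tag = f"{group}_{scenario}{'' if sl else '_nosl'}_{filt}"
                        if filt == "all_depressions":
                            artifacts[f"Q_{tag}"] = write_raster(
                                res.Q, outdir / "quality" / f"Q_{tag}.tif"
                            )
                        score_rows.append(
                            {
                                "group": group,
                                "scenario": scenario,
                                "shoreline": sl,
                                "filter": filt,
                                "total_score": res.total_score,
                                **{f"area_ha_{k}": v for k, v in res.bin_areas.items()},
                            }
                        )
        scores = outdir / "quality" / "scores.csv"
        pd.DataFrame(score_rows).to_csv(scores, index=False)
        artifacts["scores"] = scores
    except Exception as e:
        raise RuntimeError(f"stage 'run' failed: {e}") from e

    try:
        stage("sensitivity")
        if config.sensitivity:
            rows = sensitivity_grid(
                run, groups=list(config.groups), scenarios=tuple(config.scenarios)
            )
        else:
            rows = sensitivity_grid(
                run,
                groups=list(config.groups),
                presets={g: table3_presets(g)[:1] for g in config.groups},
                scenarios=tuple(config.scenarios),
            )
    except Exception as e:
        raise RuntimeError(f"stage 'sensitivity' failed: {e}") from e

    try:
        stage("report")
        paths = report(rows, results, outdir / "report", figure=config.figure)
        artifacts.update(paths)
    except Exception as e:
        raise RuntimeError(f"stage 'report' failed: {e}") from e

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": ["simulate", "build-scenarios", "hydroperiod", "run", "sensitivity", "report"],
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    artifacts["manifest"] = outdir / "run_manifest.json"
    return artifacts
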