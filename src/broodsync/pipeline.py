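"""End-to-end orchestration: generate -> detect -> behaviours -> cues ->
synchrony, with a manifest for reproducibility.

A run is a pure function of its configuration and seed.  Every stage
writes its CSV/JSON artifacts into the output directory as it completes;
the manifest records input hashes, package versions, the seed, per-stage
timings and any stage failure, so a partial run leaves completed outputs
intact and attributes the failure.
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

from . import behaviour, cues, detection, field_io, synchrony, synthetic

log = logging.getLogger("broodsync")

STAGES = ("generate", "detect", "behaviours", "cues", "synchrony")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (generator mode or file mode)."""

    outdir: str = "results"
    seed: int = 0
    generator: synthetic.GeneratorConfig | None = None
    detection: detection.DetectionConfig = field(
        default_factory=detection.DetectionConfig)
    # file mode: paths to the four inputs (generator ignored when set)
    ambient_path: str | None = None
    traces_path: str | None = None
    records_path: str | None = None
    caterpillar_path: str | None = None
    offset: float = 13.0
    null_duration_longterm: float = 14.0
    mean_duration_focal: float = 12.0
    intensity_quad_points: int = 15

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        det = raw.pop("detection", None)
        cfg = cls(**raw)
        if gen is not None:
            gen = dict(gen)
            for key in ("active_day", "night_window", "onset_range",
                        "duration_range", "clutch_range", "years"):
                if key in gen:
                    gen[key] = tuple(gen[key])
            cfg.generator = synthetic.GeneratorConfig(**gen)
        if det is not None:
            det = dict(det)
            for key in ("active_day", "night_window"):
                if key in det:
                    det[key] = tuple(det[key])
            cfg.detection = detection.DetectionConfig(**det)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": json.loads(json.dumps(config.to_dict(), default=str)),
        "stages": {},
        "artifacts": {},
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (out / "run_config.yaml").write_text(
        yaml.safe_dump(json.loads(json.dumps(config.to_dict(), default=str))))

    def finish(stage: str, t0: float, artifacts: dict[str, Path]) -> None:
        manifest["stages"][stage] = {
            "status": "ok", "seconds": round(time.time() - t0, 3)}
        for name, p in artifacts.items():
            manifest["artifacts"][name] = {
                "path": str(p), "sha256": _sha256(Path(p))}
        _write_manifest(out, manifest)

    def fail(stage: str, exc: Exception) -> None:
        manifest["stages"][stage] = {"status": "error", "error": str(exc)}
        _write_manifest(out, manifest)
        raise StageError(stage, exc) from exc

    # --- stage 1: generate or read inputs ---------------------------------
    t0 = time.time()
    try:
        if config.ambient_path is not None:
            ambient, traces, records, caterpillar = field_io.read_inputs(
                config.ambient_path, config.traces_path,
                config.records_path, config.caterpillar_path)
            dataset = None
            artifacts: dict[str, Path] = {}
        else:
            gen = config.generator or synthetic.GeneratorConfig(seed=config.seed)
            if gen.seed != config.seed:
                gen = gen.replace(seed=config.seed)
            dataset = synthetic.generate_dataset(gen)
            paths = synthetic.write_dataset(dataset, out / "inputs")
            ambient, traces = dataset.grid.df, dataset.traces
            records, caterpillar = dataset.records, dataset.caterpillar
            artifacts = dict(paths)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - recorded in the manifest
        fail("generate", exc)
    finish("generate", t0, artifacts)

    # --- stage 2: detection ------------------------------------------------
    t0 = time.time()
    try:
        loggers = field_io.logger_positions(ambient)
        nests = traces.groupby("nest_id", as_index=False).first()
        pairing = pd.Series(
            field_io.pair_all_nests(nests, loggers).to_numpy(),
            index=nests["nest_id"])
        paired = field_io.align_all(traces, ambient, pairing)
        placements = nests.set_index("nest_id")["placement_date"]
        profiles = detection.detect_all(paired, placements, config.detection)
        summary = detection.profiles_summary(profiles)
        daily_rows = pd.concat(
            [p.daily.assign(nest_id=p.nest_id) for p in profiles.values()],
            ignore_index=True)
        summary.to_csv(out / "detection_summary.csv", index=False)
        daily_rows.to_csv(out / "detection_daily.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        fail("detect", exc)
    finish("detect", t0, {"detection_summary": out / "detection_summary.csv",
                          "detection_daily": out / "detection_daily.csv"})

    # --- stage 3: behaviours ----------------------------------------------
    t0 = time.time()
    try:
        behav = behaviour.compute_behaviours(profiles, records)
        behav.to_csv(out / "behaviours.csv", index=False)
        models_txt = {}
        if len(behav) >= 10:
            int_fit = behaviour.fit_intensity_model(behav)
            dur_fit = behaviour.fit_duration_model(behav)
            models_txt = {
                "intensity_glm": {
                    "params": int_fit.params.to_dict(),
                    "bse": int_fit.bse.to_dict(),
                    "pvalues": int_fit.pvalues.to_dict()},
                "duration_lm": {
                    "params": dur_fit.params.to_dict(),
                    "bse": dur_fit.bse.to_dict(),
                    "pvalues": dur_fit.pvalues.to_dict()},
            }
        (out / "behaviour_models.json").write_text(
            json.dumps(models_txt, indent=2))
    except Exception as exc:  # noqa: BLE001
        fail("behaviours", exc)
    finish("behaviours", t0, {"behaviours": out / "behaviours.csv",
                              "behaviour_models": out / "behaviour_models.json"})

    # --- stage 4: cue windows ----------------------------------------------
    t0 = time.time()
    try:
        stats = cues.daily_ambient_stats(ambient)
        table = behav.assign(logger_id=behav["nest_id"].map(pairing))
        tvars = cues.temperature_variables(table, stats)
        onset_rank = cues.fit_onset_candidates(behav, tvars)
        duration_rank = cues.fit_duration_candidates(behav, tvars)
        daily_int = cues.intensity_daily_table(profiles, behav, stats, pairing)
        intensity_rank, _ = cues.fit_intensity_candidates(
            daily_int, n_quad=config.intensity_quad_points)
        cues.candidates_to_csv(onset_rank, out / "candidates_onset.csv")
        cues.candidates_to_csv(duration_rank, out / "candidates_duration.csv")
        cues.candidates_to_csv(intensity_rank, out / "candidates_intensity.csv")
    except Exception as exc:  # noqa: BLE001
        fail("cues", exc)
    finish("cues", t0, {
        "candidates_onset": out / "candidates_onset.csv",
        "candidates_duration": out / "candidates_duration.csv",
        "candidates_intensity": out / "candidates_intensity.csv"})

    # --- stage 5: synchrony and fitness -------------------------------------
    t0 = time.time()
    try:
        sync = synchrony.build_synchrony(
            records, caterpillar, behav,
            offset=config.offset,
            null_duration_longterm=config.null_duration_longterm,
            mean_duration_focal=config.mean_duration_focal)
        sync.to_csv(out / "synchrony.csv", index=False)
        tests: dict = {}
        focal = sync.dropna(subset=["null_no_onset"])
        if len(focal) >= 2:
            tests["paired_no_onset"] = synchrony.paired_improvement_test(
                focal["index"], focal["null_no_onset"] + config.offset)
            tests["f_no_onset"] = synchrony.variance_ratio_test(
                focal["raw_synchrony"], focal["null_no_onset"])
            tests["f_no_duration"] = synchrony.variance_ratio_test(
                focal["raw_synchrony"], focal["null_no_duration"])
        fit = synchrony.fit_fitness_model(sync)
        summary = {
            "tests": tests,
            "fitness": {
                "params": fit["params"].to_dict(),
                "bse": fit["bse"].to_dict(),
                "optimum_synchrony": fit["optimum_synchrony"]},
        }
        (out / "tests_report.json").write_text(
            json.dumps(summary, indent=2, default=float))
    except Exception as exc:  # noqa: BLE001
        fail("synchrony", exc)
    finish("synchrony", t0, {"synchrony": out / "synchrony.csv",
                             "tests_report": out / "tests_report.json"})

    manifest["completed_stages"] = [
        s for s in STAGES if manifest["stages"].get(s, {}).get("status") == "ok"]
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))


def make_fixtures(scale: str = "tiny", outdir: str | Path = "fixtures") -> Path:
    """Write a small self-contained input set for tests and demos."""
    if scale == "tiny":
        cfg = synthetic.GeneratorConfig(
            n_nests=8, n_loggers=4, seed=11, season_start=95, season_end=165)
    elif scale == "default":
        cfg = synthetic.GeneratorConfig(seed=11)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    ds = synthetic.generate_dataset(cfg)
    outdir = Path(outdir)
    synthetic.write_dataset(ds, outdir)
    return outdir
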