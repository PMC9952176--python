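"""Stage orchestration: simulate -> detect -> calibrate -> estimate -> report.

One config drives the whole chain; every run writes a manifest listing
inputs, outputs, seeds, package version, and the parameter values used,
which is sufficient to re-run the deterministic stages bit-identically.
An unchanged config is a no-op unless forced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from pamharvest import __version__ as _version
from pamharvest.audio import read_wav, write_wav
from pamharvest.calibration import (
    effective_radius,
    estimate_recall,
    fit_logistic_range,
    match_detections,
    monitored_area,
)
from pamharvest.datasets import ionian_counts, ionian_strata, load_counts, load_strata
from pamharvest.detection import (
    StftParams,
    build_template,
    detect_recording,
    write_selection_table,
)
from pamharvest.harvest import (
    adjust_counts,
    change_table,
    diel_summary,
    estimate_harvest,
    aggregate,
    percent_of_breeding_stock,
    seasonal_summary,
    weekday_summary,
)
from pamharvest.synthetic import (
    ControlShotDesign,
    GunshotSpec,
    SceneSpec,
    SeasonSimSpec,
    render_scene,
    simulate_control_experiment,
    simulate_season,
    synth_gunshot,
)

__all__ = ["PipelineConfig", "DependencyError", "run_pipeline", "STAGES"]

log = logging.getLogger("pamharvest")

STAGES = ("simulate", "detect", "calibrate", "estimate", "report")


class DependencyError(RuntimeError):
    """A stage's upstream artifact is missing."""

    def __init__(self, stage: str, missing: str):
        super().__init__(f"stage {stage!r}: missing upstream artifact {missing}")
        self.stage = stage
        self.missing = missing


@dataclass
class PipelineConfig:
    """Everything a full run needs, loadable from one YAML file."""

    output_dir: str = "pamharvest-out"
    seed: int = 0
    # detector
    threshold: float = 0.4
    min_separation_s: float = 0.5
    stft_window: int = 256
    stft_hop: int = 64
    # calibration
    match_tolerance_s: float = 1.0
    p_cut: float = 0.5
    max_observed_m: float = 1100.0
    # estimation inputs (None -> packaged Ionian tables)
    counts_csv: str | None = None
    strata_yaml: str | None = None
    breeding_pairs: float | None = 763250.0
    # simulation
    scene_duration_s: float = 60.0
    scene_noise_rms: float = 0.005
    scene_n_events: int = 10
    scene_distance_m: float = 300.0
    season: dict = field(default_factory=dict)
    force: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("force", None)  # forcing changes behaviour, not outputs
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _scene_events(cfg: PipelineConfig) -> list:
    # evenly spaced injections, > 2 s apart at the default duration
    gap = cfg.scene_duration_s / (cfg.scene_n_events + 1)
    return [(gap * (i + 1), cfg.scene_distance_m) for i in range(cfg.scene_n_events)]


def _stage_simulate(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    sim = out / "sim"
    sim.mkdir(parents=True, exist_ok=True)
    gun = GunshotSpec()
    scene = SceneSpec(
        duration_s=cfg.scene_duration_s,
        noise_rms=cfg.scene_noise_rms,
        events=_scene_events(cfg),
        seed=cfg.seed,
    )
    audio, truth = render_scene(scene, gun)
    write_wav(sim / "scene.wav", audio)
    truth.to_csv(sim / "scene_truth.csv", index=False)

    control = simulate_control_experiment(ControlShotDesign(seed=cfg.seed + 1))
    control.to_csv(sim / "control_shots.csv", index=False)

    season_kwargs = dict(cfg.season)
    for key in ("season_start", "season_end", "peak_date"):
        if isinstance(season_kwargs.get(key), str):
            season_kwargs[key] = date.fromisoformat(season_kwargs[key])
    season_spec = SeasonSimSpec(seed=cfg.seed + 2, **season_kwargs)
    truth_log, detected_log = simulate_season(season_spec)
    truth_log.to_csv(sim / "season_truth.csv", index=False)
    detected_log.to_csv(sim / "season_detected.csv", index=False)

    manifest["outputs"] += [str(sim / n) for n in
                            ("scene.wav", "scene_truth.csv", "control_shots.csv",
                             "season_truth.csv", "season_detected.csv")]
    log.info("simulate: %d scene events, %d control shots, %d season events",
             len(truth), len(control), len(truth_log))


def _stage_detect(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    wav = out / "sim" / "scene.wav"
    if not wav.exists():
        raise DependencyError("detect", str(wav))
    audio = read_wav(wav, sensor_id="synthetic")
    gun = GunshotSpec()
    params = StftParams(cfg.stft_window, cfg.stft_hop)
    clips = [synth_gunshot(gun, d, audio.sample_rate_hz) for d in (100.0, 200.0, 400.0)]
    template = build_template(clips, audio.sample_rate_hz, gun.duration_s,
                              (gun.band_low_hz, gun.band_high_hz), params)
    events = detect_recording(audio, template, cfg.threshold, cfg.min_separation_s, params)
    det = out / "detections"
    det.mkdir(parents=True, exist_ok=True)
    write_selection_table(events, det / "scene_selections.txt")
    pd.DataFrame([{
        "sensor_id": e.sensor_id, "begin_s": e.begin_s, "end_s": e.end_s,
        "peak_score": e.peak_score, "n_gunshots": e.n_gunshots,
    } for e in events]).to_csv(det / "detections.csv", index=False)
    manifest["outputs"] += [str(det / "scene_selections.txt"), str(det / "detections.csv")]
    log.info("detect: threshold=%.2f events=%d shots=%d", cfg.threshold,
             len(events), sum(e.n_gunshots for e in events))


def _stage_calibrate(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    det_csv = out / "detections" / "detections.csv"
    truth_csv = out / "sim" / "scene_truth.csv"
    control_csv = out / "sim" / "control_shots.csv"
    for p in (det_csv, truth_csv, control_csv):
        if not p.exists():
            raise DependencyError("calibrate", str(p))
    det = pd.read_csv(det_csv)
    truth = pd.read_csv(truth_csv)
    match = match_detections(det["begin_s"] + (det["end_s"] - det["begin_s"]) / 2,
                             truth["onset_s"], cfg.match_tolerance_s)
    recall = estimate_recall(match)
    control = pd.read_csv(control_csv)
    model = fit_logistic_range(control)
    radius = effective_radius(model, cfg.p_cut, cfg.max_observed_m)
    report = {
        "true_positives": match.true_positives,
        "false_negatives": match.false_negatives,
        "false_positives": match.false_positives,
        "recall": recall.recall,
        "adjustment_factor": recall.adjustment_factor,
        "beta0": model.beta0,
        "beta1": model.beta1,
        "separation_flag": model.separation_flag,
        "radius_m": radius,
        "area_km2": monitored_area(radius),
    }
    path = out / "calibration.json"
    path.write_text(json.dumps(report, indent=2) + "\n")
    manifest["outputs"].append(str(path))
    log.info("calibrate: recall=%.3f factor=%.3f radius=%.0fm area=%.1fkm2",
             recall.recall, recall.adjustment_factor, radius, report["area_km2"])


def _stage_estimate(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    counts = load_counts(cfg.counts_csv) if cfg.counts_csv else ionian_counts()
    configs, recall, precision = (load_strata(cfg.strata_yaml) if cfg.strata_yaml
                                  else ionian_strata())
    y2021 = counts[counts["year"] == 2021]
    per_stratum = (y2021.groupby("stratum", sort=False)["detected_gunshots"].sum())
    estimates = []
    for label in configs:
        detected = int(per_stratum.get(label, 0))
        adjusted = adjust_counts(detected, recall, precision)
        estimates.append(estimate_harvest(adjusted, configs[label], label=label,
                                          detected=detected))
    total = aggregate(estimates)
    rows = [e.display() for e in estimates] + [total.display()]
    table2 = pd.DataFrame(rows)
    est_dir = out
    table2.to_csv(est_dir / "harvest_table.csv", index=False)
    summary = {
        "recall": recall,
        "adjusted_gunshots_total": total.display()["adjusted_gunshots"],
        "killed_total": total.display()["killed_extrapolated"],
        "killed_or_injured_total": total.display()["killed_or_injured_extrapolated"],
    }
    if cfg.breeding_pairs:
        summary["percent_of_breeding_stock"] = percent_of_breeding_stock(
            total.killed_or_injured_extrapolated, cfg.breeding_pairs)
    (est_dir / "harvest_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    manifest["outputs"] += [str(est_dir / "harvest_table.csv"),
                            str(est_dir / "harvest_summary.json")]
    log.info("estimate: adjusted=%d killed=%d killed_or_injured=%d",
             summary["adjusted_gunshots_total"], summary["killed_total"],
             summary["killed_or_injured_total"])


def _stage_report(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    counts = load_counts(cfg.counts_csv) if cfg.counts_csv else ionian_counts()
    per_site, change = change_table(counts)
    report = {
        "grand_total_gunshots": int(counts["detected_gunshots"].sum()),
        "change_2021_2022_percent": change.percent_change,
        "change_excluded_sites": list(change.excluded_sites),
    }
    season_csv = out / "sim" / "season_truth.csv"
    if season_csv.exists():
        events = pd.read_csv(season_csv, parse_dates=["timestamp"])
        if len(events):
            frac, _ = seasonal_summary(events, "2021-04-10", "2021-05-05")
            hist, day_frac = diel_summary(events)
            report["seasonal_fraction_apr10_may5"] = frac
            report["diel_fraction_7am_5pm"] = day_frac
            report["weekday_counts"] = weekday_summary(events).to_dict()
    per_site.to_csv(out / "change_table.csv", index=False)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    manifest["outputs"] += [str(out / "change_table.csv"), str(out / "report.json")]
    log.info("report: grand_total=%d change=%.1f%%",
             report["grand_total_gunshots"], change.percent_change)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "detect": _stage_detect,
    "calibrate": _stage_calibrate,
    "estimate": _stage_estimate,
    "report": _stage_report,
}


def run_pipeline(config: PipelineConfig, stages=STAGES) -> dict:
    """Execute the requested stages in dependency order; return the manifest.

    An empty stage list writes the manifest only. When the output
    directory already holds a manifest for an identical config and all
    its outputs still exist, the run is a no-op unless ``config.force``.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGES if s in stages]
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"

    if manifest_path.exists() and not config.force:
        prev = json.loads(manifest_path.read_text())
        same = prev.get("config_hash") == config.config_hash()
        done = set(ordered) <= set(prev.get("stages", []))
        if same and done and all(Path(p).exists() for p in prev.get("outputs", [])):
            log.info("config unchanged and outputs present: no-op")
            return prev

    manifest = {
        "version": _version,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": ordered,
        "inputs": {
            "counts_csv": config.counts_csv or "packaged:ionian_counts.csv",
            "strata_yaml": config.strata_yaml or "packaged:ionian_strata.yaml",
        },
        "outputs": [],
    }
    for stage in ordered:
        _STAGE_FUNCS[stage](config, out, manifest)
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    manifest["outputs"].append(str(manifest_path))
    return manifest
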