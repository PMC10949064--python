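"""End-to-end orchestration: simulate → detect → calibrate → stats → huddle → report.

Each stage reads the previous stage's files from the output directory and
writes its own, so partial failures leave completed outputs intact.  A run
manifest records the configuration hash, root seed and a checksum of every
artifact; identical configuration and seed reproduce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrate import (
    DEFAULT_GRID,
    NoValidThresholdError,
    compare_durations,
    fit_breakpoint,
    select_threshold,
    sweep_thresholds,
)
from .detect import (
    assign_drinks,
    detect_bouts_behaviour,
    detect_bouts_tsk,
    drink_tallies,
    drop_last_torpor,
)
from .huddle import compare_hsi, compute_hsi, observer_agreement, randomize_blind
from .io import (
    dump_json,
    read_bats,
    read_bouts,
    read_drinks,
    read_masks,
    read_movements,
    read_traces,
    write_bouts,
    write_cohort,
)
from .stats import (
    cohens_d,
    fit_count_glm,
    fit_drink_proportion_glm,
    fit_duration_mixed_model,
    fit_mass_loss_glm,
    repeatability,
    welch_t,
)
from .synthetic import SimulationConfig, simulate_cohort

__all__ = ["RunManifest", "StageError", "run_pipeline", "make_report", "ALL_STAGES"]

log = logging.getLogger("torporlab")

ALL_STAGES = ("simulate", "detect", "calibrate", "stats", "huddle", "report")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[str]
    version: str
    checksums: dict[str, str] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        dump_json(self.__dict__, path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def load_config(config) -> dict:
    """Accept a dict, a YAML/JSON path, or None (all-defaults run)."""
    if config is None:
        return {"simulation": {}, "detection": {}, "calibration": {},
                "stats": {}, "huddle": {}}
    if isinstance(config, dict):
        return dict(config)
    text = Path(config).read_text()
    loaded = yaml.safe_load(text)
    if not isinstance(loaded, dict):
        raise ValueError(f"config file {config} did not parse to a mapping")
    return loaded


def _model_to_dict(result) -> dict:
    return {
        "response": result.response,
        "family": result.family,
        "transform": result.transform,
        "terms": {
            str(t): {
                "estimate": float(result.table.loc[t, "estimate"]),
                "se": float(result.table.loc[t, "se"]),
                "stat": float(result.table.loc[t, "stat"]),
                "p": float(result.table.loc[t, "p"]),
            }
            for t in result.table.index
        },
        "extras": result.extras,
    }


def run_pipeline(
    config=None,
    out_dir="runs/latest",
    seed: int | None = None,
    stages: list[str] | None = None,
) -> RunManifest:
    """Run the requested stages and return the manifest.

    ``config`` may be a mapping or a YAML/JSON file path with optional
    sections ``simulation``, ``detection``, ``calibration``, ``stats``,
    ``huddle``.  When no explicit ``stages`` are given, every stage runs,
    except ``huddle`` which is skipped if the config omits its section.
    ``seed`` overrides the config's root seed.
    """
    cfg = load_config(config)
    if seed is None:
        seed = int(cfg.get("seed", 0))
    if stages is None:
        stages = [
            s for s in ALL_STAGES if s != "huddle" or "huddle" in cfg
        ]
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    written: list[Path] = []
    if "simulate" in stages:
        written += _stage_simulate(cfg, seed, out)
    if "detect" in stages:
        written += _stage_detect(cfg, out)
    if "calibrate" in stages:
        written += _stage_calibrate(cfg, out)
    if "stats" in stages:
        written += _stage_stats(cfg, out)
    if "huddle" in stages:
        written += _stage_huddle(cfg, seed, out)
    if "report" in stages:
        written += make_report(out)

    manifest = RunManifest(
        config_hash=_config_hash({**cfg, "seed": seed}),
        seed=seed,
        stages=list(stages),
        version=__version__,
        checksums={
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(written))
        },
    )
    manifest.write(out / "manifest.json")
    return manifest


def _sim_config(cfg: dict, seed: int) -> SimulationConfig:
    kwargs = dict(cfg.get("simulation", {}))
    kwargs["seed"] = seed
    return SimulationConfig(**kwargs)


def _stage_simulate(cfg: dict, seed: int, out: Path) -> list[Path]:
    sim = _sim_config(cfg, seed)
    bundle = simulate_cohort(sim)
    files = write_cohort(bundle, out)
    log.info(
        "simulate: %d bats, %d drink events, %d masks",
        len(bundle.traces), len(bundle.drink_events), len(bundle.huddle_masks),
    )
    return files


def _read_stage_inputs(out: Path, stage: str, names: list[str]) -> dict:
    loaded = {}
    for name in names:
        path = out / name
        if not path.exists():
            raise StageError(stage, f"missing input file {path}")
        loaded[name] = path
    return loaded


def _stage_detect(cfg: dict, out: Path) -> list[Path]:
    det = cfg.get("detection", {})
    threshold = float(det.get("threshold_c", 20.0))
    merge_gap = float(det.get("merge_gap_min", 90.0))
    end_rule = det.get("end_rule", "last_movement")
    paths = _read_stage_inputs(out, "detect", ["traces.csv", "movements.csv", "bats.csv"])
    try:
        bats = read_bats(paths["bats.csv"])
        treatments = {b.bat_id: b.treatment for b in bats}
        traces = read_traces(paths["traces.csv"], treatments)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("detect", f"could not parse {paths['traces.csv']}: {exc}")
    span = (0.0, float(max(t.span[1] for t in traces)))
    logs = read_movements(
        paths["movements.csv"], span, treatments, all_bat_ids=sorted(treatments)
    )
    bouts = []
    for trace in traces:
        bouts.extend(detect_bouts_tsk(trace, threshold))
    for mlog in logs:
        bouts.extend(detect_bouts_behaviour(mlog, merge_gap=merge_gap, end_rule=end_rule))
    path = out / "bouts.csv"
    write_bouts(bouts, path)
    n_tsk = sum(b.source == "tsk_threshold" and b.kind == "arousal" for b in bouts)
    n_beh = sum(b.source == "behaviour" and b.kind == "arousal" for b in bouts)
    log.info("detect: %d T_sk arousals (at %.1f °C), %d behavioural arousals",
             n_tsk, threshold, n_beh)
    return [path]


def _stage_calibrate(cfg: dict, out: Path) -> list[Path]:
    cal = cfg.get("calibration", {})
    grid = cal.get("grid", list(DEFAULT_GRID))
    paths = _read_stage_inputs(out, "calibrate", ["traces.csv", "bouts.csv", "bats.csv"])
    bats = read_bats(paths["bats.csv"])
    treatments = {b.bat_id: b.treatment for b in bats}
    traces = read_traces(paths["traces.csv"], treatments)
    bouts = read_bouts(paths["bouts.csv"], treatments)
    behaviour = [
        (b.bat_id, b.duration_min)
        for b in bouts
        if b.source == "behaviour" and b.kind == "arousal" and not b.censored
    ]
    sweep = sweep_thresholds(traces, grid)
    fit = fit_breakpoint(sweep.thresholds, sweep.counts)
    dunnett = compare_durations(sweep, behaviour, method=cal.get("method", "montecarlo"))
    try:
        selected = select_threshold(fit, dunnett, grid)
        selection_error = None
    except NoValidThresholdError as exc:
        selected, selection_error = None, str(exc)
    sweep_path = out / "sweep.csv"
    sweep.to_frame().to_csv(sweep_path, index=False)
    report = {
        "psi": fit.psi,
        "has_breakpoint": fit.has_breakpoint,
        "left_slope": fit.left_slope,
        "right_slope": fit.right_slope,
        "breakpoint_f": fit.f_stat,
        "breakpoint_p": fit.f_p,
        "segment_stats": fit.segment_stats,
        "dunnett": {
            str(t): {
                "mean_diff": float(dunnett.table.loc[t, "mean_diff"]),
                "p_adj": float(dunnett.table.loc[t, "p_adj"]),
            }
            for t in dunnett.table.index
        },
        "levene_p": dunnett.levene_p,
        "selected_threshold_c": selected,
        "selection_error": selection_error,
    }
    cal_path = out / "calibration_report.json"
    dump_json(report, cal_path)
    log.info("calibrate: psi=%.1f °C, selected threshold=%s", fit.psi, selected)
    return [sweep_path, cal_path]


def _stage_stats(cfg: dict, out: Path) -> list[Path]:
    paths = _read_stage_inputs(out, "stats", ["bouts.csv", "bats.csv", "drinks.csv"])
    bats = read_bats(paths["bats.csv"])
    treatments = {b.bat_id: b.treatment for b in bats}
    bouts = read_bouts(paths["bouts.csv"], treatments)
    drinks = read_drinks(paths["drinks.csv"])

    behaviour = [b for b in bouts if b.source == "behaviour"]
    analysis_bouts = []
    for bat in sorted(treatments):
        per_bat = sorted(
            (b for b in behaviour if b.bat_id == bat), key=lambda b: b.start_min
        )
        analysis_bouts.extend(drop_last_torpor(per_bat))
    by_bat = {b.bat_id: b for b in bats}
    for bat in sorted(treatments):
        arousals = [
            b for b in analysis_bouts if b.bat_id == bat and b.kind == "arousal"
        ]
        assigned = assign_drinks([d for d in drinks if d.bat_id == bat], arousals)
        tallies = drink_tallies(assigned, arousals)
        rec = by_bat[bat]
        rec.n_arousals = len(arousals)
        rec.n_drinks = tallies["total_drinks"]
        rec.n_arousals_with_drink = tallies["arousals_with_drink"]
        rec.n_arousals_without_drink = tallies["arousals_without_drink"]

    report: dict = {"per_bat": [
        {
            "bat_id": b.bat_id, "treatment": b.treatment,
            "initial_mass_g": b.initial_mass, "mass_loss_g": b.mass_loss,
            "arousals": b.n_arousals, "drinks": b.n_drinks,
            "arousals_with_drink": b.n_arousals_with_drink,
        }
        for b in bats
    ]}

    for response in ("arousal_h", "torpor_day"):
        fit = fit_duration_mixed_model(analysis_bouts, bats, response)
        report[f"mixed_{response}"] = _model_to_dict(fit)
        kind = "arousal" if response == "arousal_h" else "torpor"
        scale = 60.0 if response == "arousal_h" else 1440.0
        meas = [
            (b.bat_id, np.sqrt(b.duration_min / scale))
            for b in analysis_bouts
            if b.kind == kind and not b.censored
        ]
        rep = repeatability(meas)
        report[f"repeatability_{response}"] = {
            "r": rep.r, "v_individual": rep.v_individual,
            "v_residual": rep.v_residual, "lrt_chisq": rep.lrt_chisq,
            "lrt_p": rep.lrt_p,
        }

    report["glm_arousals"] = _model_to_dict(fit_count_glm(bats, "arousals"))
    report["glm_drinks"] = _model_to_dict(fit_count_glm(bats, "drinks"))
    report["glm_drink_proportion"] = _model_to_dict(fit_drink_proportion_glm(bats))
    report["glm_mass_loss"] = _model_to_dict(fit_mass_loss_glm(bats))

    groups = {
        tr: [b for b in bats if b.treatment == tr] for tr in ("humid", "dry")
    }
    if all(len(g) >= 2 for g in groups.values()):
        h, d = groups["humid"], groups["dry"]
        report["welch_initial_mass"] = welch_t(
            [b.initial_mass for b in h], [b.initial_mass for b in d]
        )
        for name, get in (
            ("arousals", lambda b: b.n_arousals),
            ("drinks", lambda b: b.n_drinks),
            ("drink_proportion", lambda b: (
                b.n_arousals_with_drink / b.n_arousals if b.n_arousals else 0.0
            )),
        ):
            try:
                es = cohens_d([get(b) for b in h], [get(b) for b in d])
                report[f"cohens_d_{name}"] = {"d": es.d, "magnitude": es.magnitude}
            except ValueError:
                report[f"cohens_d_{name}"] = {"d": None, "magnitude": "undefined"}
    path = out / "stats_report.json"
    dump_json(report, path)
    log.info("stats: %d analysis bouts over %d bats", len(analysis_bouts), len(bats))
    return [path]


def _stage_huddle(cfg: dict, seed: int, out: Path) -> list[Path]:
    mask_dir = out / "masks"
    if not mask_dir.exists():
        raise StageError("huddle", f"missing input directory {mask_dir}")
    masks = read_masks(mask_dir)
    if not masks:
        raise StageError("huddle", f"no masks found in {mask_dir}")
    ordered, key = randomize_blind(masks, seed)
    values = [compute_hsi(m) for _, m in ordered]
    hsi_path = out / "hsi.csv"
    pd.DataFrame(
        [(v.image_id, v.treatment, v.hsi) for v in values],
        columns=["image_id", "treatment", "hsi_percent"],
    ).sort_values("image_id").to_csv(hsi_path, index=False)

    by_tr: dict[str, list[float]] = {}
    for v in values:
        by_tr.setdefault(v.treatment, []).append(v.hsi)
    report: dict = {"blind_key": key, "n_images": len(masks)}
    observers = sorted({m.observer for m in masks})
    if len(observers) == 2:
        a = sorted((m for m in masks if m.observer == observers[0]),
                   key=lambda m: m.image_id)
        b = sorted((m for m in masks if m.observer == observers[1]),
                   key=lambda m: m.image_id)
        report["observer_agreement"] = observer_agreement(
            [compute_hsi(m).hsi for m in a], [compute_hsi(m).hsi for m in b]
        )
    else:
        report["observer_agreement"] = None  # single observer set
    if len(by_tr) == 2:
        contrast, effect = compare_hsi(by_tr)
        report["treatment_contrast"] = _model_to_dict(contrast)
        report["cohens_d"] = {"d": effect.d, "magnitude": effect.magnitude}
        report["mean_hsi"] = {tr: float(np.mean(v)) for tr, v in by_tr.items()}
    agr_path = out / "agreement_report.json"
    dump_json(report, agr_path)
    log.info("huddle: %d images", len(masks))
    return [hsi_path, agr_path]


def make_report(out_dir) -> list[Path]:
    """Assemble the per-run summary report (JSON + Markdown)."""
    out = Path(out_dir)
    paths = _read_stage_inputs(out, "report", ["calibration_report.json", "stats_report.json"])
    cal = json.loads(paths["calibration_report.json"].read_text())
    stats = json.loads(paths["stats_report.json"].read_text())
    hsi_file = out / "agreement_report.json"
    huddle = json.loads(hsi_file.read_text()) if hsi_file.exists() else None

    per_bat = pd.DataFrame(stats["per_bat"])
    by_tr = per_bat.groupby("treatment")
    summary = {
        "selected_threshold_c": cal["selected_threshold_c"],
        "breakpoint_c": cal["psi"],
        "has_breakpoint": cal["has_breakpoint"],
        "arousals_per_treatment": by_tr["arousals"].sum().to_dict(),
        "mean_arousals_per_bat": by_tr["arousals"].mean().to_dict(),
        "mean_drinks_per_bat": by_tr["drinks"].mean().to_dict(),
        "mixed_arousal_h": stats["mixed_arousal_h"],
        "mixed_torpor_day": stats["mixed_torpor_day"],
        "repeatability_arousal_h": stats["repeatability_arousal_h"],
        "repeatability_torpor_day": stats["repeatability_torpor_day"],
        "glm_arousals": stats["glm_arousals"],
        "glm_drinks": stats["glm_drinks"],
        "glm_drink_proportion": stats["glm_drink_proportion"],
        "glm_mass_loss": stats["glm_mass_loss"],
        "effect_sizes": {
            k.replace("cohens_d_", ""): stats[k]
            for k in stats
            if k.startswith("cohens_d_")
        },
        "huddle": None
        if huddle is None
        else {
            "mean_hsi": huddle.get("mean_hsi"),
            "cohens_d": huddle.get("cohens_d"),
        },
    }
    json_path = out / "report.json"
    dump_json(summary, json_path)

    lines = [
        "# Hibernation pipeline report",
        "",
        f"- Breakpoint in count vs threshold: {cal['psi']:.1f} °C "
        f"(present: {cal['has_breakpoint']})",
        f"- Selected T_sk threshold: {cal['selected_threshold_c']} °C",
        "",
        "## Per-treatment summaries",
        "",
    ]
    for tr, sub in by_tr:
        lines.append(
            f"- {tr}: {int(sub['arousals'].sum())} arousals over {len(sub)} bats; "
            f"mean drinks/bat {sub['drinks'].mean():.1f}"
        )
    if huddle is not None and huddle.get("mean_hsi"):
        lines += ["", "## Huddle size", ""]
        for tr, v in huddle["mean_hsi"].items():
            lines.append(f"- {tr}: mean HSI {v:.2f}%")
        if huddle.get("cohens_d"):
            lines.append(
                f"- Cohen's d: {huddle['cohens_d']['d']:.2f} "
                f"({huddle['cohens_d']['magnitude']})"
            )
    md_path = out / "report.md"
    md_path.write_text("\n".join(lines) + "\n")
    return [json_path, md_path]
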