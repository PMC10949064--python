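"""CSV / PNG / JSON readers and writers for the pipeline's fixture set."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .detect import Bout, DrinkEvent, MovementLog, TskTrace
from .huddle import HuddleMask
from .stats import BatRecord

__all__ = [
    "write_cohort",
    "read_traces",
    "read_movements",
    "read_drinks",
    "read_bats",
    "read_masks",
    "write_bouts",
    "read_bouts",
    "dump_json",
]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def dump_json(obj, path: Path) -> None:
    Path(path).write_text(json.dumps(_plain(obj), indent=1, sort_keys=True) + "\n")


def write_cohort(bundle, out_dir) -> list[Path]:
    """Write a simulated cohort as the standard fixture set.

    traces.csv, movements.csv, drinks.csv, bats.csv, masks/*.png, truth.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    rows = []
    for tr in bundle.traces:
        rows.append(
            pd.DataFrame(
                {
                    "bat_id": tr.bat_id,
                    "time_min": tr.times,
                    "tsk_c": tr.tsk,
                    "valid": tr.valid.astype(int),
                }
            )
        )
    p = out / "traces.csv"
    pd.concat(rows, ignore_index=True).to_csv(p, index=False)
    written.append(p)

    p = out / "movements.csv"
    pd.DataFrame(
        [
            (log.bat_id, s, e)
            for log in bundle.movement_logs
            for s, e in log.intervals
        ],
        columns=["bat_id", "start_min", "end_min"],
    ).to_csv(p, index=False)
    written.append(p)

    p = out / "drinks.csv"
    pd.DataFrame(
        [(d.bat_id, d.time_min) for d in bundle.drink_events],
        columns=["bat_id", "time_min"],
    ).to_csv(p, index=False)
    written.append(p)

    p = out / "bats.csv"
    pd.DataFrame(
        [
            (b.bat_id, b.treatment, b.initial_mass, b.final_mass)
            for b in bundle.bat_records
        ],
        columns=["bat_id", "treatment", "initial_mass_g", "final_mass_g"],
    ).to_csv(p, index=False)
    written.append(p)

    mask_dir = out / "masks"
    mask_dir.mkdir(exist_ok=True)
    for m in bundle.huddle_masks:
        p = mask_dir / f"{m.image_id}.png"
        Image.fromarray((m.pixels.astype(np.uint8)) * 255, mode="L").save(p)
        written.append(p)

    p = out / "truth.json"
    dump_json(bundle.truth, p)
    written.append(p)
    return written


def read_bats(path) -> list[BatRecord]:
    df = pd.read_csv(path)
    return [
        BatRecord(
            bat_id=str(r.bat_id),
            treatment=str(r.treatment),
            initial_mass=float(r.initial_mass_g),
            final_mass=float(r.final_mass_g),
        )
        for r in df.itertuples()
    ]


def read_traces(path, treatments: dict[str, str] | None = None) -> list[TskTrace]:
    df = pd.read_csv(path)
    required = {"bat_id", "time_min", "tsk_c", "valid"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    traces = []
    for bat_id, sub in df.groupby("bat_id", sort=True):
        sub = sub.sort_values("time_min")
        traces.append(
            TskTrace(
                bat_id=str(bat_id),
                treatment=(treatments or {}).get(str(bat_id), ""),
                times=sub["time_min"].to_numpy(float),
                tsk=sub["tsk_c"].to_numpy(float),
                valid=sub["valid"].to_numpy(bool),
            )
        )
    return traces


def read_movements(
    path,
    observation_span: tuple[float, float],
    treatments: dict[str, str] | None = None,
    all_bat_ids: list[str] | None = None,
) -> list[MovementLog]:
    df = pd.read_csv(path)
    logs = {}
    for bat_id, sub in df.groupby("bat_id", sort=True):
        sub = sub.sort_values("start_min")
        logs[str(bat_id)] = MovementLog(
            bat_id=str(bat_id),
            intervals=list(zip(sub["start_min"], sub["end_min"])),
            observation_span=observation_span,
            treatment=(treatments or {}).get(str(bat_id), ""),
        )
    for bat_id in all_bat_ids or []:
        if bat_id not in logs:  # animal that never moved: empty log
            logs[bat_id] = MovementLog(
                bat_id=bat_id, intervals=[], observation_span=observation_span,
                treatment=(treatments or {}).get(bat_id, ""),
            )
    return [logs[k] for k in sorted(logs)]


def read_drinks(path) -> list[DrinkEvent]:
    df = pd.read_csv(path)
    return [
        DrinkEvent(bat_id=str(r.bat_id), time_min=float(r.time_min))
        for r in df.itertuples()
    ]


def read_masks(mask_dir) -> list[HuddleMask]:
    masks = []
    for p in sorted(Path(mask_dir).glob("*.png")) + sorted(Path(mask_dir).glob("*.pgm")):
        arr = np.asarray(Image.open(p).convert("L")) > 127
        image_id = p.stem
        treatment = image_id.split("_")[0] if "_" in image_id else ""
        masks.append(HuddleMask(image_id=image_id, treatment=treatment, pixels=arr))
    return masks


_BOUT_COLS = [
    "bat_id", "source", "kind", "threshold_c", "start_min", "end_min",
    "duration_min", "left_censored", "right_censored",
]


def write_bouts(bouts: list[Bout], path) -> None:
    pd.DataFrame(
        [
            (
                b.bat_id, b.source, b.kind,
                b.threshold_c if b.threshold_c is not None else "",
                b.start_min, b.end_min, b.duration_min,
                int(b.left_censored), int(b.right_censored),
            )
            for b in bouts
        ],
        columns=_BOUT_COLS,
    ).to_csv(path, index=False)


def read_bouts(path, treatments: dict[str, str] | None = None) -> list[Bout]:
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples():
        out.append(
            Bout(
                bat_id=str(r.bat_id),
                source=str(r.source),
                kind=str(r.kind),
                threshold_c=None if pd.isna(r.threshold_c) else float(r.threshold_c),
                start_min=float(r.start_min),
                end_min=float(r.end_min),
                left_censored=bool(r.left_censored),
                right_censored=bool(r.right_censored),
                treatment=(treatments or {}).get(str(r.bat_id), ""),
            )
        )
    return out
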