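"""Torpor/arousal segmentation from skin temperature and from behaviour.

Two detectors are implemented:

* a skin-temperature (``T_sk``) threshold rule — an animal is scored
  normothermic once ``T_sk`` rises *above* a threshold for at least two
  consecutive datalogger readings, and torpid once it falls to or below the
  threshold for at least two readings; single-sample excursions never switch
  state; and
* a behavioural rule — any recorded movement marks an arousal, and an
  arousal ends once the animal has been motionless for longer than a merge
  gap (default 90 min); movement bouts separated by less stillness than the
  gap are merged into one arousal.

Both detectors emit :class:`Bout` records on half-open ``[start, end)``
intervals in minutes since the start of observation.  Bouts that abut the
edge of the record (or an invalid stretch of the logger trace) are flagged
censored and are conventionally excluded from duration statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TskTrace",
    "MovementLog",
    "Bout",
    "DrinkEvent",
    "detect_bouts_tsk",
    "detect_bouts_behaviour",
    "drop_last_torpor",
    "assign_drinks",
    "drink_tallies",
]


@dataclass
class TskTrace:
    """One animal's quantized skin-temperature series on a regular grid.

    Parameters
    ----------
    bat_id : str
        Animal identifier.
    treatment : str
        Treatment label, e.g. ``"humid"`` or ``"dry"``.
    times : ndarray
        Sample times in minutes since experiment start; strictly increasing
        at a constant cadence.
    tsk : ndarray
        Skin temperature in °C per sample; must be finite wherever valid.
    valid : ndarray of bool
        Per-sample validity mask (False after logger shedding/failure).
    """

    bat_id: str
    treatment: str
    times: np.ndarray
    tsk: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.tsk = np.asarray(self.tsk, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.times.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.times.shape == self.tsk.shape == self.valid.shape):
            raise ValueError("times, tsk and valid must have equal length")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(steps, steps[0]):
                raise ValueError("trace cadence is not regular")
        if np.any(~np.isfinite(self.tsk[self.valid])):
            raise ValueError("tsk must be finite where valid")

    @property
    def cadence(self) -> float:
        """Sampling interval in minutes."""
        if self.times.size < 2:
            raise ValueError("cadence undefined for traces of fewer than 2 samples")
        return float(self.times[1] - self.times[0])

    @property
    def span(self) -> tuple[float, float]:
        """Half-open observation interval covered by the samples."""
        return float(self.times[0]), float(self.times[-1] + self.cadence)


@dataclass
class MovementLog:
    """Observed motion intervals for one animal within a video span.

    ``intervals`` are half-open ``[start, end)`` pairs in minutes, sorted and
    non-overlapping, contained in ``observation_span``.
    """

    bat_id: str
    intervals: list[tuple[float, float]]
    observation_span: tuple[float, float]
    treatment: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.observation_span
        if not lo < hi:
            raise ValueError("observation_span must be non-empty")
        prev_end = lo
        for s, e in self.intervals:
            if not s < e:
                raise ValueError(f"empty movement interval [{s}, {e})")
            if s < prev_end:
                raise ValueError("movement intervals must be sorted and disjoint")
            if e > hi:
                raise ValueError("movement interval outside observation span")
            prev_end = e


@dataclass(frozen=True)
class Bout:
    """A detected torpor bout or arousal."""

    bat_id: str
    kind: str  # "torpor" | "arousal"
    source: str  # "tsk_threshold" | "behaviour"
    start_min: float
    end_min: float
    left_censored: bool = False
    right_censored: bool = False
    threshold_c: float | None = None
    treatment: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("torpor", "arousal"):
            raise ValueError(f"unknown bout kind {self.kind!r}")
        if not self.end_min > self.start_min:
            raise ValueError("bout duration must be positive")

    @property
    def duration_min(self) -> float:
        return self.end_min - self.start_min

    @property
    def censored(self) -> bool:
        return self.left_censored or self.right_censored


@dataclass
class DrinkEvent:
    """A drinking visit to the water dish at ``time_min``."""

    bat_id: str
    time_min: float
    assigned_arousal: int | None = None  # index into the arousal list
    flagged: bool = False


def _valid_segments(valid: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in ``valid`` as (start, stop) index pairs."""
    if valid.size == 0:
        return []
    padded = np.concatenate(([False], valid, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _run_lengths(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a boolean array: (run start indices, run lengths)."""
    change = np.flatnonzero(np.diff(states))
    starts = np.concatenate(([0], change + 1))
    lengths = np.diff(np.concatenate((starts, [states.size])))
    return starts, lengths


def detect_bouts_tsk(trace: TskTrace, threshold: float) -> list[Bout]:
    """Segment a trace into torpor bouts and arousals at a ``T_sk`` threshold.

    The state machine scans valid samples only.  The state flips to
    normothermic at the first sample of a run of at least two consecutive
    samples strictly above ``threshold``, and to torpid at the first sample
    of a run of at least two samples at or below it.  Samples before the
    first qualifying run belong to a censored bout of the initial state's
    kind.  Bouts never span invalid gaps; bouts that abut a trace edge or an
    invalid gap are censored on that side.

    Returns bouts sorted by start time.  A trace with no valid samples
    yields an empty list with a warning.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if not np.any(trace.valid):
        warnings.warn(f"trace {trace.bat_id}: no valid samples", stacklevel=2)
        return []
    dt = trace.cadence
    bouts: list[Bout] = []
    for seg_lo, seg_hi in _valid_segments(trace.valid):
        t = trace.times[seg_lo:seg_hi]
        above = trace.tsk[seg_lo:seg_hi] > threshold
        if above.size < 2:
            continue
        starts, lengths = _run_lengths(above)
        qualifying = lengths >= 2
        if not np.any(qualifying):
            continue  # state never decidable within this segment
        q_starts = starts[qualifying]
        q_states = above[q_starts]
        # Collapse consecutive qualifying runs of the same state: only keep
        # indices where the decided state actually changes.
        flips = [q_starts[0]]
        state = q_states[0]
        for s, st in zip(q_starts[1:], q_states[1:]):
            if st != state:
                flips.append(s)
                state = st
        initial_state = bool(q_states[0])
        # The first qualifying run decides the initial state; samples before
        # it join that first (censored) bout, so it is not a boundary.
        boundaries = [t[0]] + [t[i] for i in flips[1:]] + [t[-1] + dt]
        kinds = []
        k = initial_state
        for _ in range(len(boundaries) - 1):
            kinds.append("arousal" if k else "torpor")
            k = not k
        for j, (b0, b1) in enumerate(zip(boundaries[:-1], boundaries[1:])):
            bouts.append(
                Bout(
                    bat_id=trace.bat_id,
                    kind=kinds[j],
                    source="tsk_threshold",
                    start_min=float(b0),
                    end_min=float(b1),
                    left_censored=(j == 0),
                    right_censored=(j == len(boundaries) - 2),
                    threshold_c=float(threshold),
                    treatment=trace.treatment,
                )
            )
    bouts.sort(key=lambda b: b.start_min)
    return bouts


def detect_bouts_behaviour(
    log: MovementLog,
    merge_gap: float = 90.0,
    end_rule: str = "last_movement",
) -> list[Bout]:
    """Segment a movement log into arousals and torpor bouts.

    Movement intervals whose intervening stillness is shorter than
    ``merge_gap`` minutes are merged into a single arousal.  Under the
    default ``end_rule="last_movement"`` an arousal ends with its last
    merged movement; ``"movement_plus_gap"`` extends each arousal by the
    stillness window instead (capped at the observation span), for users who
    prefer to count the terminal motionless period as part of the arousal.
    The complement of the arousals within the observation span forms the
    torpor bouts.  An empty log yields a single fully censored torpor bout.
    """
    if end_rule not in ("last_movement", "movement_plus_gap"):
        raise ValueError(f"unknown end_rule {end_rule!r}")
    lo, hi = log.observation_span
    merged: list[list[float]] = []
    for s, e in log.intervals:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    if end_rule == "movement_plus_gap":
        merged = [[s, min(e + merge_gap, hi)] for s, e in merged]
    bouts: list[Bout] = []

    def torpor(s: float, e: float) -> None:
        if e > s:
            bouts.append(
                Bout(
                    bat_id=log.bat_id,
                    kind="torpor",
                    source="behaviour",
                    start_min=s,
                    end_min=e,
                    left_censored=(s == lo),
                    right_censored=(e == hi),
                    treatment=log.treatment,
                )
            )

    cursor = lo
    for s, e in merged:
        torpor(cursor, s)
        bouts.append(
            Bout(
                bat_id=log.bat_id,
                kind="arousal",
                source="behaviour",
                start_min=s,
                end_min=e,
                left_censored=(s == lo),
                right_censored=(e == hi),
                treatment=log.treatment,
            )
        )
        cursor = e
    torpor(cursor, hi)
    return bouts


def drop_last_torpor(bouts: list[Bout]) -> list[Bout]:
    """Drop the final bout when it is a torpor bout.

    Animals removed from hibernation while torpid leave a final torpor bout
    of arbitrary length; omitting it makes the arousal count exceed the
    torpor count by at most one.
    """
    if bouts and bouts[-1].kind == "torpor":
        return bouts[:-1]
    return list(bouts)


def assign_drinks(drinks: list[DrinkEvent], arousals: list[Bout]) -> list[DrinkEvent]:
    """Assign each drinking event to the arousal containing its timestamp.

    Arousals must come from the behavioural detector (drinking is observed
    on video).  Drinks falling outside every arousal are flagged and left
    unassigned, with a warning.
    """
    for b in arousals:
        if b.kind != "arousal":
            raise ValueError("assign_drinks expects arousal bouts only")
    starts = np.array([b.start_min for b in arousals])
    ends = np.array([b.end_min for b in arousals])
    out: list[DrinkEvent] = []
    n_flagged = 0
    for d in drinks:
        hit = np.flatnonzero((starts <= d.time_min) & (d.time_min < ends))
        if hit.size == 1:
            out.append(replace(d, assigned_arousal=int(hit[0]), flagged=False))
        else:
            out.append(replace(d, assigned_arousal=None, flagged=True))
            n_flagged += 1
    if n_flagged:
        warnings.warn(
            f"{n_flagged} drinking event(s) outside any arousal were flagged",
            stacklevel=2,
        )
    return out


def drink_tallies(
    assigned: list[DrinkEvent], arousals: list[Bout]
) -> dict[str, int]:
    """Per-animal tallies: total drinks, arousals with and without drinking.

    Flagged (unassigned) drinks are excluded from the totals.
    """
    drinking_arousals = {
        d.assigned_arousal for d in assigned if d.assigned_arousal is not None
    }
    total = sum(d.assigned_arousal is not None for d in assigned)
    return {
        "total_drinks": int(total),
        "arousals_with_drink": len(drinking_arousals),
        "arousals_without_drink": len(arousals) - len(drinking_arousals),
    }
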