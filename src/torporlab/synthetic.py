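"""Synthetic hibernation cohorts for end-to-end testing of the pipeline.

The generator emulates a two-incubator humidity experiment on hibernating
big brown bats: per-animal skin-temperature (``T_sk``) traces on a 15-min
grid quantized to 0.5 °C, movement and drinking logs from continuous video,
binary huddle masks, and body-mass records.  Event timelines are alternating
torpor/arousal renewal processes with gamma-distributed durations whose
treatment means default to the regimes reported for humid (98% RH) versus
dry (50% RH) hibernation at 8 °C.  Ground truth for every generated event is
returned alongside the data so detectors and statistics can be tested for
exact recovery.

Artifacts of real datalogger studies can be injected: heating artifacts
(``T_sk`` rises above 20 °C in a motionless animal, warmed by aroused
huddle-mates), sub-threshold movements (activity with only a shallow
``T_sk`` rise), shallow thermal events peaking below the torpid/normothermic
decision band, shed dataloggers and outright logger failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .detect import DrinkEvent, MovementLog, TskTrace
from .huddle import HuddleMask
from .stats import BatRecord

__all__ = [
    "ArtifactRates",
    "SimulationConfig",
    "CohortBundle",
    "simulate_cohort",
    "simulate_tsk_trace",
    "inject_artifacts",
    "simulate_huddle_masks",
]

TREATMENTS = ("humid", "dry")


def _check_map(name: str, m: dict) -> None:
    if set(m) != set(TREATMENTS):
        raise ValueError(f"{name} must have exactly the labels {set(TREATMENTS)}")


@dataclass
class ArtifactRates:
    """Expected artifact counts per animal over the study span.

    ``heating`` events peak above the 20 °C threshold (capped at 23.2 °C)
    with no associated movement; ``subthreshold`` events are movements whose
    ``T_sk`` peak stays in 11.3–18.6 °C; ``shallow`` events are motionless
    ``T_sk`` excursions peaking below the breakpoint region (≤ 17.4 °C),
    the kind that inflate arousal counts at low thresholds.  ``shed_prob``
    and ``failure_prob`` are per-animal probabilities of losing the logger
    mid-study or of it never recording.
    """

    heating_per_bat: float = 1.4
    subthreshold_per_bat: float = 1.2
    shallow_per_bat: float = 5.0
    shed_prob: float = 0.3
    failure_prob: float = 0.1
    heating_peak_range: tuple[float, float] = (20.5, 23.2)
    subthreshold_peak_range: tuple[float, float] = (11.3, 18.6)
    shallow_peak_range: tuple[float, float] = (12.5, 18.0)

    def __post_init__(self) -> None:
        for nm in ("heating_per_bat", "subthreshold_per_bat", "shallow_per_bat"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be non-negative")
        for nm in ("shed_prob", "failure_prob"):
            if not 0 <= getattr(self, nm) <= 1:
                raise ValueError(f"{nm} must be in [0, 1]")

    @classmethod
    def none(cls) -> "ArtifactRates":
        """All rates zero: clean traces, loggers never lost."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class SimulationConfig:
    """All tunables of the cohort generator, with study-condition defaults.

    Durations are gamma with the stated treatment means; shapes set the
    dispersion implied by the reported spread of bout durations.  A
    per-animal lognormal multiplier (``individual_cv``) creates the
    consistent individual differences that make durations repeatable.
    Rewarming follows an exponential approach to the normothermic plateau
    at an initial rate of ``rewarm_rate`` °C/min; cooling decays back to the
    torpid level at an initial rate of ``cool_rate``.
    """

    seed: int = 0
    n_bats_per_treatment: "int | dict" = field(
        default_factory=lambda: {"humid": 10, "dry": 9}
    )
    study_days: float = 110.0
    ambient_temp: float = 8.0
    sample_interval: float = 15.0  # minutes
    quantization_step: float = 0.5  # °C
    torpor_mean_days: dict = field(
        default_factory=lambda: {"humid": 8.3, "dry": 7.9}
    )
    arousal_mean_min: dict = field(
        default_factory=lambda: {"humid": 134.0, "dry": 106.0}
    )
    torpor_shape: float = 4.0
    arousal_shape: float = 2.7
    min_torpor_min: float = 720.0
    min_arousal_min: float = 45.0
    individual_cv: float = 0.25
    torpid_tsk_offset: float = 1.0  # °C above ambient
    normothermic_tsk_mean: float = 30.0
    plateau_jitter: float = 0.5  # uniform ± °C, before quantization
    torpid_jitter: float = 0.25
    rewarm_rate: float = 2.0  # °C/min
    cool_rate: float = 1.0
    merge_gap_min: float = 90.0  # stillness window used when fragmenting arousals
    p_drink_given_arousal: dict = field(
        default_factory=lambda: {"humid": 0.45, "dry": 0.75}
    )
    drink_extra_visits: dict = field(
        default_factory=lambda: {"humid": 0.35, "dry": 0.2}
    )
    drink_count_range: dict = field(
        default_factory=lambda: {"humid": (4, 12), "dry": (10, 28)}
    )
    hsi_mean: dict = field(default_factory=lambda: {"humid": 2.14, "dry": 1.81})
    hsi_sd: dict = field(default_factory=lambda: {"humid": 0.10, "dry": 0.20})
    n_photos: dict = field(default_factory=lambda: {"humid": 24, "dry": 27})
    mask_shape: tuple[int, int] = (238, 352)  # rows × cols = 352×238 resolution
    initial_mass_range: tuple[float, float] = (22.4, 29.5)
    massloss_at_min_mass: float = 3.0  # g lost by the lightest animal
    massloss_slope_on_initial_mass: float = 0.93  # g per g of initial mass
    massloss_noise_sd: float = 0.5
    cascade_strength: float = 0.0  # 0 = independent arousals (default)
    cascade_jitter_min: float = 60.0
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)

    def __post_init__(self) -> None:
        for bats in self.bats_by_treatment().values():
            if bats < 1:
                raise ValueError("n_bats_per_treatment must be positive")
        if self.study_days <= 0:
            raise ValueError("study_days must be positive")
        if self.sample_interval <= 0 or self.quantization_step <= 0:
            raise ValueError("sample_interval and quantization_step must be positive")
        if (self.study_days * 1440) % self.sample_interval != 0:
            raise ValueError("sample_interval must divide the study span")
        for nm in ("torpor_mean_days", "arousal_mean_min", "p_drink_given_arousal",
                   "drink_extra_visits", "drink_count_range", "hsi_mean",
                   "hsi_sd", "n_photos"):
            _check_map(nm, getattr(self, nm))
        for tr in TREATMENTS:
            if self.torpor_mean_days[tr] <= 0 or self.arousal_mean_min[tr] <= 0:
                raise ValueError("mean durations must be positive")
            if not 0 <= self.p_drink_given_arousal[tr] <= 1:
                raise ValueError("p_drink_given_arousal must be in [0, 1]")
            if not 0 < self.hsi_mean[tr] < 100:
                raise ValueError("hsi_mean must be a percentage in (0, 100)")
        if self.torpor_shape <= 0 or self.arousal_shape <= 0:
            raise ValueError("gamma shapes must be positive")
        if self.rewarm_rate <= 0 or self.cool_rate <= 0:
            raise ValueError("rewarm/cool rates must be positive")
        if self.normothermic_tsk_mean <= self.ambient_temp + self.torpid_tsk_offset:
            raise ValueError("normothermic level must exceed the torpid level")

    def bats_by_treatment(self) -> dict[str, int]:
        if isinstance(self.n_bats_per_treatment, dict):
            _check_map("n_bats_per_treatment", self.n_bats_per_treatment)
            return dict(self.n_bats_per_treatment)
        return {tr: int(self.n_bats_per_treatment) for tr in TREATMENTS}

    @property
    def span_min(self) -> float:
        return self.study_days * 1440.0


@dataclass
class CohortBundle:
    """Everything one simulated cohort produced, plus ground truth."""

    config: SimulationConfig
    traces: list[TskTrace]
    movement_logs: list[MovementLog]
    drink_events: list[DrinkEvent]
    huddle_masks: list[HuddleMask]
    bat_records: list[BatRecord]
    truth: dict
    artifacts: list[dict]


def _rng_for(config: SimulationConfig, *key: int) -> np.random.Generator:
    # One substream per (purpose, treatment, animal): adding an animal or a
    # stage never perturbs the draws of any other.
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    s2 = np.log1p(cv**2)
    return float(np.exp(rng.normal(-0.5 * s2, np.sqrt(s2))))


def _simulate_timeline(
    rng: np.random.Generator, config: SimulationConfig, treatment: str
) -> list[dict]:
    """Alternating torpor/arousal events tiling [0, span) exactly.

    The record always ends with a right-censored torpor bout (animals are
    removed from hibernation while torpid), so every arousal in the truth
    is complete.  An arousal is only kept if it ends at least 60 min before
    the span end, leaving room for the cool-down.
    """
    span = config.span_min
    tor_mean = config.torpor_mean_days[treatment] * 1440.0
    ar_mean = config.arousal_mean_min[treatment]
    f_tor = _lognormal_factor(rng, config.individual_cv)
    f_ar = _lognormal_factor(rng, config.individual_cv)
    events: list[dict] = []
    t = 0.0
    while True:
        d_tor = max(
            rng.gamma(config.torpor_shape, tor_mean * f_tor / config.torpor_shape),
            config.min_torpor_min,
        )
        if t + d_tor >= span - 60.0:
            events.append(_event("torpor", t, span, left=(t == 0), right=True))
            return events
        events.append(_event("torpor", t, t + d_tor, left=(t == 0)))
        t += d_tor
        d_ar = max(
            rng.gamma(config.arousal_shape, ar_mean * f_ar / config.arousal_shape),
            config.min_arousal_min,
        )
        if t + d_ar >= span - 60.0:
            # Would be cut by removal from hibernation: extend torpor instead.
            events[-1]["end_min"] = span
            events[-1]["right_censored"] = True
            return events
        events.append(_event("arousal", t, t + d_ar))
        t += d_ar


def _event(kind, start, end, left=False, right=False) -> dict:
    return {
        "kind": kind,
        "start_min": float(start),
        "end_min": float(end),
        "left_censored": bool(left),
        "right_censored": bool(right),
    }


def _check_tiling(events: list[dict], span: float) -> None:
    if not events:
        raise ValueError("empty event list")
    if events[0]["start_min"] != 0.0 or events[-1]["end_min"] != span:
        raise ValueError("events do not tile the study span")
    for a, b in zip(events[:-1], events[1:]):
        if a["end_min"] != b["start_min"] or a["end_min"] <= a["start_min"]:
            raise ValueError("events do not tile the study span")


def simulate_tsk_trace(
    bat_truth: list[dict],
    config: SimulationConfig,
    seed: "int | np.random.Generator",
    bat_id: str = "bat",
    treatment: str = "humid",
) -> TskTrace:
    """Render a quantized ``T_sk`` trace from a bat's true event timeline.

    Torpid samples sit at ``ambient + torpid_tsk_offset`` with small
    uniform jitter.  Each arousal rewarms toward the normothermic plateau
    as ``T(t) = P − ΔT·exp(−r·t/ΔT)`` (initial slope = ``rewarm_rate``),
    holds with ±``plateau_jitter`` noise, and decays back after the arousal
    ends at an initial slope of ``cool_rate``.  Samples land every
    ``sample_interval`` minutes and are quantized to ``quantization_step``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    span = config.span_min
    _check_tiling(bat_truth, span)
    dt = config.sample_interval
    times = np.arange(0.0, span, dt)
    t0 = config.ambient_temp + config.torpid_tsk_offset
    plateau = config.normothermic_tsk_mean
    delta = plateau - t0
    k_r = config.rewarm_rate / delta
    k_c = config.cool_rate / delta
    temp = np.full(times.shape, t0)
    for ev in bat_truth:
        if ev["kind"] != "arousal":
            continue
        s, e = ev["start_min"], ev["end_min"]
        in_ar = (times >= s) & (times < e)
        temp[in_ar] = plateau - delta * np.exp(-k_r * (times[in_ar] - s))
        t_end = plateau - delta * np.exp(-k_r * (e - s))
        cool_span = np.log((t_end - t0) / 0.05) / k_c if t_end > t0 + 0.05 else 0.0
        in_cool = (times >= e) & (times < e + cool_span)
        temp[in_cool] = np.maximum(
            temp[in_cool], t0 + (t_end - t0) * np.exp(-k_c * (times[in_cool] - e))
        )
    on_plateau = temp >= plateau - 0.25
    torpid = temp <= t0 + 0.25
    temp = temp + on_plateau * rng.uniform(
        -config.plateau_jitter, config.plateau_jitter, times.size
    )
    temp = temp + torpid * rng.uniform(
        -config.torpid_jitter, config.torpid_jitter, times.size
    )
    q = config.quantization_step
    temp = np.round(temp / q) * q
    return TskTrace(bat_id=bat_id, treatment=treatment, times=times, tsk=temp)


def _fragment_arousal(
    rng: np.random.Generator, s: float, e: float, merge_gap: float
) -> list[tuple[float, float]]:
    """Split one arousal into movement intervals with stillness gaps that
    stay below the merge window, so the behavioural detector reconstructs
    [s, e) exactly."""
    dur = e - s
    n_frag = 1 if dur < 100 else int(rng.integers(1, 4))
    if n_frag == 1:
        return [(s, e)]
    part = dur / n_frag
    out = []
    for i in range(n_frag):
        lo = s + i * part
        hi = s + (i + 1) * part
        if i < n_frag - 1:
            gap = min(float(rng.uniform(5.0, 40.0)), part / 2, 0.8 * merge_gap)
            hi -= gap
        out.append((lo, hi))
    return out


def _place_bump(
    rng: np.random.Generator,
    trace: TskTrace,
    busy: np.ndarray,
    margin_samples: int,
) -> tuple[int, int] | None:
    """Pick a window of torpid samples for an artifact bump; None if no room."""
    n = trace.times.size
    k = int(rng.integers(2, 5))  # samples at peak
    need = k + 2  # plus one shoulder each side
    if n - need - margin_samples <= margin_samples:
        return None
    for _ in range(20):
        i0 = int(rng.integers(margin_samples, n - need - margin_samples))
        window = slice(i0 - margin_samples, i0 + need + margin_samples)
        if busy[window].any() or not trace.valid[window].all():
            continue
        return i0, k
    return None


def inject_artifacts(
    trace: TskTrace,
    log: MovementLog,
    config: SimulationConfig,
    seed: "int | np.random.Generator",
) -> tuple[TskTrace, MovementLog, list[dict]]:
    """Inject logger artifacts into one animal's trace and movement log.

    Heating and shallow thermal events alter the trace only; sub-threshold
    movement events alter both.  Bumps are only placed in stretches where
    the animal is motionless (180 min clear of any movement interval) and
    the logger is valid; an artifact that cannot be placed without touching
    an arousal is skipped and recorded with ``"skipped": True``.  Logger
    shedding truncates the validity mask from a uniformly drawn day; a
    logger failure invalidates the whole trace.
    """
    if trace.bat_id != log.bat_id:
        raise ValueError("trace and log must describe the same animal")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = config.artifact_rates
    dt = trace.cadence
    tsk = trace.tsk.copy()
    valid = trace.valid.copy()
    intervals = list(log.intervals)
    artifacts: list[dict] = []
    t0 = config.ambient_temp + config.torpid_tsk_offset
    qstep = config.quantization_step

    margin = int(np.ceil(180.0 / dt))
    busy = np.zeros(trace.times.size, dtype=bool)
    for s, e in intervals:
        busy[(trace.times >= s - 180.0) & (trace.times < e + 180.0)] = True

    def bump(kind: str, peak_range: tuple[float, float], with_movement: bool) -> None:
        peak = float(rng.uniform(*peak_range))
        spot = _place_bump(rng, trace, busy, margin)
        if spot is None:
            artifacts.append({"kind": kind, "bat_id": trace.bat_id, "skipped": True})
            return
        i0, k = spot
        shoulder = np.round(((t0 + peak) / 2) / qstep) * qstep
        peak_q = np.round(peak / qstep) * qstep
        tsk[i0] = shoulder
        tsk[i0 + 1 : i0 + 1 + k] = peak_q
        tsk[i0 + 1 + k] = shoulder
        busy[max(0, i0 - margin) : i0 + k + 2 + margin] = True
        t_start = float(trace.times[i0 + 1])
        rec = {
            "kind": kind,
            "bat_id": trace.bat_id,
            "time_min": t_start,
            "peak_c": float(peak_q),
            "n_samples": k,
            "skipped": False,
        }
        if with_movement:
            move = (t_start, float(trace.times[i0 + k] + dt))
            intervals.append(move)
            rec["movement"] = list(move)
        artifacts.append(rec)

    for _ in range(rng.poisson(rates.heating_per_bat)):
        bump("heating", rates.heating_peak_range, with_movement=False)
    for _ in range(rng.poisson(rates.subthreshold_per_bat)):
        bump("subthreshold_movement", rates.subthreshold_peak_range, with_movement=True)
    for _ in range(rng.poisson(rates.shallow_per_bat)):
        bump("shallow_thermal", rates.shallow_peak_range, with_movement=False)

    if rng.random() < rates.failure_prob:
        valid[:] = False
        artifacts.append({"kind": "logger_failure", "bat_id": trace.bat_id,
                          "skipped": False})
    elif rng.random() < rates.shed_prob:
        shed_day = float(rng.uniform(0.25 * config.study_days, config.study_days))
        valid[trace.times >= shed_day * 1440.0] = False
        artifacts.append({"kind": "shed_logger", "bat_id": trace.bat_id,
                          "day": shed_day, "skipped": False})

    new_trace = TskTrace(
        bat_id=trace.bat_id, treatment=trace.treatment,
        times=trace.times.copy(), tsk=tsk, valid=valid,
    )
    new_log = MovementLog(
        bat_id=log.bat_id, intervals=sorted(intervals),
        observation_span=log.observation_span, treatment=log.treatment,
    )
    return new_trace, new_log, artifacts


def _ellipse_mask(
    rng: np.random.Generator, shape: tuple[int, int], n_pixels: int
) -> np.ndarray:
    """Binary mask whose foreground is an elliptical region of exactly
    ``n_pixels`` pixels (the n smallest values of the ellipse quadratic, so
    the region is a convex, 4-connected discretized ellipse)."""
    h, w = shape
    if n_pixels < 1 or n_pixels >= h * w:
        raise ValueError("requested region size out of range")
    ratio = float(rng.uniform(0.5, 0.9))
    a = np.sqrt(n_pixels / (np.pi * ratio))
    b = a * ratio
    theta = float(rng.uniform(0.0, np.pi))
    r_max = a + 2
    cy = float(rng.uniform(min(r_max, h / 2), max(h - r_max, h / 2)))
    cx = float(rng.uniform(min(r_max, w / 2), max(w - r_max, w / 2)))
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    d = (u / a) ** 2 + (v / b) ** 2
    idx = np.argpartition(d.ravel(), n_pixels)[:n_pixels]
    mask = np.zeros(h * w, dtype=bool)
    mask[idx] = True
    return mask.reshape(h, w)


def simulate_huddle_masks(
    config: SimulationConfig, seed: "int | np.random.Generator"
) -> tuple[list[HuddleMask], dict[str, float]]:
    """Binary huddle masks per treatment with area fractions drawn about the
    treatment HSI mean.  Returns the masks and the true area fraction (in
    percent) of each, keyed by image id."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = config.mask_shape
    total = h * w
    masks: list[HuddleMask] = []
    truth: dict[str, float] = {}
    for tr in TREATMENTS:
        for i in range(config.n_photos[tr]):
            frac = float(
                np.clip(rng.normal(config.hsi_mean[tr], config.hsi_sd[tr]), 0.2, 50.0)
            )
            n_pix = max(1, int(round(frac / 100.0 * total)))
            pixels = _ellipse_mask(rng, (h, w), n_pix)
            image_id = f"{tr}_photo_{i:02d}"
            masks.append(
                HuddleMask(
                    image_id=image_id,
                    treatment=tr,
                    pixels=pixels,
                    capture_time_day=float(rng.uniform(0, config.study_days)),
                )
            )
            truth[image_id] = 100.0 * n_pix / total
    return masks, truth


def _cascade_template(
    config: SimulationConfig, treatment: str, rng: np.random.Generator
) -> list[float]:
    """Shared arousal onset times for a treatment group (cascade mode)."""
    span = config.span_min
    tor_mean = config.torpor_mean_days[treatment] * 1440.0
    onsets, t = [], 0.0
    while True:
        t += max(rng.gamma(config.torpor_shape, tor_mean / config.torpor_shape),
                 config.min_torpor_min)
        if t >= span - 24 * 60:
            return onsets
        onsets.append(t)
        t += config.arousal_mean_min[treatment]


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate one full cohort: traces, logs, drinks, masks, masses, truth.

    Identical configs (including the seed) produce bit-identical bundles.
    """
    span = config.span_min
    traces, logs, drinks, records = [], [], [], []
    truth_events: dict[str, list[dict]] = {}
    truth_drinks: dict[str, list[int]] = {}
    all_artifacts: list[dict] = []
    for ti, tr in enumerate(TREATMENTS):
        cascade = (
            _cascade_template(config, tr, _rng_for(config, 2, ti))
            if config.cascade_strength > 0
            else None
        )
        for bi in range(config.bats_by_treatment()[tr]):
            rng = _rng_for(config, 0, ti, bi)
            bat_id = f"{tr[0]}{bi + 1:02d}"
            events = _simulate_timeline(rng, config, tr)
            if cascade is not None:
                events = _apply_cascade(events, cascade, config, rng)
            truth_events[bat_id] = events

            intervals: list[tuple[float, float]] = []
            for ev in events:
                if ev["kind"] == "arousal":
                    intervals.extend(
                        _fragment_arousal(
                            rng, ev["start_min"], ev["end_min"], config.merge_gap_min
                        )
                    )
            log = MovementLog(
                bat_id=bat_id, intervals=sorted(intervals),
                observation_span=(0.0, span), treatment=tr,
            )

            arousals = [e for e in events if e["kind"] == "arousal"]
            drink_idx: list[int] = []
            n_drinks = 0
            for ai, ev in enumerate(arousals):
                if rng.random() < config.p_drink_given_arousal[tr]:
                    drink_idx.append(ai)
                    n_vis = 1 + int(rng.poisson(config.drink_extra_visits[tr]))
                    lo = ev["start_min"] + 2.0
                    hi = max(ev["end_min"] - 2.0, lo + 1.0)
                    for tmin in np.sort(rng.uniform(lo, hi, n_vis)):
                        drinks.append(DrinkEvent(bat_id=bat_id, time_min=float(tmin)))
                    n_drinks += n_vis
            truth_drinks[bat_id] = drink_idx

            trace = simulate_tsk_trace(events, config, rng, bat_id=bat_id, treatment=tr)
            trace, log, artifacts = inject_artifacts(trace, log, config, rng)
            all_artifacts.extend(artifacts)
            traces.append(trace)
            logs.append(log)

            m_lo, m_hi = config.initial_mass_range
            m0 = float(rng.uniform(m_lo, m_hi))
            loss = config.massloss_at_min_mass + config.massloss_slope_on_initial_mass * (
                m0 - m_lo
            ) + float(rng.normal(0.0, config.massloss_noise_sd))
            loss = max(loss, 0.5)
            records.append(
                BatRecord(
                    bat_id=bat_id, treatment=tr,
                    initial_mass=round(m0, 1), final_mass=round(m0 - loss, 1),
                    n_arousals=len(arousals), n_drinks=n_drinks,
                    n_arousals_with_drink=len(drink_idx),
                    n_arousals_without_drink=len(arousals) - len(drink_idx),
                )
            )

    masks, mask_truth = simulate_huddle_masks(config, _rng_for(config, 1))
    truth = {
        "events": truth_events,
        "drink_arousal_index": truth_drinks,
        "mask_fraction": mask_truth,
        "artifacts": all_artifacts,
    }
    return CohortBundle(
        config=config, traces=traces, movement_logs=logs, drink_events=drinks,
        huddle_masks=masks, bat_records=records, truth=truth,
        artifacts=all_artifacts,
    )


def _apply_cascade(
    events: list[dict],
    template: list[float],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """Pull arousal onsets toward shared group onset times (arousal cascades).

    Each arousal onset snaps, with probability ``cascade_strength``, to the
    nearest template onset plus Gaussian jitter, provided the move keeps the
    timeline strictly ordered; durations are preserved and the flanking
    torpor bouts absorb the shift.
    """
    out = [dict(e) for e in events]
    tmpl = np.asarray(template)
    if tmpl.size == 0:
        return out
    for i, ev in enumerate(out):
        if ev["kind"] != "arousal" or rng.random() >= config.cascade_strength:
            continue
        onset = ev["start_min"]
        target = float(tmpl[np.argmin(np.abs(tmpl - onset))]) + float(
            rng.normal(0.0, config.cascade_jitter_min)
        )
        dur = ev["end_min"] - ev["start_min"]
        prev_ev, next_ev = out[i - 1], out[i + 1]
        lo = prev_ev["start_min"] + config.min_torpor_min
        hi = next_ev["end_min"] - config.min_torpor_min - dur
        if lo >= hi:
            continue
        target = float(np.clip(target, lo, hi))
        ev["start_min"], ev["end_min"] = target, target + dur
        prev_ev["end_min"] = target
        next_ev["start_min"] = target + dur
    return out
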