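"""Tests of the synthetic cohort generator and its ground-truth contracts."""

import numpy as np
import pytest
import scipy.ndimage

from torporlab import (
    ArtifactRates,
    SimulationConfig,
    compute_hsi,
    detect_bouts_behaviour,
    detect_bouts_tsk,
    inject_artifacts,
    simulate_cohort,
    simulate_huddle_masks,
    simulate_tsk_trace,
)


def torpid_level(cfg):
    return cfg.ambient_temp + cfg.torpid_tsk_offset


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_bats_per_treatment": 0},
            {"study_days": -1},
            {"quantization_step": 0},
            {"sample_interval": 7.0},  # does not divide the span
            {"torpor_mean_days": {"humid": 8.3, "dry": -1}},
            {"p_drink_given_arousal": {"humid": 1.5, "dry": 0.5}},
            {"hsi_mean": {"humid": 120.0, "dry": 1.8}},
            {"hsi_mean": {"wet": 2.0, "dry": 1.8}},  # wrong treatment labels
            {"rewarm_rate": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestCohort:
    def test_fixed_seed_reproducibility(self, clean_config):
        a = simulate_cohort(clean_config)
        b = simulate_cohort(clean_config)
        for ta, tb in zip(a.traces, b.traces):
            assert np.array_equal(ta.tsk, tb.tsk)
            assert np.array_equal(ta.valid, tb.valid)
        assert a.truth == b.truth
        assert [m.intervals for m in a.movement_logs] == [
            m.intervals for m in b.movement_logs
        ]
        for ma, mb in zip(a.huddle_masks, b.huddle_masks):
            assert np.array_equal(ma.pixels, mb.pixels)

    def test_truth_tiles_span_without_overlap(self, clean_cohort, clean_config):
        span = clean_config.span_min
        for events in clean_cohort.truth["events"].values():
            assert events[0]["start_min"] == 0.0
            assert events[-1]["end_min"] == span
            for a, b in zip(events[:-1], events[1:]):
                assert a["end_min"] == b["start_min"]
                assert a["kind"] != b["kind"]

    def test_quantization_contract(self, clean_cohort, clean_config):
        q = clean_config.quantization_step
        for tr in clean_cohort.traces:
            ratio = tr.tsk[tr.valid] / q
            assert np.allclose(ratio, np.round(ratio))

    def test_arousal_count_matches_renewal_expectation(self):
        """Cohort-mean arousal counts track study_days / (torpor + arousal mean)."""
        cfg = SimulationConfig(
            seed=7, n_bats_per_treatment=10, artifact_rates=ArtifactRates.none()
        )
        bundle = simulate_cohort(cfg)
        for tr in ("humid", "dry"):
            counts = np.array(
                [
                    sum(e["kind"] == "arousal" for e in bundle.truth["events"][b.bat_id])
                    for b in bundle.bat_records
                    if b.treatment == tr
                ]
            )
            expected = cfg.study_days / (
                cfg.torpor_mean_days[tr] + cfg.arousal_mean_min[tr] / 1440.0
            )
            se = counts.std(ddof=1) / np.sqrt(counts.size)
            assert abs(counts.mean() - expected) < 3 * max(se, 1.0)

    def test_event_rate_limit_forces_censored_torpor(self):
        cfg = SimulationConfig(
            seed=1,
            n_bats_per_treatment=3,
            study_days=20.0,
            torpor_mean_days={"humid": 200.0, "dry": 200.0},
            artifact_rates=ArtifactRates.none(),
        )
        bundle = simulate_cohort(cfg)
        n_zero = 0
        for events in bundle.truth["events"].values():
            arousals = [e for e in events if e["kind"] == "arousal"]
            if not arousals:
                n_zero += 1
                assert len(events) == 1
                assert events[0]["kind"] == "torpor"
                assert events[0]["right_censored"]
        assert n_zero >= 1


class TestTraceRendering:
    def test_pure_torpor_trace_sits_at_torpid_level(self, clean_config):
        cfg = clean_config
        span = cfg.span_min
        events = [
            {"kind": "torpor", "start_min": 0.0, "end_min": span,
             "left_censored": True, "right_censored": True}
        ]
        tr = simulate_tsk_trace(events, cfg, seed=3)
        assert np.all(np.abs(tr.tsk - torpid_level(cfg)) <= cfg.quantization_step)

    def test_ramp_crossing_matches_closed_form(self, clean_config):
        """Detector duration at 20 °C ≈ truth + t_down − t_up from the rates."""
        cfg = clean_config
        span = cfg.span_min
        s, dur = 2880.0, 134.0
        events = [
            {"kind": "torpor", "start_min": 0.0, "end_min": s,
             "left_censored": True, "right_censored": False},
            {"kind": "arousal", "start_min": s, "end_min": s + dur,
             "left_censored": False, "right_censored": False},
            {"kind": "torpor", "start_min": s + dur, "end_min": span,
             "left_censored": False, "right_censored": True},
        ]
        tr = simulate_tsk_trace(events, cfg, seed=5)
        arousals = [b for b in detect_bouts_tsk(tr, 20.0) if b.kind == "arousal"]
        assert len(arousals) == 1
        t0 = torpid_level(cfg)
        delta = cfg.normothermic_tsk_mean - t0
        # exponential-approach crossing times, computed by hand from the rates
        t_up = (delta / cfg.rewarm_rate) * np.log(delta / (delta - (20.0 - t0)))
        t_end = cfg.normothermic_tsk_mean - delta * np.exp(
            -cfg.rewarm_rate / delta * dur
        )
        t_down = (delta / cfg.cool_rate) * np.log((t_end - t0) / (20.0 - t0))
        expected = dur - t_up + t_down
        assert abs(arousals[0].duration_min - expected) <= 2 * cfg.sample_interval

    def test_non_tiling_events_rejected(self, clean_config):
        events = [
            {"kind": "torpor", "start_min": 0.0, "end_min": 100.0,
             "left_censored": True, "right_censored": False}
        ]
        with pytest.raises(ValueError, match="tile"):
            simulate_tsk_trace(events, clean_config, seed=1)

    def test_clean_calibration_recovery(self, clean_cohort):
        """Zero artifacts: the 20 °C detector recovers truth counts exactly
        and mean durations within 2 sample intervals."""
        errs = []
        for tr in clean_cohort.traces:
            truth = [
                e
                for e in clean_cohort.truth["events"][tr.bat_id]
                if e["kind"] == "arousal"
            ]
            det = [b for b in detect_bouts_tsk(tr, 20.0) if b.kind == "arousal"]
            assert len(det) == len(truth)
            errs.extend(
                d.duration_min - (e["end_min"] - e["start_min"])
                for e, d in zip(truth, det)
            )
        assert abs(np.mean(errs)) <= 2 * 15.0


class TestArtifacts:
    def test_zero_rates_identity(self, clean_cohort, clean_config):
        tr, log = clean_cohort.traces[0], clean_cohort.movement_logs[0]
        tr2, log2, arts = inject_artifacts(tr, log, clean_config, seed=9)
        assert arts == []
        assert np.array_equal(tr.tsk, tr2.tsk)
        assert np.array_equal(tr.valid, tr2.valid)
        assert log.intervals == log2.intervals

    def test_count_difference_bookkeeping(self, clean_config):
        """k heating − m sub-threshold artifacts shift the detector-count
        difference by exactly k − m per trace."""
        from dataclasses import replace

        cfg = replace(
            clean_config,
            artifact_rates=ArtifactRates(
                heating_per_bat=2.0, subthreshold_per_bat=2.0, shallow_per_bat=2.0,
                shed_prob=0.0, failure_prob=0.0,
            ),
        )
        base = simulate_cohort(clean_config)
        for tr, log in zip(base.traces, base.movement_logs):
            tr2, log2, arts = inject_artifacts(tr, log, cfg, seed=17)
            k = sum(a["kind"] == "heating" and not a["skipped"] for a in arts)
            m = sum(
                a["kind"] == "subthreshold_movement" and not a["skipped"]
                for a in arts
            )
            n_tsk = sum(b.kind == "arousal" for b in detect_bouts_tsk(tr2, 20.0))
            n_beh = sum(
                b.kind == "arousal" for b in detect_bouts_behaviour(log2)
            )
            n_truth = sum(b.kind == "arousal" for b in detect_bouts_tsk(tr, 20.0))
            assert n_tsk - n_truth == k
            assert n_beh - n_truth == m
            assert n_tsk - n_beh == k - m

    def test_heating_peak_bounded(self, clean_config):
        from dataclasses import replace

        cfg = replace(
            clean_config, artifact_rates=ArtifactRates(heating_per_bat=3.0)
        )
        base = simulate_cohort(clean_config)
        tr2, _, arts = inject_artifacts(
            base.traces[0], base.movement_logs[0], cfg, seed=23
        )
        placed = [a for a in arts if a["kind"] == "heating" and not a["skipped"]]
        assert placed
        for a in placed:
            assert 20.0 < a["peak_c"] <= 23.2

    def test_shed_logger_truncates_validity(self, clean_config):
        from dataclasses import replace

        cfg = replace(
            clean_config,
            artifact_rates=ArtifactRates(shed_prob=1.0, failure_prob=0.0),
        )
        base = simulate_cohort(clean_config)
        tr2, _, arts = inject_artifacts(
            base.traces[0], base.movement_logs[0], cfg, seed=31
        )
        shed = [a for a in arts if a["kind"] == "shed_logger"]
        assert len(shed) == 1
        cut = shed[0]["day"] * 1440.0
        assert not tr2.valid[tr2.times >= cut].any()
        assert tr2.valid[tr2.times < cut].all()


FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


class TestHuddleMasks:
    def test_mask_contracts(self, clean_config):
        masks, truth = simulate_huddle_masks(clean_config, seed=2)
        n_photos = sum(clean_config.n_photos.values())
        assert len(masks) == n_photos
        for m in masks:
            assert m.pixels.shape == clean_config.mask_shape
            _, n_comp = scipy.ndimage.label(m.pixels, structure=FOUR_CONN)
            assert n_comp == 1
            # truth fraction equals the exact pixel fraction
            assert compute_hsi(m).hsi == pytest.approx(
                truth[m.image_id], abs=0
            )

    def test_mask_mean_matches_configured_mean(self):
        """Monte-Carlo: mean of true fractions within 3 s.e. of the target."""
        cfg = SimulationConfig(
            seed=3,
            n_photos={"humid": 400, "dry": 2},
        )
        _, truth = simulate_huddle_masks(cfg, seed=4)
        fracs = np.array(
            [v for k, v in truth.items() if k.startswith("humid")]
        )
        se = fracs.std(ddof=1) / np.sqrt(fracs.size)
        assert abs(fracs.mean() - cfg.hsi_mean["humid"]) < 3 * se

    def test_zero_fraction_rejected(self):
        from torporlab.synthetic import _ellipse_mask

        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            _ellipse_mask(rng, (10, 10), 0)
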