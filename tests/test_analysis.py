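"""Per-impulse SHIMP analysis: detection passes, ESTP, classification, QC."""

import dataclasses

import numpy as np
import pytest

from conftest import make_peak
from shimpkit import (
    AnalysisConfig,
    Channel,
    ImpulseRecord,
    InvalidTraceError,
    SimulationSpec,
    Side,
    VelocityTrace,
    analyze_impulse,
    classify_early,
    compute_estp,
    compute_latency,
    detect_head_peak,
    detect_shimp_saccade,
    detect_vor_peak,
    normalize_direction,
    simulate_impulse,
)
from shimpkit.analysis import (
    QC_HEAD_BELOW_MIN,
    QC_IRREGULAR,
    QC_NO_HEAD_PEAK,
    QC_NO_SACCADE,
)


def record_from(head, eye, rate_hz=250.0, impulse_id="t"):
    return ImpulseRecord(
        impulse_id=impulse_id,
        head=VelocityTrace(head, rate_hz, Channel.HEAD),
        eye=VelocityTrace(eye, rate_hz, Channel.EYE),
    )


class TestNormalizeDirection:
    def test_negative_impulse_is_flipped(self):
        rec = record_from([0, -200, 0], [0, -180, 0])
        out, sign = normalize_direction(rec)
        assert sign == -1
        assert out.head.samples[1] == 200 and out.eye.samples[1] == 180

    def test_positive_impulse_unchanged(self):
        rec = record_from([0, 200, 0], [0, 180, 0])
        out, sign = normalize_direction(rec)
        assert sign == 1 and out is rec

    def test_idempotent(self):
        rec = record_from([0, -200, 0], [0, -180, 0])
        once, _ = normalize_direction(rec)
        twice, sign = normalize_direction(once)
        assert sign == 1
        np.testing.assert_array_equal(once.head.samples, twice.head.samples)

    def test_zero_head_rejected(self):
        with pytest.raises(InvalidTraceError):
            normalize_direction(record_from([0, 0, 0], [0, 1, 0]))


class TestDetectionPasses:
    def test_head_peak_recovered_from_simulation(self):
        spec = SimulationSpec(noise_sd=0.0, head_peak_time=40, n_samples=200)
        rec, _ = simulate_impulse(spec)
        peak = detect_head_peak(rec.head)
        assert peak.index == 40
        assert peak.prominence == pytest.approx(200.0, abs=0.5)

    def test_low_head_lobe_not_detected(self):
        spec = SimulationSpec(noise_sd=0.0, head_peak_velocity=90.0,
                              saccade_amplitude=0.0)
        rec, _ = simulate_impulse(spec)
        assert detect_head_peak(rec.head) is None

    def test_overshoot_does_not_move_head_apex_or_width(self):
        base = SimulationSpec(noise_sd=0.0)
        with_o = dataclasses.replace(base, overshoot_amplitude=80.0)
        p0 = detect_head_peak(simulate_impulse(base)[0].head)
        p1 = detect_head_peak(simulate_impulse(with_o)[0].head)
        assert p0.index == p1.index
        assert p0.width == pytest.approx(p1.width, abs=1e-6)

    def test_vor_peak_scales_with_gain(self):
        rec, _ = simulate_impulse(SimulationSpec(noise_sd=0.0, vor_gain=0.9,
                                                 saccade_latency_ms=400.0,
                                                 n_samples=300))
        peak = detect_vor_peak(rec.eye)
        assert peak is not None
        assert peak.prominence == pytest.approx(180.0, rel=0.02)

    def test_low_gain_vor_absent(self):
        # the vestibular-loss pattern: slow-phase response below threshold
        rec, _ = simulate_impulse(SimulationSpec(noise_sd=0.0, vor_gain=0.3,
                                                 saccade_amplitude=0.0))
        assert detect_vor_peak(rec.eye) is None

    def test_zero_eye_absent(self):
        rec = record_from([0, 200, 0], [0, 0, 0.0])
        assert detect_vor_peak(rec.eye) is None
        assert detect_shimp_saccade(rec.eye) is None

    def test_saccade_recovered_at_injected_position(self):
        spec = SimulationSpec(noise_sd=0.0, saccade_latency_ms=160.0)
        rec, gt = simulate_impulse(spec)
        peak = detect_shimp_saccade(rec.eye)
        assert abs(peak.index - gt.true_saccade_apex) <= 1

    def test_small_saccade_not_detected(self):
        rec, _ = simulate_impulse(
            SimulationSpec(noise_sd=0.0, saccade_amplitude=50.0, vor_gain=0.0)
        )
        assert detect_shimp_saccade(rec.eye) is None

    def test_dual_pass_symmetry(self):
        rec, _ = simulate_impulse(SimulationSpec(noise_sd=0.0))
        assert detect_shimp_saccade(rec.eye) == detect_vor_peak(rec.eye.negated())


class TestEstpAndClassification:
    def test_estp_arithmetic(self):
        estp = compute_estp(make_peak(index=40, width=20.0),
                            make_peak(index=60, width=8.0))
        assert estp == 40 + 1.5 * 20 + 8 == 78.0

    def test_estp_zero_head_width_limit(self):
        estp = compute_estp(make_peak(index=40, width=0.0),
                            make_peak(index=60, width=8.0))
        assert estp == 48.0

    def test_estp_linearity_in_head_width(self):
        base = compute_estp(make_peak(width=20.0), make_peak(width=8.0))
        doubled = compute_estp(make_peak(width=40.0), make_peak(width=8.0))
        assert doubled - base == pytest.approx(1.5 * 20.0)

    def test_strictly_before_estp_is_early(self):
        assert classify_early(make_peak(index=70), 78.0) is True

    def test_tie_is_not_early(self):
        assert classify_early(make_peak(index=78), 78.0) is False

    def test_left_crossing_reference_mode(self):
        cfg = AnalysisConfig(early_time_reference="left_crossing")
        peak = make_peak(index=80, width=20.0)  # left crossing at 70
        assert classify_early(peak, 78.0, cfg) is True
        assert classify_early(peak, 78.0) is False

    def test_later_saccade_never_becomes_early(self):
        estp = 78.0
        flags = [classify_early(make_peak(index=i), estp) for i in range(60, 100)]
        assert flags == sorted(flags, reverse=True)


class TestLatency:
    def test_peak_referenced_latency(self):
        head = VelocityTrace(np.zeros(100) + 1e-9, 250.0)
        lat_s, lat_ms, irregular = compute_latency(
            make_peak(index=38), make_peak(index=55), head
        )
        assert (lat_s, lat_ms, irregular) == (17, 68.0, False)

    def test_zero_latency_is_irregular(self):
        head = VelocityTrace(np.zeros(100) + 1e-9, 250.0)
        lat_s, lat_ms, irregular = compute_latency(
            make_peak(index=38), make_peak(index=38), head
        )
        assert lat_s == 0 and lat_ms == 0.0 and irregular

    def test_onset_reference_gives_longer_latency(self):
        rec, _ = simulate_impulse(SimulationSpec(noise_sd=0.0))
        head_peak = detect_head_peak(rec.head)
        sac = detect_shimp_saccade(rec.eye)
        cfg_onset = AnalysisConfig(latency_reference="head_onset")
        lat_peak, *_ = compute_latency(head_peak, sac, rec.head)
        lat_onset, *_ = compute_latency(head_peak, sac, rec.head, cfg_onset)
        assert lat_onset > lat_peak


class TestAnalyzeImpulse:
    def test_clean_impulse_full_pipeline(self):
        rec, gt = simulate_impulse(
            SimulationSpec(noise_sd=0.0, saccade_latency_ms=250.0, n_samples=300)
        )
        a = analyze_impulse(rec)
        assert a.head_peak is not None and a.vor_peak is not None
        assert a.saccade is not None and a.saccade.early == gt.true_early is False
        assert a.saccade.latency_ms == pytest.approx(250.0, abs=4.0)
        assert a.qc == set()

    def test_early_saccade_case(self):
        rec, gt = simulate_impulse(SimulationSpec(noise_sd=0.0,
                                                  saccade_latency_ms=50.0))
        a = analyze_impulse(rec)
        assert gt.true_early and a.saccade.early

    def test_flat_eye_has_no_saccade(self):
        rec = record_from([0, 0, 200, 0, 0], [0, 0, 0, 0, 0.0])
        a = analyze_impulse(rec)
        assert a.saccade is None and QC_NO_SACCADE in a.qc

    def test_direction_symmetry(self):
        rec, _ = simulate_impulse(SimulationSpec(noise_sd=0.0), side=Side.RIGHT)
        flipped = record_from(-rec.head.samples, -rec.eye.samples)
        a, b = analyze_impulse(rec), analyze_impulse(flipped)
        assert a.head_peak == b.head_peak
        assert a.saccade == b.saccade
        assert (a.sign, b.sign) == (1, -1)

    def test_exactly_one_saccade(self):
        # two saccade-like lobes: only the first passing one is reported
        t = np.arange(250.0)
        head = 200 * np.exp(-((t - 50) ** 2) / 200)
        eye = (0.9 * head
               - 250 * np.exp(-((t - 90) ** 2) / 20)
               - 250 * np.exp(-((t - 150) ** 2) / 20))
        a = analyze_impulse(record_from(head, eye))
        assert a.saccade is not None and a.saccade.peak.index < 120


class TestQC:
    def test_low_head_velocity_flagged(self):
        a = analyze_impulse(record_from([0, 119.9, 0], [0, 0, 0.0]))
        assert QC_HEAD_BELOW_MIN in a.qc

    def test_boundary_velocity_passes(self):
        a = analyze_impulse(record_from([0, 120.0, 0], [0, 0, 0.0]))
        assert QC_HEAD_BELOW_MIN not in a.qc

    def test_absent_head_peak_takes_precedence(self):
        a = analyze_impulse(record_from([0, 50.0, 0], [0, 0, 0.0]))
        assert QC_NO_HEAD_PEAK in a.qc and QC_HEAD_BELOW_MIN not in a.qc

    def test_saccade_before_head_peak_is_irregular(self):
        t = np.arange(250.0)
        head = 200 * np.exp(-((t - 100) ** 2) / 200)
        eye = 0.9 * head - 250 * np.exp(-((t - 60) ** 2) / 20)
        a = analyze_impulse(record_from(head, eye))
        assert a.saccade is not None and a.saccade.latency_samples <= 0
        assert QC_IRREGULAR in a.qc
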