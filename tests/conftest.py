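import numpy as np
import pytest

from shimpkit import (
    AnalysisConfig,
    ImpulseAnalysis,
    PeakFeature,
    SaccadeMeasure,
    SimulationSpec,
    simulate_impulse,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture
def clean_impulse():
    """A noiseless simulated impulse and its ground truth (not-early saccade)."""
    spec = SimulationSpec(noise_sd=0.0, saccade_latency_ms=250.0)
    return simulate_impulse(spec)


def make_peak(index=40, velocity=200.0, prominence=200.0, width=20.0):
    return PeakFeature(
        index=index,
        velocity=velocity,
        prominence=prominence,
        width=width,
        left_crossing=index - width / 2,
        right_crossing=index + width / 2,
    )


def make_analysis(
    impulse_id="imp",
    head_velocity=200.0,
    latency_ms=None,
    early=False,
    width_ms=30.0,
    velocity=250.0,
    rate_hz=250.0,
):
    """Assemble a minimal ImpulseAnalysis for summary-level tests."""
    head = make_peak(velocity=head_velocity, prominence=head_velocity)
    saccade = None
    if latency_ms is not None:
        latency_samples = int(round(latency_ms * rate_hz / 1000.0))
        sac_peak = make_peak(
            index=head.index + latency_samples,
            velocity=velocity,
            prominence=velocity,
            width=width_ms * rate_hz / 1000.0,
        )
        saccade = SaccadeMeasure(
            peak=sac_peak,
            latency_samples=latency_samples,
            latency_ms=latency_samples * 1000.0 / rate_hz,
            width_ms=width_ms,
            velocity=velocity,
            estp_samples=100.0,
            early=early,
        )
    return ImpulseAnalysis(
        record_ref=impulse_id,
        head_peak=head,
        saccade=saccade,
        rate_hz=rate_hz,
    )


def random_trace(rng, max_len=50, lo=-200, hi=200):
    n = int(rng.integers(3, max_len + 1))
    return rng.integers(lo, hi + 1, size=n).astype(float)
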