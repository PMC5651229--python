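"""Ground-truth simulator of SHIMP head-impulse / eye-response traces.

Every event is a Gaussian velocity lobe: real vHIT head impulses and
saccades are bell-shaped, and a Gaussian has a closed-form full width at
half maximum (FWHM = 2*sigma*sqrt(2*ln 2)) so the half-prominence widths the
analysis measures can be predicted exactly. One simulated impulse is

    head(t) = A_h * G(t; t0, s_h) - A_o * G(t; t0 + 3*s_h + d, s_o)
    eye(t)  = g * head(t) - A_s * G(t; t0 + L, s_s) + noise

with ``G`` a unit Gaussian lobe (the overshoot lobe is a truncated Gaussian
with exact zero outside +/- 3 sigma, since a real overshoot has finite
duration), ``A_o`` the optional post-impulse overshoot amplitude, ``g`` the
VOR gain, ``A_s`` the anticompensatory saccade amplitude,
``L`` the saccade latency after the head apex and ``noise`` white Gaussian
noise on the eye channel. The stored eye trace uses the device convention
(slow phase aligned with head, saccade lobe negative), so simulated records
round-trip through the readers and the analysis unchanged.

Protocol presets carry the first-saccade latency distributions measured
under three levels of impulse predictability: the more predictable the
protocol, the shorter (and thus more often "early") the saccade latency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .analysis import ImpulseRecord, Side
from .errors import SimulationError
from .peaks import Channel, VelocityTrace

__all__ = [
    "FWHM_FACTOR",
    "SimulationSpec",
    "GroundTruth",
    "ProtocolPreset",
    "PROTOCOL_PRESETS",
    "protocol_preset",
    "simulate_impulse",
    "simulate_test",
]

#: FWHM of a unit Gaussian in units of sigma.
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated SHIMP impulse.

    Defaults give a 200 deg/s head impulse with ~100 ms FWHM at 250 Hz
    (within the method's QC bounds and typical vHIT morphology), VOR gain
    0.9, and a 250 deg/s saccade lobe of ~30 ms FWHM.
    """

    rate_hz: float = 250.0
    n_samples: int = 250
    head_peak_velocity: float = 200.0
    head_sigma: float = 25.0 / FWHM_FACTOR  # ~100 ms FWHM at 250 Hz
    head_peak_time: int = 50
    overshoot_amplitude: float = 0.0
    overshoot_delay: float = 5.0
    overshoot_sigma: Optional[float] = None  # defaults to head_sigma / 2
    vor_gain: float = 0.9
    saccade_amplitude: float = 250.0
    saccade_latency_ms: float = 150.0
    saccade_sigma: float = 7.5 / FWHM_FACTOR  # ~30 ms FWHM at 250 Hz
    noise_sd: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.head_peak_velocity > 0):
            raise SimulationError("head_peak_velocity must be positive")
        if not (self.head_sigma > 0 and self.saccade_sigma > 0):
            raise SimulationError("head_sigma and saccade_sigma must be positive")
        if self.noise_sd < 0 or self.overshoot_amplitude < 0:
            raise SimulationError("noise_sd and overshoot_amplitude must be >= 0")
        if not (0 <= self.vor_gain <= 1.2):
            raise SimulationError("vor_gain must be in [0, 1.2]")
        if self.n_samples < 3:
            raise SimulationError("n_samples must be >= 3")

    @property
    def saccade_latency_samples(self) -> float:
        return self.saccade_latency_ms * self.rate_hz / 1000.0

    @property
    def saccade_apex_sample(self) -> float:
        return self.head_peak_time + self.saccade_latency_samples


@dataclass(frozen=True)
class GroundTruth:
    """True event positions/widths of a simulated impulse, plus the true
    early classification obtained by applying the ESTP rule to them."""

    true_head_apex: int
    true_head_width: float
    true_saccade_apex: int
    true_saccade_width: float
    true_latency_ms: float
    true_estp: float
    true_early: bool


@dataclass(frozen=True)
class ProtocolPreset:
    """First-saccade latency distribution for one predictability protocol."""

    name: str
    latency_mean_ms: float
    latency_sd_ms: float
    min_latency_ms: float = 20.0


PROTOCOL_PRESETS: dict[str, ProtocolPreset] = {
    "predictable": ProtocolPreset("predictable", 112.8, 56.96),
    "less_predictable": ProtocolPreset("less_predictable", 152.04, 58.00),
    "unpredictable": ProtocolPreset("unpredictable", 178.32, 46.04),
}


def protocol_preset(name: str) -> ProtocolPreset:
    """Latency-distribution preset by protocol name."""
    try:
        return PROTOCOL_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {sorted(PROTOCOL_PRESETS)}"
        ) from None


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-((t - center) ** 2) / (2.0 * sigma**2))


def _compact_gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    # Truncated-Gaussian lobe with exact zero outside +/- 3 sigma: a real
    # overshoot has finite duration, and the exact compact support lets the
    # width-based measurements be provably untouched by a post-lobe overshoot.
    edge = math.exp(-4.5)
    return np.maximum(_gauss(t, center, sigma) - edge, 0.0) / (1.0 - edge)


def _ground_truth(spec: SimulationSpec) -> GroundTruth:
    head_width = FWHM_FACTOR * spec.head_sigma
    sac_width = FWHM_FACTOR * spec.saccade_sigma
    sac_apex = int(round(spec.saccade_apex_sample))
    estp = spec.head_peak_time + 1.5 * head_width + sac_width
    return GroundTruth(
        true_head_apex=spec.head_peak_time,
        true_head_width=head_width,
        true_saccade_apex=sac_apex,
        true_saccade_width=sac_width,
        true_latency_ms=spec.saccade_latency_ms,
        true_estp=estp,
        true_early=sac_apex < estp,
    )


def simulate_impulse(
    spec: SimulationSpec,
    rng: Optional[np.random.Generator] = None,
    impulse_id: str = "sim000",
    side: Side = Side.RIGHT,
) -> tuple[ImpulseRecord, GroundTruth]:
    """Generate one impulse record and its ground truth.

    Deterministic for a given spec and RNG state. A leftward ``side`` stores
    the traces negated (device convention); the ground truth always refers to
    the normalized, head-positive orientation.
    """
    if not (0 <= spec.head_peak_time < spec.n_samples):
        raise SimulationError("head_peak_time outside the trace")
    if spec.saccade_amplitude > 0 and not (
        0 <= spec.saccade_apex_sample <= spec.n_samples - 1
    ):
        raise SimulationError(
            f"saccade apex at sample {spec.saccade_apex_sample:.1f} lies beyond "
            f"the {spec.n_samples}-sample trace"
        )
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    t = np.arange(spec.n_samples, dtype=float)
    head = spec.head_peak_velocity * _gauss(t, spec.head_peak_time, spec.head_sigma)
    if spec.overshoot_amplitude > 0:
        o_sigma = spec.overshoot_sigma or spec.head_sigma / 2.0
        o_center = spec.head_peak_time + 3.0 * spec.head_sigma + spec.overshoot_delay
        head = head - spec.overshoot_amplitude * _compact_gauss(t, o_center, o_sigma)

    eye = spec.vor_gain * head
    if spec.saccade_amplitude > 0:
        eye = eye - spec.saccade_amplitude * _gauss(
            t, spec.saccade_apex_sample, spec.saccade_sigma
        )
    if spec.noise_sd > 0:
        eye = eye + rng.normal(0.0, spec.noise_sd, size=spec.n_samples)

    side = Side(side)
    flip = -1.0 if side == Side.LEFT else 1.0
    record = ImpulseRecord(
        impulse_id=impulse_id,
        side=side,
        head=VelocityTrace(flip * head, spec.rate_hz, Channel.HEAD),
        eye=VelocityTrace(flip * eye, spec.rate_hz, Channel.EYE),
    )
    return record, _ground_truth(spec)


def simulate_test(
    preset: ProtocolPreset | str,
    n_impulses: int,
    base_spec: Optional[SimulationSpec] = None,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> list[tuple[ImpulseRecord, GroundTruth]]:
    """Simulate a SHIMP test: ``n_impulses`` impulses with alternating sides
    and per-impulse saccade latency drawn from the preset distribution.

    Latencies are drawn Normal(mean, sd) and clipped to
    [``min_latency_ms``, trace end - 3 saccade sigma]. Deterministic under a
    fixed seed/RNG.
    """
    if isinstance(preset, str):
        preset = protocol_preset(preset)
    if n_impulses < 1:
        raise ValueError("n_impulses must be >= 1")
    spec = base_spec if base_spec is not None else SimulationSpec()
    if rng is None:
        rng = np.random.default_rng(seed)

    max_latency_ms = (
        (spec.n_samples - 1 - spec.head_peak_time) - 3.0 * spec.saccade_sigma
    ) * 1000.0 / spec.rate_hz
    out = []
    for i in range(n_impulses):
        latency = float(
            np.clip(
                rng.normal(preset.latency_mean_ms, preset.latency_sd_ms),
                preset.min_latency_ms,
                max_latency_ms,
            )
        )
        one = replace(spec, saccade_latency_ms=latency, seed=None)
        side = Side.RIGHT if i % 2 == 0 else Side.LEFT
        out.append(simulate_impulse(one, rng, impulse_id=f"imp{i:04d}", side=side))
    return out
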