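"""Per-impulse SHIMP analysis.

In the suppression head impulse paradigm (SHIMP) the participant follows a
head-fixed target, so an intact vestibulo-ocular reflex (VOR) produces a
slow-phase eye response mirroring the head impulse, followed by a large
*anticompensatory* saccade in the opposite direction. This module detects the
head-velocity peak, the VOR peak, and the saccade (on the inverted eye trace,
because peak detection only sees positive maxima), then classifies the
saccade as *early* when its apex falls inside the head-movement window.

That window is the early saccade time period (ESTP):

    ESTP = Hpt + 1.5 * Hw + Sw

with Hpt the head apex time, Hw the head half-prominence width and Sw the
saccade half-prominence width, all in samples. Being width-based, the bound
is robust to head-impulse overshoot, which corrupts zero-crossing-based
windows. A saccade is early iff its time of appearance is strictly below
ESTP.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np

from .errors import InvalidTraceError
from .peaks import PeakFeature, VelocityTrace, find_peaks

__all__ = [
    "Side",
    "ImpulseRecord",
    "SaccadeMeasure",
    "ImpulseAnalysis",
    "AnalysisConfig",
    "normalize_direction",
    "detect_head_peak",
    "detect_vor_peak",
    "detect_shimp_saccade",
    "compute_estp",
    "classify_early",
    "compute_latency",
    "analyze_impulse",
    "qc_impulse",
]

# QC flag names
QC_HEAD_BELOW_MIN = "head_below_120"
QC_NO_HEAD_PEAK = "no_head_peak"
QC_NO_SACCADE = "no_saccade"
QC_WIDTH_CLAMPED = "width_clamped"
QC_IRREGULAR = "irregular"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ImpulseRecord:
    """Paired head/eye velocity traces for one head impulse."""

    impulse_id: str
    head: VelocityTrace
    eye: VelocityTrace
    side: Side = Side.UNKNOWN

    def __post_init__(self) -> None:
        if len(self.head) != len(self.eye):
            raise InvalidTraceError(
                f"impulse {self.impulse_id!r}: head ({len(self.head)}) and eye "
                f"({len(self.eye)}) traces differ in length"
            )
        if self.head.rate_hz != self.eye.rate_hz:
            raise InvalidTraceError(
                f"impulse {self.impulse_id!r}: head and eye rate_hz differ"
            )
        object.__setattr__(self, "side", Side(self.side))


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds of the SHIMP analysis.

    Defaults are the published operating point of the method: prominence
    thresholds of 100 deg/s (head) and 80 deg/s (eye), one peak per trace,
    a 130 deg/s bound for counting low-velocity impulses, a 120 deg/s QC
    minimum for the head impulse, and an ESTP head-width factor of 1.5.
    """

    head_min_prominence: float = 100.0
    eye_min_prominence: float = 80.0
    n_peaks: int = 1
    latency_reference: str = "head_peak"  # or "head_onset"
    onset_fraction: float = 0.10
    low_velocity_threshold: float = 130.0
    qc_min_head_velocity: float = 120.0
    estp_head_width_factor: float = 1.5
    peak_selection: str = "first"  # or "max_prominence"
    early_time_reference: str = "apex"  # or "left_crossing"

    def __post_init__(self) -> None:
        for name in (
            "head_min_prominence",
            "eye_min_prominence",
            "low_velocity_threshold",
            "qc_min_head_velocity",
            "estp_head_width_factor",
        ):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if not (0 < self.onset_fraction < 1):
            raise ValueError("onset_fraction must be in (0, 1)")
        if self.latency_reference not in ("head_peak", "head_onset"):
            raise ValueError(f"unknown latency_reference {self.latency_reference!r}")
        if self.early_time_reference not in ("apex", "left_crossing"):
            raise ValueError(
                f"unknown early_time_reference {self.early_time_reference!r}"
            )


@dataclass(frozen=True)
class SaccadeMeasure:
    """The single classified SHIMP saccade of one impulse.

    ``peak`` is measured on the inverted eye trace; ``velocity`` is its
    prominence there (a positive magnitude). Classification happens in
    samples; millisecond values are derived for presentation only.
    """

    peak: PeakFeature
    latency_samples: int
    latency_ms: float
    width_ms: float
    velocity: float
    estp_samples: float
    early: bool


@dataclass
class ImpulseAnalysis:
    """Per-impulse analysis result: detected peaks, saccade measure, QC flags."""

    record_ref: str
    sign: int = 1
    head_peak: Optional[PeakFeature] = None
    vor_peak: Optional[PeakFeature] = None
    saccade: Optional[SaccadeMeasure] = None
    qc: set[str] = field(default_factory=set)
    rate_hz: float = 250.0


def normalize_direction(record: ImpulseRecord) -> tuple[ImpulseRecord, int]:
    """Orient the record so the head-impulse lobe is positive.

    Leftward and rightward impulses are analyzed identically; if the extreme
    head velocity (largest absolute value) is negative both traces are
    negated, keeping the device convention for the stored eye trace (slow
    phase aligned with head, saccade lobe negative). Returns the oriented
    record and the applied sign (+1 or -1). Idempotent.
    """
    h = record.head.samples
    extreme = h[int(np.argmax(np.abs(h)))]
    if extreme == 0:
        raise InvalidTraceError(
            f"impulse {record.impulse_id!r}: head trace is all zero"
        )
    if extreme < 0:
        return (
            replace(record, head=record.head.negated(), eye=record.eye.negated()),
            -1,
        )
    return record, 1


def detect_head_peak(
    head: VelocityTrace, cfg: AnalysisConfig = AnalysisConfig()
) -> Optional[PeakFeature]:
    """Detect the head-impulse peak (prominence >= 100 deg/s by default)."""
    peaks = find_peaks(
        head, cfg.head_min_prominence, cfg.n_peaks, selection=cfg.peak_selection
    )
    return peaks[0] if peaks else None


def detect_vor_peak(
    eye: VelocityTrace, cfg: AnalysisConfig = AnalysisConfig()
) -> Optional[PeakFeature]:
    """First eye-trace pass: the VOR slow-phase peak, in stored orientation."""
    peaks = find_peaks(
        eye, cfg.eye_min_prominence, cfg.n_peaks, selection=cfg.peak_selection
    )
    return peaks[0] if peaks else None


def detect_shimp_saccade(
    eye: VelocityTrace, cfg: AnalysisConfig = AnalysisConfig()
) -> Optional[PeakFeature]:
    """Second eye-trace pass: the anticompensatory saccade.

    The saccade opposes the slow-phase response, so detection runs on the
    negated eye trace; the returned feature's index and width refer to the
    original time axis, and its velocity/prominence are the (positive)
    magnitudes on the negated trace.
    """
    peaks = find_peaks(
        eye.negated(), cfg.eye_min_prominence, cfg.n_peaks, selection=cfg.peak_selection
    )
    return peaks[0] if peaks else None


def compute_estp(
    head_peak: PeakFeature,
    saccade_peak: PeakFeature,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> float:
    """Early saccade time period: ``Hpt + 1.5*Hw + Sw`` in samples."""
    return float(
        head_peak.index
        + cfg.estp_head_width_factor * head_peak.width
        + saccade_peak.width
    )


def classify_early(
    saccade_peak: PeakFeature,
    estp_samples: float,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> bool:
    """Early iff the saccade's time of appearance is strictly below ESTP.

    The time of appearance is the saccade apex by default (the method
    measures latency at apexes too); the left half-prominence crossing can be
    used instead via ``cfg.early_time_reference``. A tie resolves to
    not-early.
    """
    if cfg.early_time_reference == "apex":
        appearance: float = saccade_peak.index
    else:
        appearance = saccade_peak.left_crossing
    return bool(appearance < estp_samples)


def compute_latency(
    head_peak: PeakFeature,
    saccade_peak: PeakFeature,
    head: VelocityTrace,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> tuple[int, float, bool]:
    """Saccade latency relative to the head peak (default) or head onset.

    Returns ``(latency_samples, latency_ms, irregular)``. With the
    ``head_onset`` reference, onset is the latest sample before the head apex
    at or below ``onset_fraction`` of the head prominence. A saccade at or
    before the reference is flagged irregular but still reported.
    """
    if cfg.latency_reference == "head_peak":
        ref = head_peak.index
    else:
        x = head.samples
        level = cfg.onset_fraction * head_peak.prominence
        ref = 0
        for j in range(head_peak.index - 1, -1, -1):
            if x[j] <= level:
                ref = j
                break
    latency_samples = saccade_peak.index - ref
    latency_ms = latency_samples * 1000.0 / head.rate_hz
    return latency_samples, latency_ms, latency_samples <= 0


def analyze_impulse(
    record: ImpulseRecord, cfg: AnalysisConfig = AnalysisConfig()
) -> ImpulseAnalysis:
    """Full per-impulse pipeline; never raises on signal content.

    Direction normalization, head-peak detection, the dual eye-trace pass,
    then ESTP, early classification and latency — each downstream step runs
    only when its inputs were detected, and exactly zero or one saccade is
    reported per impulse. QC flags record what was missing or suspect.
    """
    oriented, sign = normalize_direction(record)
    analysis = ImpulseAnalysis(
        record_ref=record.impulse_id, sign=sign, rate_hz=record.head.rate_hz
    )
    analysis.head_peak = detect_head_peak(oriented.head, cfg)
    analysis.vor_peak = detect_vor_peak(oriented.eye, cfg)
    sac_peak = detect_shimp_saccade(oriented.eye, cfg)

    if analysis.head_peak is not None and sac_peak is not None:
        estp = compute_estp(analysis.head_peak, sac_peak, cfg)
        early = classify_early(sac_peak, estp, cfg)
        lat_samples, lat_ms, irregular = compute_latency(
            analysis.head_peak, sac_peak, oriented.head, cfg
        )
        if irregular:
            analysis.qc.add(QC_IRREGULAR)
        if sac_peak.width_clamped or analysis.head_peak.width_clamped:
            analysis.qc.add(QC_WIDTH_CLAMPED)
        analysis.saccade = SaccadeMeasure(
            peak=sac_peak,
            latency_samples=lat_samples,
            latency_ms=lat_ms,
            width_ms=sac_peak.width * 1000.0 / record.eye.rate_hz,
            velocity=sac_peak.prominence,
            estp_samples=estp,
            early=early,
        )
    return qc_impulse(analysis, cfg)


def qc_impulse(
    analysis: ImpulseAnalysis, cfg: AnalysisConfig = AnalysisConfig()
) -> ImpulseAnalysis:
    """Apply quality-control flags (flagged-but-retained; exclusion is the caller's choice).

    The head impulse must reach ``qc_min_head_velocity`` (120 deg/s, inclusive
    boundary); an absent head peak or saccade gets its own flag and the
    velocity check is not evaluated without a head peak.
    """
    if analysis.head_peak is None:
        analysis.qc.add(QC_NO_HEAD_PEAK)
    elif analysis.head_peak.velocity < cfg.qc_min_head_velocity:
        analysis.qc.add(QC_HEAD_BELOW_MIN)
    if analysis.saccade is None:
        analysis.qc.add(QC_NO_SACCADE)
    return analysis
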