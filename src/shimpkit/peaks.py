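"""Topographic peak detection on 1-D angular-velocity traces.

The analysis method this package implements rests on three primitives that
MATLAB users would recognise from ``findpeaks``: local maxima, topographic
*prominence* (peak height above the basal velocity line, not above the
x-axis), and the full *width* of the peak measured at half of its prominence.
They are implemented here from their definitions so their exact semantics —
plateau handling, interpolated crossings, end-of-trace clamping — are pinned
down and testable rather than inherited from a black box.

All positions are expressed in samples; callers convert to milliseconds at
presentation time using the trace's sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
import numpy as np

from .errors import InvalidTraceError

__all__ = [
    "Channel",
    "VelocityTrace",
    "PeakFeature",
    "find_local_maxima",
    "compute_prominence",
    "compute_width",
    "find_peaks",
]


class Channel(str, Enum):
    HEAD = "head"
    EYE = "eye"


@dataclass(frozen=True)
class VelocityTrace:
    """One channel (head or eye) of angular velocity in deg/s at a fixed rate.

    Parameters
    ----------
    samples
        Angular velocity samples, deg/s. Must contain at least 3 finite values.
    rate_hz
        Sampling frequency in Hz (vHIT devices typically record at 250 Hz).
    channel
        Which signal this trace carries, ``head`` or ``eye``.
    """

    samples: np.ndarray
    rate_hz: float = 250.0
    channel: Channel = Channel.HEAD

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size < 3:
            raise InvalidTraceError(
                f"trace needs >= 3 samples in one dimension, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidTraceError("trace contains non-finite samples")
        if not (self.rate_hz > 0):
            raise InvalidTraceError(f"rate_hz must be positive, got {self.rate_hz}")
        arr.setflags(write=False)
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "channel", Channel(self.channel))

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def ms_per_sample(self) -> float:
        return 1000.0 / self.rate_hz

    def negated(self) -> "VelocityTrace":
        return replace(self, samples=-self.samples)


@dataclass(frozen=True)
class PeakFeature:
    """A detected local maximum and its topographic measurements.

    ``index`` and ``velocity`` locate the apex; ``prominence`` is the apex
    height above the basal line; ``left_crossing``/``right_crossing`` are the
    (fractional, linearly interpolated) sample positions where the trace
    crosses the half-prominence reference height, and ``width`` their
    difference. ``width_clamped`` marks a crossing that ran off the trace end
    and was clamped there instead of failing.
    """

    index: int
    velocity: float
    prominence: float
    width: float
    left_crossing: float
    right_crossing: float
    width_clamped: bool = False


def find_local_maxima(trace: VelocityTrace) -> list[int]:
    """Return indices of strict interior local maxima, in time order.

    A flat-topped run of equal values strictly above both neighbours counts
    once, at the first sample of the run. Trace endpoints are never candidates.
    """
    x = trace.samples
    n = x.size
    out: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        if i > 0 and j < n - 1 and x[i] > x[i - 1] and x[j] > x[j + 1]:
            out.append(i)
        i = j + 1
    return out


def _prominence_at(x: np.ndarray, index: int) -> float:
    # Walk outward until a strictly higher sample or the trace end; the basal
    # line is the higher of the two interval minima.
    apex = x[index]
    left_min = apex
    for j in range(index - 1, -1, -1):
        if x[j] > apex:
            break
        if x[j] < left_min:
            left_min = x[j]
    right_min = apex
    for j in range(index + 1, x.size):
        if x[j] > apex:
            break
        if x[j] < right_min:
            right_min = x[j]
    return float(apex - max(left_min, right_min))


def compute_prominence(trace: VelocityTrace, index: int) -> float:
    """Topographic prominence of the local maximum at ``index``, in deg/s.

    The prominence is the apex value minus the basal velocity line: extend
    left and right from the apex until a strictly higher sample (or the trace
    end) is reached, take the minimum in each interval, and subtract the
    higher of the two minima. It is therefore invariant under adding a
    constant to the whole trace.
    """
    if index not in find_local_maxima(trace):
        raise ValueError(f"index {index} is not a local maximum of the trace")
    return _prominence_at(trace.samples, index)


def _width_at(
    x: np.ndarray, index: int, prominence: float
) -> tuple[float, float, float, bool]:
    apex = x[index]
    ref = apex - prominence / 2.0
    n = x.size
    clamped = False

    left = 0.0
    for j in range(index - 1, -1, -1):
        if x[j] <= ref:
            # x[j] <= ref < x[j + 1]: interpolate the crossing between them
            left = j + (ref - x[j]) / (x[j + 1] - x[j])
            break
    else:
        clamped = True

    right = float(n - 1)
    for j in range(index + 1, n):
        if x[j] <= ref:
            right = j - (ref - x[j]) / (x[j - 1] - x[j])
            break
    else:
        clamped = True

    return right - left, left, right, clamped


def compute_width(
    trace: VelocityTrace, index: int, prominence: float
) -> tuple[float, float, float, bool]:
    """Full width of the peak at half its prominence, in samples.

    The reference height is ``apex - prominence/2``. Walking outward from the
    apex, the first sample at or below the reference brackets a crossing whose
    exact position is linearly interpolated. Returns
    ``(width, left_crossing, right_crossing, clamped)``; a side that never
    drops to the reference before the trace end clamps to that end and sets
    ``clamped``.
    """
    if not (prominence > 0):
        raise ValueError(f"prominence must be positive, got {prominence}")
    return _width_at(trace.samples, index, prominence)


def find_peaks(
    trace: VelocityTrace,
    min_prominence: float,
    n_peaks: int = 1,
    selection: str = "first",
) -> list[PeakFeature]:
    """Detect up to ``n_peaks`` peaks with prominence >= ``min_prominence``.

    Every interior local maximum is measured; those passing the prominence
    threshold are candidates. With ``selection="first"`` (default, matching
    the behaviour of the routine this re-implements) the first ``n_peaks``
    candidates in time order are returned; ``selection="max_prominence"``
    returns the ``n_peaks`` most prominent ones instead, still sorted by time.
    An empty list is a valid outcome (no detectable response).
    """
    if not (min_prominence > 0):
        raise ValueError(f"min_prominence must be positive, got {min_prominence}")
    if n_peaks < 1:
        raise ValueError(f"n_peaks must be >= 1, got {n_peaks}")
    if selection not in ("first", "max_prominence"):
        raise ValueError(f"unknown selection {selection!r}")

    x = trace.samples
    candidates = [
        (i, p)
        for i in find_local_maxima(trace)
        if (p := _prominence_at(x, i)) >= min_prominence
    ]
    if selection == "first":
        chosen = candidates[:n_peaks]
    else:
        chosen = sorted(
            sorted(candidates, key=lambda c: -c[1])[:n_peaks], key=lambda c: c[0]
        )

    feats = []
    for i, prom in chosen:
        width, left, right, clamped = _width_at(x, i, prom)
        feats.append(
            PeakFeature(
                index=int(i),
                velocity=float(x[i]),
                prominence=float(prom),
                width=float(width),
                left_crossing=float(left),
                right_crossing=float(right),
                width_clamped=clamped,
            )
        )
    return feats
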