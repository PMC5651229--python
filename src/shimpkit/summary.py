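"""Per-test and per-protocol aggregation of impulse analyses.

Reproduces the per-test report of the analysis tool: impulse counts, mean
head peak velocity, count of low-velocity impulses (< 130 deg/s, strict, as
distinct from the inclusive 120 deg/s QC minimum), first-saccade latency
statistics, and the early / not-early breakdown with latency, width and
velocity means. All "mean ± SD" values use the sample SD (n-1 denominator).

Protocol comparison is purely descriptive: per-protocol mean first-saccade
latency (unweighted across tests) and all pairwise mean differences.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .analysis import ImpulseAnalysis

__all__ = [
    "GroupStats",
    "TestSummary",
    "ProtocolComparison",
    "summarize_test",
    "compare_protocol_means",
]


def _mean_sd(values: Sequence[float]) -> tuple[Optional[float], Optional[float]]:
    if len(values) == 0:
        return None, None
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else None
    return mean, sd


@dataclass(frozen=True)
class GroupStats:
    """Latency/width/velocity statistics over one saccade class (early or not)."""

    n: int
    latency_mean_ms: Optional[float]
    latency_sd_ms: Optional[float]
    width_mean_ms: Optional[float]
    width_sd_ms: Optional[float]
    velocity_mean: Optional[float]
    velocity_sd: Optional[float]


@dataclass(frozen=True)
class TestSummary:
    """Aggregates for one SHIMP test (one sequence of impulses)."""

    n_impulses: int
    rate_hz: float
    mean_head_peak_velocity: Optional[float]
    n_head_below_130: int
    first_saccade_latency_mean_ms: Optional[float]
    first_saccade_latency_sd_ms: Optional[float]
    pct_early: Optional[float]
    early: GroupStats
    not_early: GroupStats
    early_impulse_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class ProtocolComparison:
    """Per-protocol mean first-saccade latencies and pairwise differences (ms)."""

    protocols: tuple[str, ...]
    means_ms: Mapping[str, float]

    def difference(self, a: str, b: str) -> float:
        """Mean latency of protocol ``a`` minus that of ``b`` (antisymmetric)."""
        return self.means_ms[a] - self.means_ms[b]

    @property
    def differences_ms(self) -> dict[tuple[str, str], float]:
        return {
            (a, b): self.difference(a, b)
            for a, b in itertools.combinations(self.protocols, 2)
        }


def _group_stats(measures) -> GroupStats:
    lat_mean, lat_sd = _mean_sd([m.latency_ms for m in measures])
    w_mean, w_sd = _mean_sd([m.width_ms for m in measures])
    v_mean, v_sd = _mean_sd([m.velocity for m in measures])
    return GroupStats(len(measures), lat_mean, lat_sd, w_mean, w_sd, v_mean, v_sd)


def summarize_test(
    analyses: Sequence[ImpulseAnalysis],
    rate_hz: float = 250.0,
    low_velocity_threshold: float = 130.0,
) -> TestSummary:
    """Aggregate per-impulse analyses into one test summary.

    The "first saccade" of an impulse is its single detected saccade, whether
    early or not; impulses without a detected saccade contribute to
    ``n_impulses`` only. ``pct_early`` is undefined (None) when no saccade
    was detected in the whole test.
    """
    if len(analyses) == 0:
        raise ValueError("cannot summarize an empty list of analyses")

    head_velocities = [a.head_peak.velocity for a in analyses if a.head_peak]
    head_mean, _ = _mean_sd(head_velocities)
    n_below = sum(1 for v in head_velocities if v < low_velocity_threshold)

    with_sac = [a for a in analyses if a.saccade is not None]
    lat_mean, lat_sd = _mean_sd([a.saccade.latency_ms for a in with_sac])

    early = [a for a in with_sac if a.saccade.early]
    not_early = [a for a in with_sac if not a.saccade.early]
    pct_early = 100.0 * len(early) / len(with_sac) if with_sac else None

    return TestSummary(
        n_impulses=len(analyses),
        rate_hz=rate_hz,
        mean_head_peak_velocity=head_mean,
        n_head_below_130=n_below,
        first_saccade_latency_mean_ms=lat_mean,
        first_saccade_latency_sd_ms=lat_sd,
        pct_early=pct_early,
        early=_group_stats([a.saccade for a in early]),
        not_early=_group_stats([a.saccade for a in not_early]),
        early_impulse_ids=tuple(a.record_ref for a in early),
    )


def compare_protocol_means(
    summaries: Mapping[str, Iterable[TestSummary]],
) -> ProtocolComparison:
    """Descriptive comparison of first-saccade latency across protocols.

    The per-protocol mean is the unweighted mean of per-test latency means;
    a protocol whose tests carry no latency data is excluded with a warning.
    At least two protocols must be supplied.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two protocols to compare")
    means: dict[str, float] = {}
    for protocol, tests in summaries.items():
        values = [
            t.first_saccade_latency_mean_ms
            for t in tests
            if t.first_saccade_latency_mean_ms is not None
        ]
        if not values:
            warnings.warn(
                f"protocol {protocol!r} has no first-saccade latency data; excluded",
                stacklevel=2,
            )
            continue
        means[protocol] = float(np.mean(values))
    return ProtocolComparison(protocols=tuple(means), means_ms=means)
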