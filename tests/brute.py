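"""Independent brute-force oracle for the peak primitives.

Implements the definitions (local maximum with plateau-first rule,
topographic prominence, half-prominence width) by exhaustive enumeration and
numeric bisection on the piecewise-linear interpolant — deliberately not
sharing code or algorithmic structure with the package implementation.
"""

from __future__ import annotations

import numpy as np


def brute_local_maxima(x) -> list[int]:
    x = np.asarray(x, dtype=float)
    n = len(x)
    out = []
    for i in range(1, n - 1):
        if x[i - 1] == x[i]:
            continue  # not the first sample of its plateau
        j = i - 1
        k = i + 1
        while k < n and x[k] == x[i]:
            k += 1
        if k < n and x[j] < x[i] and x[k] < x[i]:
            out.append(i)
    return out


def brute_prominence(x, i: int) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x)
    apex = x[i]
    higher_left = [j for j in range(i) if x[j] > apex]
    lo = max(higher_left) + 1 if higher_left else 0
    higher_right = [j for j in range(i + 1, n) if x[j] > apex]
    hi = min(higher_right) if higher_right else n
    left_min = float(np.min(x[lo : i + 1]))
    right_min = float(np.min(x[i:hi]))
    return float(apex - max(left_min, right_min))


def _bisect_crossing(x, lo: float, hi: float, ref: float, increasing: bool) -> float:
    # Find p in [lo, hi] where the linear interpolant equals ref, by bisection.
    f = lambda p: np.interp(p, np.arange(len(x)), x)
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if (f(mid) < ref) == increasing:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def brute_width(x, i: int, prominence: float):
    """Return (width, left, right, clamped) at the half-prominence height."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    ref = x[i] - prominence / 2.0
    clamped = False

    left = 0.0
    for j in range(i - 1, -1, -1):
        if x[j] <= ref:
            left = _bisect_crossing(x, j, j + 1, ref, increasing=True)
            break
    else:
        clamped = True

    right = float(n - 1)
    for j in range(i + 1, n):
        if x[j] <= ref:
            right = _bisect_crossing(x, j - 1, j, ref, increasing=False)
            break
    else:
        clamped = True

    return right - left, left, right, clamped


def brute_find_peaks(x, min_prominence: float, n_peaks: int = 1):
    """First-in-time passing peaks as (index, prominence, width) tuples."""
    found = []
    for i in brute_local_maxima(x):
        prom = brute_prominence(x, i)
        if prom >= min_prominence:
            width, *_ = brute_width(x, i, prom)
            found.append((i, prom, width))
    return found[:n_peaks]
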