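"""Shared signal-processing helpers (zero-phase filtering, local fits)."""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy.signal import butter, filtfilt


def lowpass(x: np.ndarray, rate: float, cutoff_hz: Optional[float], order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the first axis (None = no-op)."""
    if cutoff_hz is None or cutoff_hz <= 0 or cutoff_hz >= rate / 2:
        return np.asarray(x, dtype=float)
    b, a = butter(order, cutoff_hz / (rate / 2.0))
    return filtfilt(b, a, x, axis=0)


def cubic_extremum(
    t: np.ndarray, y: np.ndarray, lo: float, hi: float
) -> Optional[Tuple[float, float]]:
    """Stationary point of a local cubic least-squares fit within [lo, hi].

    Returns (t*, y*) of the stationary point inside the bracket, or None.
    Used for sub-sample refinement of force peaks/dips: the synthetic walk
    waveform is piecewise cubic with a node at each extremum, so one-sided
    fits on either side of the sampled extremum recover the exact node.
    """
    if len(t) < 5:
        return None
    t0 = t.mean()
    c = np.polyfit(t - t0, y, 3)
    dc = np.polyder(c)
    roots = np.roots(dc)
    best = None
    for r in roots:
        if abs(r.imag) > 1e-12:
            continue
        tr = float(r.real) + t0
        if lo - 1e-12 <= tr <= hi + 1e-12:
            yr = float(np.polyval(c, tr - t0))
            if best is None or abs(tr - t.mean()) < abs(best[0] - t.mean()):
                best = (tr, yr)
    return best


def quadratic_extremum_value(t: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Vertex of a parabolic fit (for smooth marker-signal extrema)."""
    t0 = t.mean()
    a, b, c = np.polyfit(t - t0, y, 2)
    if a == 0:
        i = int(np.argmax(np.abs(y - y.mean())))
        return float(t[i]), float(y[i])
    tv = -b / (2 * a)
    return float(tv + t0), float(np.polyval([a, b, c], tv))


def local_extrema(y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Indices of strict local minima and maxima of a 1-D signal."""
    d = np.diff(y)
    s = np.sign(d)
    # propagate the sign across flat runs so plateaus count once
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    turn = np.diff(s)
    minima = np.where(turn > 0)[0] + 1
    maxima = np.where(turn < 0)[0] + 1
    return minima, maxima
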