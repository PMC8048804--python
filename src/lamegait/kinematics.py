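"""Upper-body symmetry indices and limb kinematics per stride.

Vertical symmetry of a landmark (poll, withers) is computed per stride with
half-cycles delimited by the two forelimb hoof-on events: MinDiff is the
difference of the two half-cycle minima (right minus left), RUD/RDD compare
the upward/downward excursion amplitudes around those minima, and ROMz is
the total vertical range over the stride.  Limb kinematics: sagittal
protraction/retraction of the pivot->hoof segment, maximal fetlock
hyperextension during stance, swing peak speed, protraction height and
stance length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from ._signal import local_extrema, lowpass, quadratic_extremum_value
from .config import ExtractionConfig

logger = logging.getLogger(__name__)


@dataclass
class _Extremum:
    t: float
    value: float
    kind: str  # 'min' | 'max'


def _refined_extrema(t: np.ndarray, z: np.ndarray) -> List[_Extremum]:
    minima, maxima = local_extrema(z)
    out: List[_Extremum] = []
    for idx, kind in [(i, "min") for i in minima] + [(i, "max") for i in maxima]:
        a = max(0, idx - 3)
        b = min(len(z), idx + 4)
        tv, zv = quadratic_extremum_value(t[a:b], z[a:b])
        if not t[a] <= tv <= t[b - 1]:
            tv, zv = float(t[idx]), float(z[idx])
        out.append(_Extremum(tv, zv, kind))
    out.sort(key=lambda e: e.t)
    return out


def vertical_symmetry(
    time: np.ndarray,
    signal: np.ndarray,
    window: Tuple[float, float],
    split: float,
    rate: float,
    config: ExtractionConfig = ExtractionConfig(),
    _extrema: Optional[List[_Extremum]] = None,
) -> Optional[Dict[str, float]]:
    """Symmetry indices of one landmark over one stride.

    ``window`` is the stride (left-fore hoof-on to next); ``split`` is the
    contralateral-fore hoof-on delimiting the two half-cycles.  The left
    half-cycle begins with the left forelimb's stance, the right half with
    the right's.  Returns None (flagged, excluded) when a half-cycle has no
    interior minimum or the trailing maximum is not observable.
    """
    t0, t1 = window
    if not t0 < split < t1:
        return None
    if _extrema is None:
        signal = lowpass(signal, rate, config.marker_lowpass_hz)
        _extrema = _refined_extrema(np.asarray(time, dtype=float), signal)
    ext = _extrema

    def min_in(a: float, b: float) -> Optional[_Extremum]:
        cands = [e for e in ext if e.kind == "min" and a < e.t < b]
        return min(cands, key=lambda e: e.value) if cands else None

    def next_of(kind: str, after: float) -> Optional[_Extremum]:
        cands = [e for e in ext if e.kind == kind and e.t > after]
        return min(cands, key=lambda e: e.t) if cands else None

    def prev_of(kind: str, before: float) -> Optional[_Extremum]:
        cands = [e for e in ext if e.kind == kind and e.t < before]
        return max(cands, key=lambda e: e.t) if cands else None

    min_left = min_in(t0, split)
    min_right = min_in(split, t1)
    if min_left is None or min_right is None:
        logger.info("stride at %.3f s: missing interior half-cycle minimum", t0)
        return None
    max_after_l = next_of("max", min_left.t)
    max_after_r = next_of("max", min_right.t)
    max_before_l = prev_of("max", min_left.t)
    max_before_r = prev_of("max", min_right.t)
    if None in (max_after_l, max_after_r, max_before_l, max_before_r):
        return None

    min_diff = min_right.value - min_left.value
    rud = (max_after_l.value - min_left.value) - (max_after_r.value - min_right.value)
    rdd = (max_before_l.value - min_left.value) - (max_before_r.value - min_right.value)
    inside = [e.value for e in ext if t0 <= e.t <= t1]
    edge_vals = [float(np.interp(x, time, signal)) for x in (t0, t1)]
    allv = inside + edge_vals
    romz = max(allv) - min(allv)
    return {"MinDiff": min_diff, "RUD": rud, "RDD": rdd, "ROMz": romz}


def _refined_max(time: np.ndarray, series: np.ndarray, mask: np.ndarray) -> float:
    """Peak of a smooth series on a masked span, robust to sample noise.

    The peak is *located* on a moving-average copy (so the argmax does not
    chase the highest noise excursion) and the value is a parabolic fit of
    the raw series around that location, which averages the noise instead of
    selecting its maximum.  Falls back to the sampled maximum at span edges.
    """
    idx = np.flatnonzero(mask)
    vals = series[idx]
    loc_w, fit_h = 21, 11
    if len(idx) >= loc_w + 2:
        kernel = np.ones(loc_w) / loc_w
        smooth = np.convolve(vals, kernel, mode="same")
        h = loc_w // 2
        smooth[:h] = -np.inf
        smooth[-h:] = -np.inf
        i = idx[int(np.argmax(smooth))]
    else:
        i = idx[int(np.argmax(vals))]
    a = max(idx[0], i - fit_h)
    b = min(idx[-1], i + fit_h) + 1
    if b - a < 5:
        return float(series[idx[np.argmax(vals)]])
    tv, v = quadratic_extremum_value(time[a:b], series[a:b])
    if not np.isfinite(v) or not time[a] <= tv <= time[b - 1]:
        return float(np.max(series[a:b]))
    return float(v)


def fetlock_peak_fraction(
    time: np.ndarray,
    hyperext_deg: np.ndarray,
    stances: List[Tuple[float, float]],
) -> Optional[float]:
    """Stance fraction of the fetlock-extension peak, from the ensemble mean.

    All stances of a trial are resampled onto a common stance-fraction grid
    and averaged; the argmax of the averaged curve fixes the peak phase used
    for every stride of that trial.
    """
    grid = np.linspace(0.0, 1.0, 201)
    curves = []
    for on, off in stances:
        m = (time >= on) & (time <= off)
        if m.sum() < 5:
            continue
        s = (time[m] - on) / (off - on)
        curves.append(np.interp(grid, s, hyperext_deg[m]))
    if not curves:
        return None
    avg = np.mean(curves, axis=0)
    i = int(np.argmax(avg))
    a, b = max(0, i - 5), min(len(grid), i + 6)
    tv, _ = quadratic_extremum_value(grid[a:b], avg[a:b])
    if not grid[a] <= tv <= grid[b - 1]:
        tv = grid[i]
    return float(np.clip(tv, 0.0, 1.0))


def limb_angle(pivot: np.ndarray, hoof: np.ndarray) -> np.ndarray:
    """Signed sagittal angle (deg) of the pivot->hoof segment vs vertical.

    Cranial (hoof ahead of pivot) positive.  Raises on zero-length segments.
    """
    dy = hoof[:, 1] - pivot[:, 1]
    dz = pivot[:, 2] - hoof[:, 2]
    if np.any(np.hypot(dy, dz) < 1e-9):
        raise ValueError("zero-length pivot->hoof segment")
    return np.degrees(np.arctan2(dy, dz))


def fetlock_angle(prox: np.ndarray, fetlock: np.ndarray, hoof: np.ndarray) -> np.ndarray:
    """Fetlock hyperextension time series: 180 deg minus the vertex angle."""
    a = prox - fetlock
    b = hoof - fetlock
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na < 1e-9) or np.any(nb < 1e-9):
        raise ValueError("degenerate (coincident) fetlock markers")
    cosang = np.clip(np.einsum("ij,ij->i", a, b) / (na * nb), -1.0, 1.0)
    vertex = np.degrees(np.arccos(cosang))
    return 180.0 - vertex


def stride_limb_kinematics(
    time: np.ndarray,
    angle_deg: np.ndarray,
    hyperext_deg: np.ndarray,
    hoof: np.ndarray,
    stance: Tuple[float, float],
    swing: Optional[Tuple[float, float]],
    belt_speed: float,
    rate: float,
    config: ExtractionConfig = ExtractionConfig(),
    fetlock_peak_frac: Optional[float] = None,
) -> Dict[str, float]:
    """Per-stride limb parameters: angles, A_fetlock, swing metrics, StL."""
    on, off = stance
    out: Dict[str, float] = {}

    if swing is not None:
        span = (time >= on) & (time <= swing[1])
        if span.sum() >= 3:
            out["Prot_max"] = float(np.max(angle_deg[span]))
            out["Ret_max"] = float(np.min(angle_deg[span]))
    in_stance = (time >= on) & (time <= off)
    if in_stance.sum() >= 3:
        if fetlock_peak_frac is not None:
            # peak phase fixed per trial from the stride-ensemble average:
            # avoids the selection bias of a per-stride argmax when the
            # extension curve has two nearly equal maxima
            t_peak = on + fetlock_peak_frac * (off - on)
            i = int(np.clip(np.searchsorted(time, t_peak), 0, len(time) - 1))
            a = max(0, i - 11)
            b = min(len(time), i + 12)
            tv, v = quadratic_extremum_value(time[a:b], hyperext_deg[a:b])
            if np.isfinite(v) and time[a] <= tv <= time[b - 1]:
                out["A_fetlock"] = float(v)
            else:
                out["A_fetlock"] = float(np.max(hyperext_deg[a:b]))
        else:
            out["A_fetlock"] = _refined_max(time, hyperext_deg, in_stance)
    out["StL"] = float(abs(np.interp(off, time, hoof[:, 1]) - np.interp(on, time, hoof[:, 1])))

    if swing is not None:
        s0, s1 = swing
        m = (time > s0) & (time < s1)
        if m.sum() < 3:
            logger.info("swing at %.3f s shorter than 3 marker frames", s0)
        else:
            pos = hoof
            if config.speed_lowpass_hz:
                pos = lowpass(hoof, rate, config.speed_lowpass_hz)
            vel = np.gradient(pos, 1.0 / rate, axis=0)
            speed = np.linalg.norm(vel, axis=1)
            out["Prot_speed"] = _refined_max(time, speed, m)
            out["ProtH"] = _refined_max(time, hoof[:, 2], m)
    return out
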