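"""Gait-event detection from vertical GRF traces.

Stance onset/offset is the intersection of the linear approximation to the
initial/terminal slope of the force curve with the zero baseline: candidate
stances are located by threshold crossing, then a least-squares line is fit
to the rising limb between 20% and 80% of the first local force maximum and
extrapolated to zero (symmetrically on the falling limb for hoof-off).
Strides are segmented by consecutive left-forelimb hoof-ons.  All event
times are real-valued (sub-sample) seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._signal import lowpass
from .config import (
    CONTRALATERAL,
    DIAGONAL,
    ExtractionConfig,
    IPSILATERAL,
    LIMBS,
)

logger = logging.getLogger(__name__)

#: walk support-phase catalogue: limb set -> phase label (Fig-style numbering)
WALK_SUPPORT_LABELS: Dict[frozenset, str] = {
    frozenset({"RF", "LH", "LF"}): "1",  # tripedal
    frozenset({"LH", "LF"}): "2",        # left ipsilateral bipedal
    frozenset({"LH", "LF", "RH"}): "3",  # tripedal
    frozenset({"LF", "RH"}): "4",        # left diagonal bipedal
    frozenset({"LF", "RH", "RF"}): "5",  # tripedal
    frozenset({"RH", "RF"}): "6",        # right ipsilateral bipedal
    frozenset({"RH", "RF", "LH"}): "7",  # tripedal
    frozenset({"RF", "LH"}): "8",        # right diagonal bipedal
}

TROT_SUPPORT_LABELS: Dict[frozenset, str] = {
    frozenset({"LF", "RH"}): "diag_left",
    frozenset({"RF", "LH"}): "diag_right",
    frozenset(): "suspension",
}


@dataclass
class StrideEvents:
    """Detected stances per limb plus stride windows from LF hoof-ons."""

    stances: Dict[str, List[Tuple[float, float]]]
    stride_windows: List[Tuple[float, float]] = field(default_factory=list)

    def ons(self, limb: str) -> np.ndarray:
        return np.asarray([s[0] for s in self.stances[limb]])

    def offs(self, limb: str) -> np.ndarray:
        return np.asarray([s[1] for s in self.stances[limb]])


def _crossing_time(
    t: np.ndarray, f: np.ndarray, level: float, i_from: int, i_to: int, rising: bool
) -> Optional[float]:
    """Sub-sample time where f crosses ``level`` between i_from and i_to."""
    if rising:
        idx = np.flatnonzero(f[i_from:i_to] >= level)
        if idx.size == 0:
            return None
        j = i_from + idx[0]
        if j == 0:
            return None
    else:
        idx = np.flatnonzero(f[i_from:i_to] >= level)
        if idx.size == 0:
            return None
        j = i_from + idx[-1] + 1
        if j >= len(f):
            return None
    a, b = j - 1, j
    if f[b] == f[a]:
        return float(t[a])
    return float(t[a] + (level - f[a]) * (t[b] - t[a]) / (f[b] - f[a]))


def _chord_zero(
    t: np.ndarray, f: np.ndarray, peak: float, i_lo: int, i_hi: int,
    lo_frac: float, hi_frac: float, rising: bool,
) -> Optional[float]:
    """Zero intercept of the chord through the lo/hi crossings of one limb.

    The chord through the 20% and 80% crossing points is the linear
    approximation to the initial (terminal) slope; its intersection with the
    zero baseline is the hoof-on (hoof-off) time.
    """
    t_lo = _crossing_time(t, f, lo_frac * peak, i_lo, i_hi, rising)
    t_hi = _crossing_time(t, f, hi_frac * peak, i_lo, i_hi, rising)
    if t_lo is None or t_hi is None or t_lo == t_hi:
        return None
    slope = (hi_frac - lo_frac) * peak / (t_hi - t_lo)
    return t_lo - lo_frac * peak / slope


def detect_stances(
    force: np.ndarray,
    rate: float,
    body_mass: Optional[float] = None,
    config: ExtractionConfig = ExtractionConfig(),
) -> List[Tuple[float, float]]:
    """Detect (hoof_on, hoof_off) stance intervals in one limb's force trace.

    Parameters
    ----------
    force : raw vertical GRF trace in newtons (baseline approximately zero).
    rate : sampling rate, Hz.
    body_mass : unused by the default absolute threshold; accepted so callers
        can pass trial metadata for mass-relative thresholds in subclasses.

    Candidate stances shorter than ``config.min_stance_s`` are discarded with
    a log entry.  Stances touching the trace edges are dropped (their rising
    or falling limb is incomplete).
    """
    force = np.asarray(force, dtype=float)
    if force.size == 0 or not np.any(force > config.stance_threshold_N):
        return []
    t = np.arange(force.size) / rate
    # baseline removal: median of the swing-phase plateau
    plateau = force[force < 0.25 * np.percentile(force, 95)]
    if plateau.size:
        force = force - np.median(plateau)
    smooth = lowpass(force, rate, config.force_lowpass_hz)

    above = smooth > config.stance_threshold_N
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(force.size)

    # merge regions separated by short gaps
    regions: List[Tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if regions and (s - regions[-1][1]) / rate < config.merge_gap_s:
            regions[-1] = (regions[-1][0], e)
        else:
            regions.append((s, e))

    stances: List[Tuple[float, float]] = []
    for s, e in regions:
        if (e - s) / rate < config.min_stance_s:
            logger.info("discarding stance candidate of %.0f ms (< %.0f ms minimum)",
                        1e3 * (e - s) / rate, 1e3 * config.min_stance_s)
            continue
        if s == 0 or e == force.size:
            continue  # incomplete stance at trace edge
        seg = smooth[s:e]
        # first / last local maxima of the smoothed segment
        interior = np.flatnonzero((seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:])) + 1
        if interior.size == 0:
            interior = np.array([int(np.argmax(seg))])
        p_first = s + int(interior[0])
        p_last = s + int(interior[-1])
        p1 = smooth[p_first]
        p2 = smooth[p_last]

        i_start = max(0, s - int(0.05 * rate))  # rise may begin below threshold
        on = _chord_zero(t, smooth, p1, i_start, p_first + 1,
                         config.chord_lo, config.chord_hi, rising=True)
        i_end = min(force.size, e + int(0.05 * rate))
        off = _chord_zero(t, smooth, p2, p_last, i_end,
                          config.chord_lo, config.chord_hi, rising=False)

        if on is None or off is None or not on < off:
            logger.warning("slope fit failed for stance candidate at %.3f s", t[s])
            continue
        half = 0.5 / rate
        if on < t[0] - half or off > t[-1] + half:
            continue  # extrapolated event outside the recorded trace
        stances.append((on, off))
    return stances


def detect_events(
    forces: np.ndarray,
    rate: float,
    body_mass: Optional[float] = None,
    config: ExtractionConfig = ExtractionConfig(),
) -> StrideEvents:
    """Detect stances for all four limbs and segment strides (columns = LIMBS)."""
    stances = {
        limb: detect_stances(forces[:, j], rate, body_mass, config)
        for j, limb in enumerate(LIMBS)
    }
    ev = StrideEvents(stances=stances)
    ev.stride_windows = segment_strides(ev)
    return ev


def segment_strides(events: StrideEvents) -> List[Tuple[float, float]]:
    """Stride windows between consecutive left-forelimb hoof-ons."""
    ons = events.ons("LF")
    if len(ons) < 2:
        logger.warning("fewer than 2 LF hoof-ons: no strides segmented")
        return []
    return [(float(a), float(b)) for a, b in zip(ons[:-1], ons[1:])]


def _first_on_in(ons: np.ndarray, t0: float, t1: float) -> Optional[float]:
    m = ons[(ons >= t0 - 1e-9) & (ons < t1 - 1e-9)]
    return float(m[0]) if m.size else None


def _next_on(ons: np.ndarray, t: float) -> Optional[float]:
    m = ons[ons > t + 1e-9]
    return float(m[0]) if m.size else None


def _nearest_on(ons: np.ndarray, t: float) -> Optional[float]:
    if ons.size == 0:
        return None
    return float(ons[np.argmin(np.abs(ons - t))])


def temporal_parameters(
    events: StrideEvents, window: Tuple[float, float], gait: str = "walk"
) -> Optional[Dict[str, float]]:
    """Temporal stride parameters for one stride window.

    Returns stride duration SD; absolute and relative stance durations per
    limb; step durations StpDi (ipsilateral hind -> same-side fore) and StpDc
    (fore -> contralateral fore) per side; diagonal dissociation TAP per
    diagonal (fore_on - diagonal hind_on; forelimb-first negative).  Returns
    None (incomplete) if any limb lacks an event in the window.
    """
    t0, t1 = window
    sd = t1 - t0
    out: Dict[str, float] = {"SD": sd}
    ons_within: Dict[str, float] = {}
    # limbs whose footfall phase is near the stride boundary (trot diagonal
    # partner of the reference forelimb) may jitter just across it
    tol = 0.1 * sd
    for limb in LIMBS:
        ons = events.ons(limb)
        on = _first_on_in(ons, t0 - tol, t1 - tol)
        if on is None:
            return None
        offs = events.offs(limb)
        off = offs[np.argmin(np.abs(events.ons(limb) - on))]
        std = float(off - on)
        if not 0 < std < sd * 1.5:
            return None
        ons_within[limb] = on
        out[f"StD_abs_{limb}"] = std
        out[f"StD_rel_{limb}"] = std / sd
    for fore, hind, side in (("LF", "LH", "left"), ("RF", "RH", "right")):
        nxt = _next_on(events.ons(fore), ons_within[hind])
        if nxt is None:
            return None
        out[f"StpDi_{side}"] = nxt - ons_within[hind]
        contra = CONTRALATERAL[fore]
        nxt = _next_on(events.ons(contra), ons_within[fore])
        if nxt is None:
            return None
        out[f"StpDc_{side}"] = nxt - ons_within[fore]
        diag_hind_on = _nearest_on(events.ons(DIAGONAL[fore]), ons_within[fore])
        if diag_hind_on is None:
            return None
        out[f"TAP_{side}"] = ons_within[fore] - diag_hind_on
    return out


def support_phases(
    events: StrideEvents,
    window: Tuple[float, float],
    gait: str,
    min_phase_s: float = 0.002,
) -> List[Tuple[str, float, float]]:
    """Labelled support-phase sequence tiling one stride window.

    Walk phases follow the eight-phase tripedal/bipedal catalogue; limb sets
    outside the catalogue are labelled 'other' and logged.  Intervals shorter
    than ``min_phase_s`` (detection jitter around nominally simultaneous
    contacts, e.g. trot diagonal pairs) are absorbed into their predecessor.
    Interval durations sum exactly to the stride duration.
    """
    t0, t1 = window
    cuts = {t0, t1}
    for limb in LIMBS:
        for on, off in events.stances[limb]:
            for x in (on, off):
                if t0 < x < t1:
                    cuts.add(float(x))
    grid = sorted(cuts)
    labels = WALK_SUPPORT_LABELS if gait == "walk" else TROT_SUPPORT_LABELS
    seq: List[Tuple[str, float, float]] = []
    for a, b in zip(grid[:-1], grid[1:]):
        mid = 0.5 * (a + b)
        in_stance = frozenset(
            limb
            for limb in LIMBS
            if any(on <= mid < off for on, off in events.stances[limb])
        )
        label = labels.get(in_stance)
        if label is None:
            label = "other"
            logger.info("support set %s at %.3f s not in %s catalogue",
                        set(in_stance) or "{}", mid, gait)
        if seq and seq[-1][0] == label:
            seq[-1] = (label, seq[-1][1], b)
        else:
            seq.append((label, a, b))
    # absorb micro-intervals from near-simultaneous contacts
    merged: List[Tuple[str, float, float]] = []
    for label, a, b in seq:
        if merged and (b - a) < min_phase_s:
            lab0, a0, _ = merged[-1]
            merged[-1] = (lab0, a0, b)
        elif merged and (merged[-1][2] - merged[-1][1]) < min_phase_s:
            merged[-1] = (label, merged[-1][1], b)
        elif merged and merged[-1][0] == label:
            merged[-1] = (label, merged[-1][1], b)
        else:
            merged.append((label, a, b))
    return merged


def support_phase_percentages(
    seq: Sequence[Tuple[str, float, float]], window: Tuple[float, float]
) -> Dict[str, float]:
    """Total duration of each support label as percent of the stride."""
    sd = window[1] - window[0]
    out: Dict[str, float] = {}
    for label, a, b in seq:
        out[label] = out.get(label, 0.0) + 100.0 * (b - a) / sd
    return out
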