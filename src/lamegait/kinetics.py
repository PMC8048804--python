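"""Per-stride vertical-force parameters, normalised to body mass.

Walk stances are double-peaked: the two largest local maxima (in stance
order) give Fz_peak1 and Fz_peak2 with the intervening minimum as the force
dip.  Trot stances are single-peaked.  The vertical impulse Iz is the time
integral of the normalised force over stance; loading and unloading rates
are 20-80% chord slopes of the rising/falling limb (the unloading rate is
reported as a positive magnitude).  First-peak timing t_Fz_peak1 is percent
of stance.  Peak values are refined to sub-sample precision with one-sided
local cubic fits on the raw trace.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.signal import find_peaks

from ._signal import cubic_extremum, lowpass
from .config import ExtractionConfig

logger = logging.getLogger(__name__)

_FIT_HALF_WIDTH = 8  # samples on each side of a sampled extremum


def _refine_extremum(
    t: np.ndarray, f: np.ndarray, i: int, maximum: bool
) -> Tuple[float, float]:
    """Sub-sample extremum near sample i via one-sided cubic fits.

    The synthetic waveform is piecewise cubic with a node at each extremum,
    so fits on the left and right of the node each recover the exact segment;
    the better of the two stationary values is returned.  Falls back to the
    sampled extremum when no valid stationary point exists.
    """
    n = len(t)
    # re-centre on the raw extremum near the smoothed location: the raw
    # argmax sits within one sample of the waveform node, so the one-sided
    # windows do not straddle it
    a0, b0 = max(0, i - 3), min(n, i + 4)
    local = f[a0:b0]
    i = a0 + int(np.argmax(local) if maximum else np.argmin(local))
    candidates = []
    lo = max(0, i - _FIT_HALF_WIDTH)
    hi = min(n - 1, i + _FIT_HALF_WIDTH)
    for a, b in ((lo, i + 1), (i, hi + 1)):
        if b - a >= 5:
            res = cubic_extremum(t[a:b], f[a:b], t[max(a, i - 2)], t[min(b - 1, i + 2)])
            if res is not None:
                candidates.append(res)
    if not candidates:
        return float(t[i]), float(f[i])
    pick = max(candidates, key=lambda r: r[1]) if maximum else min(
        candidates, key=lambda r: r[1]
    )
    return pick


def _chord_rate(
    t: np.ndarray,
    f: np.ndarray,
    smooth: np.ndarray,
    peak_value: float,
    peak_idx: int,
    rising: bool,
    cfg: ExtractionConfig,
) -> Optional[float]:
    """Least-squares slope of the raw force between the 20% and 80% band."""
    lo = cfg.chord_lo * peak_value
    hi = cfg.chord_hi * peak_value
    if rising:
        idx = np.flatnonzero((smooth[: peak_idx + 1] >= lo) & (smooth[: peak_idx + 1] <= hi))
    else:
        idx = peak_idx + np.flatnonzero((smooth[peak_idx:] >= lo) & (smooth[peak_idx:] <= hi))
    if idx.size < 2:
        return None
    slope = np.polyfit(t[idx], f[idx], 1)[0]
    return float(slope)


def kinetic_parameters(
    force: np.ndarray,
    stance: Tuple[float, float],
    mass: float,
    rate: float,
    gait: str,
    config: ExtractionConfig = ExtractionConfig(),
) -> Dict[str, float]:
    """Kinetic parameters of one stance of one limb.

    Parameters are in N/kg (forces), N.s/kg (Iz), N/kg/s (rates) and percent
    of stance (t_Fz_peak1).  Walk stances without two local maxima after
    smoothing are flagged ``monophasic`` with peak2/dip missing (NaN).
    """
    on, off = stance
    if mass <= 0:
        raise ValueError("body mass must be positive")
    t_all = np.arange(force.size) / rate
    half = 0.5 / rate
    if on < t_all[0] - half or off > t_all[-1] + half or on >= off:
        raise ValueError("stance not inside force trace")
    on = max(on, float(t_all[0]))
    off = min(off, float(t_all[-1]))
    f_norm = np.asarray(force, dtype=float) / mass

    i0 = int(np.searchsorted(t_all, on))
    i1 = int(np.searchsorted(t_all, off))
    t = t_all[i0:i1]
    f = f_norm[i0:i1]
    smooth = lowpass(f_norm, rate, config.force_lowpass_hz)[i0:i1]

    # vertical impulse on the sub-sample-clipped stance window
    tt = np.concatenate([[on], t, [off]])
    ff = np.concatenate([[np.interp(on, t_all, f_norm)], f, [np.interp(off, t_all, f_norm)]])
    iz = float(np.trapezoid(ff, tt))

    out: Dict[str, float] = {"Iz": iz}
    stance_dur = off - on

    if gait == "walk":
        peaks, _ = find_peaks(smooth, prominence=0.02 * smooth.max())
        if peaks.size < 2:
            logger.info("monophasic walk stance at %.3f s", on)
            i_peak = int(np.argmax(smooth))
            t1p, p1 = _refine_extremum(t, f, i_peak, maximum=True)
            out.update(
                Fz_peak1=p1,
                Fz_peak2=np.nan,
                Fz_dip=np.nan,
                t_Fz_peak1=100.0 * (t1p - on) / stance_dur,
                monophasic=1.0,
            )
            rate_peak_idx = i_peak
            rate_peak_val = p1
            last_peak_idx = i_peak
            last_peak_val = p1
        else:
            two = np.sort(peaks[np.argsort(smooth[peaks])[-2:]])
            ia, ib = int(two[0]), int(two[1])
            t1p, p1 = _refine_extremum(t, f, ia, maximum=True)
            t2p, p2 = _refine_extremum(t, f, ib, maximum=True)
            i_dip = ia + int(np.argmin(smooth[ia:ib + 1]))
            _, dip = _refine_extremum(t, f, i_dip, maximum=False)
            out.update(
                Fz_peak1=p1,
                Fz_peak2=p2,
                Fz_dip=dip,
                t_Fz_peak1=100.0 * (t1p - on) / stance_dur,
                monophasic=0.0,
            )
            rate_peak_idx, rate_peak_val = ia, p1
            last_peak_idx, last_peak_val = ib, p2
    else:
        i_peak = int(np.argmax(smooth))
        tp, pk = _refine_extremum(t, f, i_peak, maximum=True)
        out.update(Fz_peak=pk, t_Fz_peak1=100.0 * (tp - on) / stance_dur)
        rate_peak_idx, rate_peak_val = i_peak, pk
        last_peak_idx, last_peak_val = i_peak, pk

    load = _chord_rate(t, f, smooth, rate_peak_val, rate_peak_idx, True, config)
    unload = _chord_rate(t, f, smooth, last_peak_val, last_peak_idx, False, config)
    out["dFz_load"] = np.nan if load is None else load
    out["dFz_unload"] = np.nan if unload is None else abs(unload)
    return out
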