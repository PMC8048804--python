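"""Centre-of-mass proxy, centre of force, and COF-COM path metrics.

The COM is proxied per frame as a weighted mean of the sternum and L3
markers (trunk-segment approximation).  The COF is the force-weighted mean
of the hoof ground positions,

    COF_xy = sum_limbs(Fz_limb * hoof_xy_limb) / sum_limbs(Fz_limb),

defined only when total vertical force is positive (undefined frames occur
only during trot suspension).  Marker series are resampled onto the force
timeline by linear interpolation.  The walk COF-COM path metric is, per
side, the maximal cranial displacement of the COF relative to the COM
during the transition from tripedal support into that side's ipsilateral
bipedal support.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

#: walk support phases bracketing the transition into each side's
#: ipsilateral bipedal support (tripedal -> bipedal)
_SIDE_WINDOW_LABELS = {"left": ("1", "2"), "right": ("5", "6")}


def com_proxy(sternum: np.ndarray, l3: np.ndarray, w: float = 0.6) -> np.ndarray:
    """COM proxy: w * sternum + (1 - w) * l3, per frame (NaN propagates)."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("COM weight w must be in [0, 1]")
    return w * np.asarray(sternum, dtype=float) + (1.0 - w) * np.asarray(l3, dtype=float)


def cof(forces: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Centre of force per frame.

    Parameters
    ----------
    forces : (n, 4) vertical GRF per limb, N (must be >= 0; small negative
        noise values are clipped to zero).
    positions : (n, 4, 2) hoof ground positions (x, y) per limb, m.

    Returns (n, 2); frames with non-positive total force are NaN.  The COF is
    a convex combination of supporting-hoof positions; containment in their
    bounding box is asserted for every defined frame.
    """
    f = np.clip(np.asarray(forces, dtype=float), 0.0, None)
    pos = np.asarray(positions, dtype=float)
    total = f.sum(axis=1)
    out = np.full((f.shape[0], 2), np.nan)
    ok = total > 0
    if np.any(ok):
        w = f[ok] / total[ok, None]
        out[ok] = np.einsum("nl,nlk->nk", w, pos[ok])
        # convex-hull (bounding-box) containment check per defined frame
        mask = f[ok] > 0
        for k in range(2):
            coords = np.where(mask, pos[ok, :, k], np.nan)
            lo = np.nanmin(coords, axis=1) - 1e-9
            hi = np.nanmax(coords, axis=1) + 1e-9
            if np.any(out[ok, k] < lo) or np.any(out[ok, k] > hi):
                raise AssertionError("COF left the support polygon bounding box")
    return out


def resample_markers(
    marker_time: np.ndarray, series: np.ndarray, force_time: np.ndarray
) -> np.ndarray:
    """Linear interpolation of a marker series onto force timestamps.

    Endpoints are clamped.  Raises if the time spans do not overlap.
    """
    marker_time = np.asarray(marker_time, dtype=float)
    force_time = np.asarray(force_time, dtype=float)
    if force_time[0] > marker_time[-1] or force_time[-1] < marker_time[0]:
        raise ValueError("marker and force time spans do not overlap")
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        return np.interp(force_time, marker_time, series)
    return np.column_stack(
        [np.interp(force_time, marker_time, series[:, j]) for j in range(series.shape[1])]
    )


def com_rom(com_window: np.ndarray) -> Dict[str, float]:
    """Per-stride COM translation range along each axis (m)."""
    rng = np.nanmax(com_window, axis=0) - np.nanmin(com_window, axis=0)
    return {"COM_ROM_x": float(rng[0]), "COM_ROM_y": float(rng[1]), "COM_ROM_z": float(rng[2])}


def cof_com_metrics(
    force_time: np.ndarray,
    cof_xy: np.ndarray,
    com_xy: np.ndarray,
    phases: Sequence[Tuple[str, float, float]],
    lame_side: str = "left",
) -> Dict[str, float]:
    """Maximal cranial COF-COM displacement toward each forelimb.

    For each side the window is the tripedal phase preceding that side's
    ipsilateral bipedal support plus the bipedal phase itself.  The reported
    asymmetry is left-side maximum minus right-side maximum (mirroring to
    the lame-side convention happens downstream); a missing phase leaves the
    side's value NaN.
    """
    dy = cof_xy[:, 1] - com_xy[:, 1]
    out: Dict[str, float] = {}
    for side, wanted in _SIDE_WINDOW_LABELS.items():
        vals: List[float] = []
        for label, a, b in phases:
            if label in wanted:
                m = (force_time >= a) & (force_time <= b)
                seg = dy[m]
                seg = seg[~np.isnan(seg)]
                if seg.size:
                    vals.append(float(seg.max()))
        out[f"COF_cranial_max_{side}"] = max(vals) if vals else np.nan
    left = out["COF_cranial_max_left"]
    right = out["COF_cranial_max_right"]
    out["COF_asym"] = left - right
    return out
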