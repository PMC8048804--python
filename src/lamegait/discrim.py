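"""Per-horse Youden-index discrimination, heat-map tables, trial-side
selection and left-lame mirroring.

Sensitivity/specificity of each variable are computed per horse using all
strides of that horse's baseline and induced conditions: candidate cutoffs
are midpoints between consecutive sorted unique pooled values, both
classification directions are considered, and the cutoff maximising
Youden's J = sensitivity + specificity - 1 is kept (ties broken toward the
cutoff nearest the pooled median, then toward direction 'greater').
Group-level summaries use the median across horses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: variables whose sign encodes side; negated when mirroring right-limb inductions
SIGNED_VARIABLES_PREFIXES = ("MinDiff", "RUD", "RDD", "COF_asym")

_LIMB_ROLE = {
    "left": {"LF": "lame", "RF": "contra", "LH": "ipsi", "RH": "diag"},
    "right": {"RF": "lame", "LF": "contra", "RH": "ipsi", "LH": "diag"},
}
_SIDE_ROLE = {
    "left": {"left": "lame", "right": "contra"},
    "right": {"right": "lame", "left": "contra"},
}
#: support-phase mirror for right-side inductions (1<->5, 2<->6, 3<->7, 4<->8)
_SUPP_MIRROR = {"1": "5", "2": "6", "3": "7", "4": "8",
                "5": "1", "6": "2", "7": "3", "8": "4"}


@dataclass
class DiscriminationCell:
    horse_id: str
    variable: str
    sensitivity: float
    specificity: float
    cutoff: float
    direction: str  # 'greater' | 'less'
    youden_j: float
    n_baseline: int
    n_lame: int


def youden(
    baseline: Sequence[float],
    lame: Sequence[float],
    horse_id: str = "",
    variable: str = "",
) -> DiscriminationCell:
    """Optimal-cutoff sensitivity/specificity of one variable for one horse.

    'greater' classifies a stride as lame when value > cutoff; 'less' when
    value < cutoff.  Equivalent to maximising the two-sample Kolmogorov
    distance between the baseline and lame empirical distributions.
    """
    b = np.asarray(baseline, dtype=float)
    l = np.asarray(lame, dtype=float)
    b = b[~np.isnan(b)]
    l = l[~np.isnan(l)]
    if b.size < 2 or l.size < 2:
        raise ValueError("youden requires >= 2 values per condition")
    pooled = np.concatenate([b, l])
    uniq = np.unique(pooled)
    if uniq.size == 1:
        cuts = np.array([uniq[0]])
    else:
        cuts = 0.5 * (uniq[:-1] + uniq[1:])
    med = np.median(pooled)

    best: Optional[Tuple[float, float, float, float, str]] = None
    for c in cuts:
        for direction in ("greater", "less"):
            if direction == "greater":
                sens = np.mean(l > c)
                spec = np.mean(b <= c)
            else:
                sens = np.mean(l < c)
                spec = np.mean(b >= c)
            j = sens + spec - 1.0
            if best is None:
                best = (j, sens, spec, c, direction)
                continue
            jb = best[0]
            if j > jb + 1e-12:
                best = (j, sens, spec, c, direction)
            elif abs(j - jb) <= 1e-12:
                # ties: cutoff nearest the pooled median, then 'greater'
                d_new, d_old = abs(c - med), abs(best[3] - med)
                if d_new < d_old - 1e-12 or (
                    abs(d_new - d_old) <= 1e-12
                    and direction == "greater"
                    and best[4] == "less"
                ):
                    best = (j, sens, spec, c, direction)
    j, sens, spec, cut, direction = best
    return DiscriminationCell(
        horse_id=horse_id,
        variable=variable,
        sensitivity=float(sens),
        specificity=float(spec),
        cutoff=float(cut),
        direction=direction,
        youden_j=float(j),
        n_baseline=int(b.size),
        n_lame=int(l.size),
    )


def youden_table(strides: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    """One DiscriminationCell per horse x variable from a long stride table."""
    rows = []
    for (horse, var), grp in strides[strides["variable"].isin(variables)].groupby(
        ["horse_id", "variable"], sort=True
    ):
        b = grp.loc[grp["condition"] == "baseline", "value"].to_numpy()
        l = grp.loc[grp["condition"] == "lame", "value"].to_numpy()
        b, l = b[~np.isnan(b)], l[~np.isnan(l)]
        if b.size < 2 or l.size < 2:
            logger.info("skipping %s/%s: insufficient strides", horse, var)
            continue
        cell = youden(b, l, horse_id=horse, variable=var)
        rows.append(cell.__dict__)
    return pd.DataFrame(rows)


def heatmap_table(cells: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format heat-map grid plus per-variable group medians.

    Returns (grid, summary); the summary holds median sensitivity,
    specificity and J per variable, ranked by median J (descending).
    """
    grid = cells.sort_values(["variable", "horse_id"]).reset_index(drop=True)
    summary = (
        cells.groupby("variable")
        .agg(
            median_sens=("sensitivity", "median"),
            median_spec=("specificity", "median"),
            median_J=("youden_j", "median"),
            n_horses=("horse_id", "nunique"),
        )
        .sort_values("median_J", ascending=False)
        .reset_index()
    )
    return grid, summary


def select_induction_side(
    left: Optional[Dict[str, float]],
    right: Optional[Dict[str, float]],
    equivalence_band: float = 0.05,
) -> str:
    """Choose the induction trial to analyse: left or right.

    Each argument summarises one trot induction: ``min_diff`` (head MinDiff,
    m) and ``dfz_peak`` (front-limb peak-force difference, N/kg).  The side
    with larger |MinDiff| wins; within the relative equivalence band the
    larger |dFz_peak| decides; exact ties go to 'left'.  A missing side
    returns the other with a log note.
    """
    if left is None and right is None:
        raise ValueError("both induction trials missing")
    if left is None:
        logger.warning("left induction missing; using right")
        return "right"
    if right is None:
        logger.warning("right induction missing; using left")
        return "left"
    ml, mr = abs(left["min_diff"]), abs(right["min_diff"])
    ref = max(ml, mr)
    if ref > 0 and abs(ml - mr) > equivalence_band * ref:
        return "left" if ml > mr else "right"
    fl, fr = abs(left["dfz_peak"]), abs(right["dfz_peak"])
    if fl == fr:
        return "left"
    return "left" if fl > fr else "right"


def _mirror_name(variable: str, lame_side: str) -> Tuple[str, float]:
    """Map a limb/side-suffixed variable to lame-relative roles.

    Returns (new name, sign) where sign is -1 for signed symmetry variables
    of right-side inductions.
    """
    sign = 1.0
    name = variable
    limb_roles = _LIMB_ROLE[lame_side]
    side_roles = _SIDE_ROLE[lame_side]
    for limb, role in limb_roles.items():
        if name.endswith(f"_{limb}"):
            name = name[: -(len(limb) + 1)] + f"_{role}"
            break
    else:
        for side, role in side_roles.items():
            if name.endswith(f"_{side}"):
                name = name[: -(len(side) + 1)] + f"_{role}"
                break
        else:
            if name.startswith("supp") and lame_side == "right":
                name = "supp" + _SUPP_MIRROR.get(name[4:], name[4:])
    if lame_side == "right" and any(
        variable.startswith(p) for p in SIGNED_VARIABLES_PREFIXES
    ):
        sign = -1.0
    return name, sign


def mirror_right(records: pd.DataFrame, lame_side: str) -> pd.DataFrame:
    """Express stride records of one horse in the left-lame convention.

    Limb-suffixed variables are relabelled to lame/contra/ipsi/diag roles,
    side-suffixed variables to lame/contra, support phases mirrored, and
    signed symmetry variables multiplied by -1 for right-side inductions.
    Applying the mirror twice is the identity on left-side data.
    """
    if lame_side not in ("left", "right"):
        raise ValueError(f"lame_side must be 'left' or 'right', got {lame_side!r}")
    out = records.copy()
    mapped = [_mirror_name(v, lame_side) for v in out["variable"]]
    out["variable"] = [m[0] for m in mapped]
    out["value"] = out["value"].to_numpy() * np.array([m[1] for m in mapped])
    return out
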