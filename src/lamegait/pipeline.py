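"""End-to-end stride-parameter extraction and cohort orchestration.

``extract_trial`` turns one trial into a long-format table of per-stride
variables (temporal, kinetic, kinematic, COM/COF); ``extract_cohort`` runs a
whole cohort and mirrors every horse's records into the left-lame
convention; ``percent_change_study`` is the standard baseline-vs-lame
experiment: generate a cohort, extract, mirror, and fit the mixed model per
variable.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._signal import lowpass
from .comcof import cof, cof_com_metrics, com_proxy, com_rom, resample_markers
from .config import ExtractionConfig, LIMBS, NoiseConfig, Trial
from .discrim import mirror_right
from .events import (
    StrideEvents,
    detect_events,
    support_phase_percentages,
    support_phases,
    temporal_parameters,
)
from .kinematics import (
    _refined_extrema,
    fetlock_angle,
    fetlock_peak_fraction,
    limb_angle,
    stride_limb_kinematics,
    vertical_symmetry,
)
from .kinetics import kinetic_parameters
from .stats import model_table
from .synthgen import generate_cohort, induction_sides

logger = logging.getLogger(__name__)

UNITS: Dict[str, str] = {
    "SD": "s", "StD_abs": "s", "StD_rel": "1", "StpDi": "s", "StpDc": "s", "TAP": "s",
    "supp": "%", "Fz_peak1": "N/kg", "Fz_peak2": "N/kg", "Fz_dip": "N/kg",
    "Fz_peak": "N/kg", "t_Fz_peak1": "%", "Iz": "N.s/kg", "dFz_load": "N/kg/s",
    "dFz_unload": "N/kg/s", "MinDiff": "m", "RUD": "m", "RDD": "m", "ROMz": "m",
    "Prot_max": "deg", "Ret_max": "deg", "ProtH": "m", "Prot_speed": "m/s",
    "A_fetlock": "deg", "StL": "m", "COM_ROM_x": "m", "COM_ROM_y": "m",
    "COM_ROM_z": "m", "COF_cranial_max": "m", "COF_asym": "m",
}


def units_of(variable: str) -> str:
    for prefix, u in UNITS.items():
        if variable == prefix or variable.startswith(prefix + "_") or (
            prefix == "supp" and variable.startswith("supp")
        ):
            return u
    return "1"


def _stance_in_window(
    events: StrideEvents, limb: str, window: Tuple[float, float]
) -> Optional[Tuple[float, float]]:
    tol = 0.1 * (window[1] - window[0])  # phase-0 limbs jitter across the boundary
    for on, off in events.stances[limb]:
        if window[0] - tol <= on < window[1] - tol:
            return (on, off)
    return None


def _swing_after(
    events: StrideEvents, limb: str, stance: Tuple[float, float]
) -> Optional[Tuple[float, float]]:
    ons = events.ons(limb)
    nxt = ons[ons > stance[0] + 1e-9]
    if nxt.size == 0:
        return None
    return (stance[1], float(nxt[0]))


def extract_trial(
    trial: Trial, config: ExtractionConfig = ExtractionConfig()
) -> pd.DataFrame:
    """All per-stride parameters of one trial as long-format records."""
    ev = detect_events(trial.forces, trial.force_rate, trial.body_mass, config)
    windows = ev.stride_windows
    t_m = trial.marker_time
    t_f = trial.force_time
    mrate = trial.marker_rate

    # landmark symmetry signals: filtered once, extrema shared across strides
    sym: Dict[str, tuple] = {}
    for lm in ("poll", "withers"):
        z = lowpass(trial.markers[lm][:, 2], mrate, config.marker_lowpass_hz)
        sym[lm] = (z, _refined_extrema(t_m, z))

    # limb angle series from filtered markers; raw hoof for swing speed
    ang: Dict[str, np.ndarray] = {}
    hyp: Dict[str, np.ndarray] = {}
    hoof_raw: Dict[str, np.ndarray] = {}
    for limb in LIMBS:
        piv = lowpass(trial.markers[f"pivot_{limb}"], mrate, config.marker_lowpass_hz)
        hoof_f = lowpass(trial.markers[f"hoof_{limb}"], mrate, config.marker_lowpass_hz)
        ang[limb] = limb_angle(piv, hoof_f)
        # raw markers: the peak refinement averages white noise, whereas
        # pre-filtered noise is correlated across the fit window and biases it
        hyp[limb] = fetlock_angle(
            trial.markers[f"prox_{limb}"],
            trial.markers[f"fetlock_{limb}"],
            trial.markers[f"hoof_{limb}"],
        )
        hoof_raw[limb] = trial.markers[f"hoof_{limb}"]
    fet_frac = {
        limb: fetlock_peak_fraction(t_m, hyp[limb], ev.stances[limb]) for limb in LIMBS
    }

    # COM at marker rate (filtered) and COF at force rate with stance-gated forces
    com_m = com_proxy(
        lowpass(trial.markers["sternum"], mrate, config.marker_lowpass_hz),
        lowpass(trial.markers["L3"], mrate, config.marker_lowpass_hz),
        config.com_weight,
    )
    gated = np.zeros_like(trial.forces)
    for j, limb in enumerate(LIMBS):
        for on, off in ev.stances[limb]:
            i0, i1 = np.searchsorted(t_f, [on, off])
            gated[i0:i1, j] = np.clip(trial.forces[i0:i1, j], 0.0, None)
    hoof_xy_f = np.stack(
        [resample_markers(t_m, hoof_raw[limb][:, :2], t_f) for limb in LIMBS], axis=1
    )
    cof_xy = cof(gated, hoof_xy_f)
    com_f = resample_markers(t_m, com_m[:, :2], t_f)

    rows: List[dict] = []

    def emit(stride: int, name: str, value: float) -> None:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return
        rows.append(
            {
                "horse_id": trial.horse_id,
                "gait": trial.gait,
                "condition": trial.condition,
                "stride_index": stride,
                "variable": name,
                "value": float(value),
                "units": units_of(name),
            }
        )

    for i, window in enumerate(windows):
        temporal = temporal_parameters(ev, window, trial.gait)
        if temporal is None:
            logger.info("stride %d flagged incomplete; excluded", i)
            continue
        for k, v in temporal.items():
            emit(i, k, v)

        phases = support_phases(ev, window, trial.gait)
        for label, pct in support_phase_percentages(phases, window).items():
            emit(i, f"supp{label}" if label[0].isdigit() else f"supp_{label}", pct)

        for j, limb in enumerate(LIMBS):
            stance = _stance_in_window(ev, limb, window)
            if stance is None:
                continue
            kin = kinetic_parameters(
                trial.forces[:, j], stance, trial.body_mass, trial.force_rate,
                trial.gait, config,
            )
            for k, v in kin.items():
                if k != "monophasic":
                    emit(i, f"{k}_{limb}", v)

            swing = _swing_after(ev, limb, stance)
            limb_kin = stride_limb_kinematics(
                t_m, ang[limb], hyp[limb], hoof_raw[limb], stance, swing,
                trial.belt_speed, mrate, config, fetlock_peak_frac=fet_frac[limb],
            )
            for k, v in limb_kin.items():
                emit(i, f"{k}_{limb}", v)

        split_ons = ev.ons("RF")
        split = split_ons[(split_ons > window[0]) & (split_ons < window[1])]
        if split.size:
            for lm, (z, ext) in sym.items():
                res = vertical_symmetry(
                    t_m, z, window, float(split[0]), mrate, config, _extrema=ext
                )
                if res is not None:
                    for k, v in res.items():
                        emit(i, f"{k}_{lm}", v)

        m_win = (t_m >= window[0]) & (t_m <= window[1])
        if m_win.sum() >= 4:
            for k, v in com_rom(com_m[m_win]).items():
                emit(i, k, v)
        if trial.gait == "walk":
            metrics = cof_com_metrics(t_f, cof_xy, com_f, phases)
            for k, v in metrics.items():
                emit(i, k, v)

    return pd.DataFrame(
        rows,
        columns=["horse_id", "gait", "condition", "stride_index", "variable", "value", "units"],
    )


def extract_cohort(
    trials: Sequence[Trial],
    config: ExtractionConfig = ExtractionConfig(),
    mirror: bool = True,
    sides: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Extract all trials; optionally mirror to the left-lame convention.

    ``sides`` maps horse_id to induction side; by default it is inferred
    from the cohort's lame trials (baseline trials of a horse are mirrored
    with the same side as its induction, as in a paired design).
    """
    if sides is None:
        sides = induction_sides(trials)
    parts = []
    for trial in trials:
        df = extract_trial(trial, config)
        if df.empty:
            continue
        if mirror:
            df = mirror_right(df, sides.get(trial.horse_id, "left"))
        parts.append(df)
    if not parts:
        return pd.DataFrame(
            columns=["horse_id", "gait", "condition", "stride_index", "variable", "value", "units"]
        )
    return pd.concat(parts, ignore_index=True)


def percent_change_study(
    gait: str,
    profile,
    n_horses: int = 10,
    seed: int = 1,
    duration: float = 20.0,
    noise: NoiseConfig = NoiseConfig(),
    config: ExtractionConfig = ExtractionConfig(),
    variables: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a paired cohort, extract strides and fit per-variable models.

    Returns (strides, models); ``models.percent_change`` holds the
    mixed-model least-square-mean percent change of each variable.
    """
    trials = generate_cohort(
        n_horses, gait, profile=profile, seed=seed, duration=duration, noise=noise
    )
    strides = extract_cohort(trials, config)
    models = model_table(strides, variables=variables, gait=gait)
    return strides, models
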