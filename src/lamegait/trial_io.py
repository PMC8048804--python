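"""Trial bundles and result tables on disk.

A trial bundle is a directory with three plain-text files:

* ``metadata.json`` — scalar fields (horse, gait, condition, lame side,
  body mass, belt speed, rates, duration, seed) and, for synthetic trials,
  the ground-truth events;
* ``forces.csv`` — columns time_s, LF_N, RF_N, LH_N, RH_N;
* ``markers.csv`` — columns time_s and <marker>_{x,y,z}_m.

Round-trips are lossless to 1e-6 N / 1e-6 m.  Result tables are long-format
CSV with deterministic column order and row sort, so identical data always
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .config import LIMBS, Trial, marker_names


class TrialFormatError(ValueError):
    """A trial bundle or result table violates the on-disk format."""


RESULT_COLUMNS = ["horse_id", "gait", "condition", "stride_index", "variable", "value", "units"]
_FLOAT_FMT = "%.6f"


def write_trial(trial: Trial, path: str | Path) -> Path:
    """Write a trial bundle; returns the bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "horse_id": trial.horse_id,
        "gait": trial.gait,
        "condition": trial.condition,
        "lame_side": trial.lame_side,
        "body_mass_kg": trial.body_mass,
        "belt_speed_m_s": trial.belt_speed,
        "force_rate_hz": trial.force_rate,
        "marker_rate_hz": trial.marker_rate,
        "duration_s": trial.duration,
        "seed": trial.seed,
        "ground_truth_events": (
            {limb: [[round(a, 9), round(b, 9)] for a, b in ev]
             for limb, ev in trial.ground_truth.items()}
            if trial.ground_truth is not None
            else None
        ),
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))

    t_f = trial.force_time
    forces = pd.DataFrame({"time_s": t_f})
    for j, limb in enumerate(LIMBS):
        forces[f"{limb}_N"] = trial.forces[:, j]
    forces.to_csv(path / "forces.csv", index=False, float_format=_FLOAT_FMT)

    t_m = trial.marker_time
    markers = pd.DataFrame({"time_s": t_m})
    for name in marker_names():
        arr = trial.markers[name]
        for k, ax in enumerate("xyz"):
            markers[f"{name}_{ax}_m"] = arr[:, k]
    markers.to_csv(path / "markers.csv", index=False, float_format=_FLOAT_FMT)
    return path


def _require_columns(df: pd.DataFrame, cols: List[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{fname}: missing column(s) {missing}")


def _check_time(df: pd.DataFrame, fname: str) -> None:
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise TrialFormatError(f"{fname}: time_s not strictly increasing")


def read_trial(path: str | Path) -> Trial:
    """Read a trial bundle written by :func:`write_trial`."""
    path = Path(path)
    for fname in ("metadata.json", "forces.csv", "markers.csv"):
        if not (path / fname).exists():
            raise TrialFormatError(f"bundle {path}: missing {fname}")
    meta = json.loads((path / "metadata.json").read_text())

    forces_df = pd.read_csv(path / "forces.csv")
    _require_columns(forces_df, ["time_s"] + [f"{l}_N" for l in LIMBS], "forces.csv")
    _check_time(forces_df, "forces.csv")
    forces = forces_df[[f"{l}_N" for l in LIMBS]].to_numpy()

    markers_df = pd.read_csv(path / "markers.csv")
    names = marker_names()
    cols = ["time_s"] + [f"{n}_{ax}_m" for n in names for ax in "xyz"]
    _require_columns(markers_df, cols, "markers.csv")
    _check_time(markers_df, "markers.csv")
    markers: Dict[str, np.ndarray] = {}
    for n in names:
        markers[n] = markers_df[[f"{n}_{ax}_m" for ax in "xyz"]].to_numpy()

    gt = meta.get("ground_truth_events")
    ground_truth = (
        {limb: [tuple(ev) for ev in evs] for limb, evs in gt.items()} if gt else None
    )
    return Trial(
        horse_id=meta["horse_id"],
        gait=meta["gait"],
        condition=meta["condition"],
        lame_side=meta["lame_side"],
        body_mass=meta["body_mass_kg"],
        belt_speed=meta["belt_speed_m_s"],
        force_rate=meta["force_rate_hz"],
        marker_rate=meta["marker_rate_hz"],
        duration=meta["duration_s"],
        forces=forces,
        markers=markers,
        ground_truth=ground_truth,
        seed=meta.get("seed"),
    )


def write_results(records: pd.DataFrame, path: str | Path) -> Path:
    """Write a long-format result table with deterministic order.

    Rows are sorted by (horse, gait, condition, stride, variable); the key
    must be unique and units non-empty.
    """
    path = Path(path)
    df = records.copy()
    _require_columns(df, RESULT_COLUMNS, path.name)
    if (df["units"].astype(str).str.len() == 0).any():
        raise TrialFormatError(f"{path.name}: empty units")
    key = ["horse_id", "gait", "condition", "stride_index", "variable"]
    if df.duplicated(subset=key).any():
        dup = df[df.duplicated(subset=key)].iloc[0]
        raise TrialFormatError(
            f"{path.name}: duplicate record key {tuple(dup[k] for k in key)}"
        )
    df = df[RESULT_COLUMNS].sort_values(key, kind="mergesort").reset_index(drop=True)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, RESULT_COLUMNS, Path(path).name)
    return df
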