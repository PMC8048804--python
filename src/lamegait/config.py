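"""Domain types and configuration for synthetic treadmill gait trials.

Coordinate frame (treadmill): x lateral (right positive), y cranial
(positive), z up; origin at the treadmill centre.  Hooves move in -y during
stance at belt speed.

Units are SI throughout: seconds, metres, kilograms, newtons.  Force shapes
are expressed in N/kg (normalised to body mass); the generator multiplies by
body mass when synthesising raw force traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

LIMBS: Tuple[str, ...] = ("LF", "RF", "LH", "RH")
FORELIMBS: Tuple[str, str] = ("LF", "RF")
HINDLIMBS: Tuple[str, str] = ("LH", "RH")

#: diagonal partner of each limb
DIAGONAL: Dict[str, str] = {"LF": "RH", "RF": "LH", "LH": "RF", "RH": "LF"}
#: contralateral partner (same girdle)
CONTRALATERAL: Dict[str, str] = {"LF": "RF", "RF": "LF", "LH": "RH", "RH": "LH"}
#: ipsilateral partner (same side, other girdle)
IPSILATERAL: Dict[str, str] = {"LF": "LH", "RF": "RH", "LH": "LF", "RH": "RF"}

GRAVITY = 9.81  # N/kg

BODY_LANDMARKS: Tuple[str, ...] = ("poll", "withers", "sternum", "L3")


class ConfigurationError(ValueError):
    """Raised when generator or pipeline configuration is inconsistent."""


@dataclass
class GaitTiming:
    """Stride timing of a steady-state gait.

    ``footfall_phase`` holds the hoof-on instant of each limb as a fraction of
    the stride, with the left forelimb as reference 0.  ``diagonal_dissociation``
    is the signed time by which the forelimb of a diagonal pair leads its
    diagonal hindlimb (forelimb-first positive); it shifts the hindlimb phases
    at trot.
    """

    stride_duration: float
    duty_factor: Dict[str, float]
    footfall_phase: Dict[str, float]
    diagonal_dissociation: float = 0.0

    def __post_init__(self) -> None:
        if self.stride_duration <= 0:
            raise ConfigurationError("stride_duration must be positive")
        for limb in LIMBS:
            d = self.duty_factor[limb]
            if not 0.0 < d < 1.0:
                raise ConfigurationError(f"duty_factor[{limb}]={d} outside (0,1)")
            p = self.footfall_phase[limb]
            if not 0.0 <= p < 1.0:
                raise ConfigurationError(f"footfall_phase[{limb}]={p} outside [0,1)")


@dataclass
class StanceForceShape:
    """Shape of the vertical ground-reaction-force curve over one stance.

    Walk stances are double-peaked: control points (t_peak1, peak1),
    (t_dip, dip), (t_peak2, peak2) in fractions of stance / N/kg.  Trot
    stances are single-peaked: ``peak * sin(pi*s)**q``.
    """

    gait: str
    # walk fields
    peak1: float = 0.0
    dip: float = 0.0
    peak2: float = 0.0
    t_peak1: float = 0.3
    t_dip: float = 0.5
    t_peak2: float = 0.75
    # trot fields
    peak: float = 0.0
    q: float = 1.12

    def __post_init__(self) -> None:
        if self.gait == "walk":
            if not (0.0 < self.t_peak1 < self.t_dip < self.t_peak2 < 1.0):
                raise ConfigurationError(
                    "walk control points must satisfy 0 < t_peak1 < t_dip < t_peak2 < 1"
                )
            if self.dip >= min(self.peak1, self.peak2):
                raise ConfigurationError("walk dip must lie below both peaks")
            if min(self.peak1, self.peak2, self.dip) < 0:
                raise ConfigurationError("force control points must be >= 0")
        elif self.gait == "trot":
            if self.peak < 0 or self.q <= 0:
                raise ConfigurationError("trot peak must be >= 0 and q > 0")
        else:
            raise ConfigurationError(f"unknown gait {self.gait!r}")


@dataclass
class LandmarkMotion:
    """Periodic motion of one upper-body landmark.

    Vertical position: z(t) = mean_z + a2*sin(2*theta + phi2) + a1*sin(theta + phi1)
    with theta the stride phase in radians (2*pi per stride).  The a2 term is
    the symmetric twice-per-stride oscillation; a1 is the once-per-stride
    asymmetry component injected under lameness (a1 = 0 for a perfectly
    symmetric signal).  Lateral (x) and fore-aft (y) components are
    once- and twice-per-stride sinusoids respectively.
    """

    mean_y: float
    mean_z: float
    a2: float
    phi2: float = 0.0
    a1: float = 0.0
    phi1: float = 0.0
    lateral_amp: float = 0.0
    lateral_phase: float = 0.0
    foreaft_amp: float = 0.0
    foreaft_phase: float = 0.0

    def __post_init__(self) -> None:
        if min(self.a2, self.a1, self.lateral_amp, self.foreaft_amp) < 0:
            raise ConfigurationError("motion amplitudes must be >= 0")


@dataclass
class UpperBodyMotion:
    landmarks: Dict[str, LandmarkMotion]

    def __post_init__(self) -> None:
        missing = set(BODY_LANDMARKS) - set(self.landmarks)
        if missing:
            raise ConfigurationError(f"missing landmark motions: {sorted(missing)}")


@dataclass
class LimbGeometry:
    """Minimal marker geometry of one limb.

    The limb is reduced to four markers: hoof, fetlock, proximal joint
    (carpus/tarsus) and the upper-limb pivot (scapula/hip).  The fetlock
    extension angle during stance is driven proportionally to the normalised
    vertical force with ``fetlock_gain`` degrees per N/kg.
    ``swing_exponent`` shapes the swing velocity profile v(u) ~ (u(1-u))**p;
    larger p concentrates the displacement into a faster mid-swing peak.
    """

    hoof_x: float
    hoof_home_y: float
    hoof_z: float = 0.05
    pivot_y: float = 0.45
    pivot_z: float = 1.30
    lift: float = 0.10
    swing_exponent: float = 1.0
    fetlock_gain: float = 3.0  # deg per N/kg
    seg_hoof_fetlock: float = 0.10
    seg_fetlock_prox: float = 0.30


@dataclass
class NoiseConfig:
    """Measurement noise and physiological stride-to-stride variability."""

    sigma_force: float = 0.05  # N/kg, additive white noise on force traces
    sigma_marker: float = 0.001  # m, additive white noise on marker positions
    stride_cv: float = 0.02  # multiplicative jitter CV on stride timing/shape
    horse_cv: float = 0.03  # inter-horse spread on baseline parameters

    @classmethod
    def none(cls) -> "NoiseConfig":
        return cls(sigma_force=0.0, sigma_marker=0.0, stride_cv=0.0, horse_cv=0.0)


@dataclass
class HorseParams:
    """Complete parameterisation of one horse at one gait and condition."""

    horse_id: str
    gait: str
    body_mass: float
    belt_speed: float
    timing: GaitTiming
    shapes: Dict[str, StanceForceShape]
    motion: UpperBodyMotion
    limbs: Dict[str, LimbGeometry]


@dataclass
class Trial:
    """One treadmill recording: forces, markers and metadata.

    ``forces`` is (n_force, 4) in newtons with columns ordered as LIMBS.
    ``markers`` maps marker name to an (n_marker, 3) array of x, y, z in
    metres.  ``ground_truth`` (generator output only) maps limb to the exact
    hoof-on/hoof-off times of every complete stance within the trial.
    """

    horse_id: str
    gait: str
    condition: str
    lame_side: str  # 'left' | 'right' | 'none'
    body_mass: float
    belt_speed: float
    force_rate: float
    marker_rate: float
    duration: float
    forces: np.ndarray
    markers: Dict[str, np.ndarray]
    ground_truth: Optional[Dict[str, List[Tuple[float, float]]]] = None
    seed: Optional[int] = None

    @property
    def force_time(self) -> np.ndarray:
        return np.arange(self.forces.shape[0]) / self.force_rate

    @property
    def marker_time(self) -> np.ndarray:
        n = next(iter(self.markers.values())).shape[0]
        return np.arange(n) / self.marker_rate


@dataclass
class ExtractionConfig:
    """Tunables of the analysis pipeline (all config keys; see docs/methods.md)."""

    stance_threshold_N: float = 50.0
    min_stance_s: float = 0.100
    merge_gap_s: float = 0.020
    force_lowpass_hz: float = 30.0
    marker_lowpass_hz: float = 10.0
    speed_lowpass_hz: Optional[float] = None  # swing speed: no smoothing by default
    chord_lo: float = 0.20
    chord_hi: float = 0.80
    com_weight: float = 0.6  # COM proxy weight toward the sternum
    mindiff_equivalence: float = 0.05  # trial-side selection equivalence band


def marker_names() -> List[str]:
    """Canonical marker set of a trial (order fixed for on-disk tables)."""
    names = list(BODY_LANDMARKS)
    for limb in LIMBS:
        for part in ("hoof", "fetlock", "prox", "pivot"):
            names.append(f"{part}_{limb}")
    return names


def clone(obj, **changes):
    """Dataclass deep-ish copy helper used by the effect-profile realization."""
    import copy

    new = copy.deepcopy(obj)
    for k, v in changes.items():
        setattr(new, k, v)
    return new
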