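"""Lameness effect profiles and their realization as generator parameters.

A :class:`LamenessEffectProfile` maps (parameter name, limb role) to a
multiplicative factor describing how a moderate supporting forelimb lameness
changes that parameter relative to baseline.  The presets ``walk_moderate``
and ``trot_moderate`` encode the group-level percentage changes measured for
induced forelimb lameness on a treadmill (e.g. lame-limb vertical impulse
x0.949 at walk, peak force x0.823 at trot, head ROMz x1.505 at trot).

Encoding is by *calibration*: :func:`apply_profile` solves the generator's
internal waveform knobs (dip height for vertical impulse, peak-timing
fractions for chord loading rates, the trot shape exponent, the swing
velocity exponent, the fetlock force-angle gain, the once-per-stride head
amplitude, the hoof home position) so that the noise-free analytic
measurement of each targeted parameter changes by exactly the encoded
factor.  Untargeted parameters keep their baseline values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .config import (
    ConfigurationError,
    GaitTiming,
    HorseParams,
    LimbGeometry,
    clone,
)
from .waveforms import (
    swing_displacement,
    swing_lift,
    unit_stance_mean,
    vertical_rom,
    walk_mean_affine_in_dip,
)

ROLES = ("lame_fore", "contralateral_fore", "ipsilateral_hind", "diagonal_hind", "global")

KNOWN_PARAMETERS = frozenset(
    {
        "SD",
        "StD_rel",
        "t_Fz_peak1",
        "Fz_peak1",
        "Fz_peak2",
        "Fz_peak",
        "Iz",
        "dFz_load",
        "dFz_unload",
        "A_fetlock",
        "Prot_speed",
        "Prot_max",
        "Ret_max",
        "ProtH",
        "ROMz_poll",
    }
)

#: phase of the injected once-per-stride head asymmetry; aligned so that it
#: maximally differentiates the two half-cycle minima of the default a2 term
ASYMMETRY_PHASE = 3.0 * math.pi / 4.0


@dataclass
class LamenessEffectProfile:
    """Multiplicative per-parameter, per-limb-role effect sizes.

    ``factors`` maps (parameter, role) -> factor (> 0).  ``head_a1`` holds
    additive once-per-stride vertical amplitudes (m) injected into upper-body
    landmarks.  The identity profile (no factors, no injections) leaves
    generated trials statistically identical to baseline.
    """

    name: str = "baseline"
    factors: Dict[Tuple[str, str], float] = field(default_factory=dict)
    head_a1: Dict[str, float] = field(default_factory=dict)
    head_a1_phase: float = ASYMMETRY_PHASE

    def __post_init__(self) -> None:
        for (param, role), f in self.factors.items():
            if param not in KNOWN_PARAMETERS:
                raise ConfigurationError(f"unknown effect parameter {param!r}")
            if role not in ROLES:
                raise ConfigurationError(f"unknown limb role {role!r}")
            if not f > 0:
                raise ConfigurationError(f"factor for ({param}, {role}) must be > 0")

    @property
    def is_identity(self) -> bool:
        return all(f == 1.0 for f in self.factors.values()) and all(
            a == 0.0 for a in self.head_a1.values()
        )

    def factor(self, param: str, role: str) -> float:
        """Combined factor for a parameter on the limb occupying ``role``."""
        f = self.factors.get((param, role), 1.0)
        f *= self.factors.get((param, "global"), 1.0) if role != "global" else 1.0
        return f


def role_map(lame_side: str) -> Dict[str, str]:
    """Limb occupying each role for a given induction side."""
    if lame_side == "left":
        return {
            "lame_fore": "LF",
            "contralateral_fore": "RF",
            "ipsilateral_hind": "LH",
            "diagonal_hind": "RH",
        }
    if lame_side == "right":
        return {
            "lame_fore": "RF",
            "contralateral_fore": "LF",
            "ipsilateral_hind": "RH",
            "diagonal_hind": "LH",
        }
    raise ConfigurationError(f"lame_side must be 'left' or 'right', got {lame_side!r}")


def _role_of(limb: str, roles: Dict[str, str]) -> str:
    for role, l in roles.items():
        if l == limb:
            return role
    raise ConfigurationError(f"limb {limb!r} has no role")


# ---------------------------------------------------------------------------
# presets: group-level percentage changes under moderate forelimb lameness
# ---------------------------------------------------------------------------

WALK_MODERATE = LamenessEffectProfile(
    name="walk_moderate",
    factors={
        ("SD", "global"): 1.0 - 0.0205,            # stride duration -2.05%
        ("StD_rel", "lame_fore"): 1.004,           # duty factor +0.4%
        ("StD_rel", "ipsilateral_hind"): 1.004,
        ("t_Fz_peak1", "lame_fore"): 1.084,        # first-peak delay +8.4%
        ("t_Fz_peak1", "ipsilateral_hind"): 1.084,
        ("t_Fz_peak1", "diagonal_hind"): 1.084,
        ("Fz_peak1", "lame_fore"): 1.0 - 0.019,    # -1.9%
        ("Fz_peak2", "lame_fore"): 1.0 - 0.061,    # -6.1%
        ("Fz_peak1", "diagonal_hind"): 1.048,      # +4.8%
        ("Iz", "lame_fore"): 1.0 - 0.051,          # vertical impulse -5.1%
        ("dFz_load", "contralateral_fore"): 1.165,   # +16.5%
        ("dFz_unload", "contralateral_fore"): 1.15,  # +15%
        ("A_fetlock", "lame_fore"): 1.0 - 0.033,   # fetlock hyperextension -3.3%
        ("Prot_speed", "lame_fore"): 1.0 - 0.046,  # swing limb speed -4.6%
        ("Prot_speed", "ipsilateral_hind"): 1.024,
        ("Prot_speed", "diagonal_hind"): 1.027,
        ("Ret_max", "lame_fore"): 1.0 - 0.026,     # max retraction -2.6%
        ("ProtH", "contralateral_fore"): 1.025,    # protraction height +2.5%
    },
    head_a1={"poll": 0.006, "withers": 0.0015},
)

TROT_MODERATE = LamenessEffectProfile(
    name="trot_moderate",
    factors={
        ("StD_rel", "lame_fore"): 1.055,           # duty factor +5.5% (both fronts)
        ("StD_rel", "contralateral_fore"): 1.055,
        ("Fz_peak", "lame_fore"): 1.0 - 0.177,     # peak force -17.7%
        ("Iz", "lame_fore"): 1.0 - 0.143,          # vertical impulse -14.3%
        ("ROMz_poll", "global"): 1.505,            # head vertical ROM +50.5%
        ("Prot_max", "lame_fore"): 1.016,          # +1.6%
        ("Ret_max", "lame_fore"): 1.0 - 0.028,     # -2.8%
        ("ProtH", "lame_fore"): 1.0 - 0.168,       # protraction height -16.8%
    },
    head_a1={"withers": 0.004},
)

BASELINE = LamenessEffectProfile(name="baseline")

PRESETS: Dict[str, LamenessEffectProfile] = {
    "baseline": BASELINE,
    "walk_moderate": WALK_MODERATE,
    "trot_moderate": TROT_MODERATE,
}


def get_profile(name: str) -> LamenessEffectProfile:
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown profile {name!r}; available: {sorted(PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# analytic measurement analogues used by the realization solves
# ---------------------------------------------------------------------------


def analytic_swing_peak_speed(
    timing: GaitTiming,
    geom: LimbGeometry,
    limb: str,
    belt_speed: float,
    marker_rate: float = 256.0,
) -> float:
    """Peak resultant hoof speed during swing, measured as the pipeline does.

    Samples the noise-free swing trajectory at the marker rate and takes the
    maximum central-difference resultant speed, so the solved swing exponent
    reproduces the target under the pipeline's own estimator.
    """
    stance = timing.duty_factor[limb] * timing.stride_duration
    t_swing = timing.stride_duration - stance
    travel = belt_speed * stance
    dt = 1.0 / marker_rate
    t = np.arange(0.0, t_swing + dt, dt)
    u = np.clip(t / t_swing, 0.0, 1.0)
    y = travel * swing_displacement(u, geom.swing_exponent)
    z = geom.lift * swing_lift(u)
    vy = np.gradient(y, dt)
    vz = np.gradient(z, dt)
    return float(np.max(np.hypot(vy, vz)))


def _limb_angles_deg(geom: LimbGeometry, travel: float, home_y: float) -> Tuple[float, float]:
    """(max protraction, max retraction) of the pivot->hoof segment, degrees."""
    h = geom.pivot_z - geom.hoof_z
    y_on = home_y + travel / 2.0
    y_off = home_y - travel / 2.0
    prot = math.degrees(math.atan2(y_on - geom.pivot_y, h))
    ret = math.degrees(math.atan2(y_off - geom.pivot_y, h))
    return prot, ret


# ---------------------------------------------------------------------------
# realization
# ---------------------------------------------------------------------------


def apply_profile(
    base: HorseParams,
    profile: LamenessEffectProfile,
    lame_side: str,
) -> HorseParams:
    """Realize an effect profile on a horse's baseline parameters.

    Returns a new :class:`HorseParams` whose noise-free analytic measurements
    differ from baseline by exactly the profile's factors.  The identity
    profile returns an equal copy of the input.
    """
    p = clone(base)
    if profile.is_identity:
        return p
    roles = role_map(lame_side)
    gait = base.gait

    # --- timing -----------------------------------------------------------
    f_sd = profile.factor("SD", "global")
    p.timing.stride_duration = base.timing.stride_duration * f_sd
    stance_ratio: Dict[str, float] = {}
    for limb in p.timing.duty_factor:
        role = _role_of(limb, roles)
        f_duty = profile.factor("StD_rel", role)
        p.timing.duty_factor[limb] = base.timing.duty_factor[limb] * f_duty
        stance_ratio[limb] = f_sd * f_duty

    # --- force shapes -----------------------------------------------------
    for limb, shape in p.shapes.items():
        role = _role_of(limb, roles)
        base_shape = base.shapes[limb]
        sr = stance_ratio[limb]
        if gait == "walk":
            f_p1 = profile.factor("Fz_peak1", role)
            f_p2 = profile.factor("Fz_peak2", role)
            shape.peak1 = base_shape.peak1 * f_p1
            shape.peak2 = base_shape.peak2 * f_p2

            f_t1 = profile.factor("t_Fz_peak1", role)
            f_load = profile.factor("dFz_load", role)
            if f_t1 != 1.0 and f_load != 1.0:
                raise ConfigurationError(
                    f"{limb}: t_Fz_peak1 and dFz_load cannot both be targeted"
                )
            if f_load != 1.0:
                # chord loading rate ~ peak1 / (t_peak1 * stance)
                f_t1 = f_p1 / (f_load * sr)
            shape.t_peak1 = base_shape.t_peak1 * f_t1

            f_unload = profile.factor("dFz_unload", role)
            if f_unload != 1.0:
                # chord unloading rate ~ peak2 / ((1 - t_peak2) * stance)
                fall = (1.0 - base_shape.t_peak2) * f_p2 / (f_unload * sr)
                shape.t_peak2 = 1.0 - fall
            if not (0.0 < shape.t_peak1 < shape.t_dip < shape.t_peak2 < 1.0):
                raise ConfigurationError(
                    f"{limb}: realized control points out of order "
                    f"(t_peak1={shape.t_peak1:.3f}, t_peak2={shape.t_peak2:.3f})"
                )

            f_iz = profile.factor("Iz", role)
            if f_iz != 1.0:
                m_base = unit_stance_mean(base_shape, "walk")
                m_target = f_iz * m_base / sr
                a, b = walk_mean_affine_in_dip(shape)
                dip = (m_target - a) / b
                if not 0.0 <= dip < min(shape.peak1, shape.peak2):
                    raise ConfigurationError(
                        f"{limb}: impulse factor {f_iz} requires dip {dip:.3f} N/kg "
                        f"outside [0, min(peaks))"
                    )
                shape.dip = dip
        else:  # trot
            f_pk = profile.factor("Fz_peak", role)
            shape.peak = base_shape.peak * f_pk
            f_iz = profile.factor("Iz", role)
            if f_iz != 1.0:
                m_base = unit_stance_mean(base_shape, "trot")
                m_target = f_iz * m_base / sr

                def _resid(q: float) -> float:
                    return unit_stance_mean(clone(shape, q=q), "trot") - m_target

                shape.q = brentq(_resid, 0.4, 5.0, xtol=1e-10)

    # --- fetlock gain -----------------------------------------------------
    for limb, geom in p.limbs.items():
        role = _role_of(limb, roles)
        f_fet = profile.factor("A_fetlock", role)
        if f_fet != 1.0:
            if gait == "walk":
                ratio = max(p.shapes[limb].peak1, p.shapes[limb].peak2) / max(
                    base.shapes[limb].peak1, base.shapes[limb].peak2
                )
            else:
                ratio = p.shapes[limb].peak / base.shapes[limb].peak
            geom.fetlock_gain = base.limbs[limb].fetlock_gain * f_fet / ratio

    # --- swing speed ------------------------------------------------------
    for limb, geom in p.limbs.items():
        role = _role_of(limb, roles)
        f_speed = profile.factor("Prot_speed", role)
        if f_speed != 1.0:
            target = f_speed * analytic_swing_peak_speed(
                base.timing, base.limbs[limb], limb, base.belt_speed
            )

            def _resid(q: float) -> float:
                return (
                    analytic_swing_peak_speed(
                        p.timing, clone(geom, swing_exponent=q), limb, p.belt_speed
                    )
                    - target
                )

            geom.swing_exponent = brentq(_resid, 0.05, 12.0, xtol=1e-9)

    # --- protraction / retraction / protraction height --------------------
    for limb, geom in p.limbs.items():
        role = _role_of(limb, roles)
        f_prot = profile.factor("Prot_max", role)
        f_ret = profile.factor("Ret_max", role)
        f_h = profile.factor("ProtH", role)
        base_geom = base.limbs[limb]
        travel0 = base.belt_speed * base.timing.duty_factor[limb] * base.timing.stride_duration
        travel1 = p.belt_speed * p.timing.duty_factor[limb] * p.timing.stride_duration
        if f_prot != 1.0 or f_ret != 1.0:
            prot0, ret0 = _limb_angles_deg(base_geom, travel0, base_geom.hoof_home_y)
            tp = math.tan(math.radians(prot0 * f_prot))
            tr = math.tan(math.radians(ret0 * f_ret))
            if f_prot != 1.0 and f_ret != 1.0:
                # two targets, two knobs: limb length and home position
                h1 = travel1 / (tp - tr)
                geom.pivot_z = geom.hoof_z + h1
            h1 = geom.pivot_z - geom.hoof_z
            if f_ret != 1.0:
                geom.hoof_home_y = geom.pivot_y + h1 * tr + travel1 / 2.0
            else:
                geom.hoof_home_y = geom.pivot_y + h1 * tp - travel1 / 2.0
        if f_h != 1.0:
            lift = f_h * (base_geom.hoof_z + base_geom.lift) - geom.hoof_z
            if lift <= 0:
                raise ConfigurationError(f"{limb}: ProtH factor {f_h} yields no lift")
            geom.lift = lift

    # --- upper-body asymmetry --------------------------------------------
    f_rom = profile.factor("ROMz_poll", "global")
    if f_rom != 1.0 and profile.head_a1.get("poll"):
        raise ConfigurationError("poll a1 injection and ROMz_poll target both given")
    for landmark, a1 in profile.head_a1.items():
        lm = p.motion.landmarks[landmark]
        lm.a1 = lm.a1 + a1
        lm.phi1 = profile.head_a1_phase
    if f_rom != 1.0:
        poll = p.motion.landmarks["poll"]
        target = f_rom * vertical_rom(base.motion.landmarks["poll"])
        poll.phi1 = profile.head_a1_phase

        def _resid(a1: float) -> float:
            return vertical_rom(clone(poll, a1=a1)) - target

        poll.a1 = brentq(_resid, 0.0, 8.0 * poll.a2, xtol=1e-12)

    return p
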