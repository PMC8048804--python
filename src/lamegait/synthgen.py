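"""Synthetic treadmill trial generator.

Generates per-limb vertical GRF traces at the force rate and a minimal
marker set at the marker rate, with exact ground-truth gait events, for a
cohort of horses at walk or trot under a configurable lameness effect
profile.  The generator defines the study conditions the pipeline is tested
against: 10 horses, 20 s trials, walk at ~1.68 m/s with a four-beat lateral
footfall sequence and double-peaked forelimb GRFz, trot at ~3.87 m/s with
diagonal pairs and single-peaked GRFz, and upper-body vertical oscillation
at twice the stride frequency with a once-per-stride asymmetry component
injected under lameness.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import (
    BODY_LANDMARKS,
    GRAVITY,
    ConfigurationError,
    GaitTiming,
    HorseParams,
    LandmarkMotion,
    LimbGeometry,
    LIMBS,
    NoiseConfig,
    StanceForceShape,
    Trial,
    UpperBodyMotion,
    clone,
)
from .profiles import LamenessEffectProfile, apply_profile, get_profile
from .waveforms import (
    grf_waveform,
    landmark_xyz,
    swing_displacement,
    swing_lift,
    unit_stance_mean,
)

WALK_SPEED_RANGE = (1.57, 1.79)  # m/s, cohort preferred-speed range
TROT_SPEED_RANGE = (3.78, 3.94)
BODY_MASS_RANGE = (480.0, 640.0)  # kg, adult Warmblood geldings

FORCE_RATE = 512.0
MARKER_RATE = 256.0


def default_params(
    gait: str,
    horse_id: str = "H00",
    body_mass: float = 560.0,
    belt_speed: Optional[float] = None,
) -> HorseParams:
    """Reference horse parameterisation for one gait (pre-calibration).

    Walk: stride 1.25 s, duty 0.625, lateral footfall sequence LH-LF-RH-RF at
    quarter phases.  Trot: stride 0.75 s, duty 0.45, diagonal pairs offset by
    half a stride.  Force-shape control points are design defaults chosen to
    match the qualitative double-peaked walk / single-peaked trot curves; the
    absolute levels are rescaled by :func:`calibrate_weight_support`.
    """
    if gait == "walk":
        belt = belt_speed if belt_speed is not None else 1.68
        timing = GaitTiming(
            stride_duration=1.25,
            duty_factor={l: 0.625 for l in LIMBS},
            footfall_phase={"LF": 0.0, "RH": 0.25, "RF": 0.5, "LH": 0.75},
        )
        fore = dict(peak1=6.3, dip=4.5, peak2=6.6, t_peak1=0.28, t_dip=0.50, t_peak2=0.75)
        hind = dict(peak1=5.04, dip=3.6, peak2=5.28, t_peak1=0.28, t_dip=0.50, t_peak2=0.75)
        shapes = {
            "LF": StanceForceShape("walk", **fore),
            "RF": StanceForceShape("walk", **fore),
            "LH": StanceForceShape("walk", **hind),
            "RH": StanceForceShape("walk", **hind),
        }
        motion = UpperBodyMotion(
            landmarks={
                "poll": LandmarkMotion(mean_y=1.30, mean_z=1.50, a2=0.020),
                "withers": LandmarkMotion(mean_y=0.40, mean_z=1.69, a2=0.012, phi2=math.pi),
                "sternum": LandmarkMotion(
                    mean_y=0.30, mean_z=1.05, a2=0.008, phi2=math.pi,
                    lateral_amp=0.025, foreaft_amp=0.008,
                ),
                "L3": LandmarkMotion(
                    mean_y=-0.50, mean_z=1.55, a2=0.010, phi2=math.pi,
                    lateral_amp=0.030, foreaft_amp=0.008,
                ),
            }
        )
    elif gait == "trot":
        belt = belt_speed if belt_speed is not None else 3.87
        timing = GaitTiming(
            stride_duration=0.75,
            duty_factor={l: 0.45 for l in LIMBS},
            footfall_phase={"LF": 0.0, "RH": 0.0, "RF": 0.5, "LH": 0.5},
        )
        fore = dict(peak=11.0, q=1.12)
        hind = dict(peak=8.8, q=1.12)
        shapes = {
            "LF": StanceForceShape("trot", **fore),
            "RF": StanceForceShape("trot", **fore),
            "LH": StanceForceShape("trot", **hind),
            "RH": StanceForceShape("trot", **hind),
        }
        motion = UpperBodyMotion(
            landmarks={
                "poll": LandmarkMotion(mean_y=1.30, mean_z=1.55, a2=0.030),
                "withers": LandmarkMotion(mean_y=0.40, mean_z=1.70, a2=0.025, phi2=math.pi),
                "sternum": LandmarkMotion(
                    mean_y=0.30, mean_z=1.06, a2=0.015, phi2=math.pi,
                    lateral_amp=0.008, foreaft_amp=0.008,
                ),
                "L3": LandmarkMotion(
                    mean_y=-0.50, mean_z=1.56, a2=0.018, phi2=math.pi,
                    lateral_amp=0.008, foreaft_amp=0.008,
                ),
            }
        )
    else:
        raise ConfigurationError(f"unknown gait {gait!r}")

    limbs = {
        "LF": LimbGeometry(hoof_x=-0.15, hoof_home_y=0.55, pivot_y=0.45, pivot_z=1.30, lift=0.10),
        "RF": LimbGeometry(hoof_x=0.15, hoof_home_y=0.55, pivot_y=0.45, pivot_z=1.30, lift=0.10),
        "LH": LimbGeometry(hoof_x=-0.18, hoof_home_y=-0.55, pivot_y=-0.45, pivot_z=1.05, lift=0.08),
        "RH": LimbGeometry(hoof_x=0.18, hoof_home_y=-0.55, pivot_y=-0.45, pivot_z=1.05, lift=0.08),
    }
    return HorseParams(
        horse_id=horse_id,
        gait=gait,
        body_mass=body_mass,
        belt_speed=belt,
        timing=timing,
        shapes=shapes,
        motion=motion,
        limbs=limbs,
    )


def calibrate_weight_support(params: HorseParams) -> HorseParams:
    """Rescale all force shapes so mean total normalised force equals g.

    Over an integer number of steady-state strides, each limb contributes
    ``duty_factor * unit_stance_mean`` to the mean whole-stride force per kg;
    the sum must equal g = 9.81 N/kg for a weight-supporting gait.
    """
    p = clone(params)
    total = sum(
        p.timing.duty_factor[l] * unit_stance_mean(p.shapes[l], p.gait) for l in LIMBS
    )
    scale = GRAVITY / total
    for shape in p.shapes.values():
        if p.gait == "walk":
            shape.peak1 *= scale
            shape.dip *= scale
            shape.peak2 *= scale
        else:
            shape.peak *= scale
    return p


def _lognormal(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative jitter with unit mean and coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


def jitter_horse(params: HorseParams, rng: np.random.Generator, cv: float) -> HorseParams:
    """Inter-horse variation: multiplicative spread on timing, force levels,
    motion amplitudes and fetlock gain (control-point fractions kept fixed)."""
    p = clone(params)
    p.timing.stride_duration *= float(_lognormal(rng, cv))
    for shape in p.shapes.values():
        f = float(_lognormal(rng, cv))
        if p.gait == "walk":
            shape.peak1 *= f
            shape.dip *= f
            shape.peak2 *= f
        else:
            shape.peak *= f
    for lm in p.motion.landmarks.values():
        lm.a2 *= float(_lognormal(rng, cv))
    for geom in p.limbs.values():
        geom.fetlock_gain *= float(_lognormal(rng, cv))
        geom.lift *= float(_lognormal(rng, cv))
    return p


def _stride_train(
    timing: GaitTiming, duration: float, rng: np.random.Generator, cv: float
) -> np.ndarray:
    """Left-forelimb hoof-on times spanning [-2 SD, duration + 2 SD]."""
    sd = timing.stride_duration
    t = [-2.0 * sd]
    while t[-1] < duration + 2.0 * sd:
        t.append(t[-1] + sd * float(_lognormal(rng, cv)))
    return np.asarray(t)


def _limb_phase(timing: GaitTiming, limb: str) -> float:
    phase = timing.footfall_phase[limb]
    if limb in ("LH", "RH"):
        phase = phase + timing.diagonal_dissociation / timing.stride_duration
    return phase


def synthesize_trial(
    params: HorseParams,
    condition: str,
    lame_side: str,
    duration: float = 20.0,
    noise: NoiseConfig = NoiseConfig(),
    rng: Optional[np.random.Generator] = None,
    force_rate: float = FORCE_RATE,
    marker_rate: float = MARKER_RATE,
    seed: Optional[int] = None,
) -> Trial:
    """Synthesise one trial from fully-specified horse parameters."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    timing = params.timing
    n_f = int(round(duration * force_rate))
    n_m = int(round(duration * marker_rate))
    t_f = np.arange(n_f) / force_rate
    t_m = np.arange(n_m) / marker_rate

    boundaries = _stride_train(timing, duration, rng, noise.stride_cv)
    theta_m = np.interp(t_m, boundaries, 2.0 * np.pi * np.arange(len(boundaries)))

    forces = np.zeros((n_f, len(LIMBS)))
    fnorm_m = {l: np.zeros(n_m) for l in LIMBS}  # normalised force at marker rate
    ground_truth: Dict[str, List[Tuple[float, float]]] = {l: [] for l in LIMBS}
    markers: Dict[str, np.ndarray] = {}

    for j, limb in enumerate(LIMBS):
        shape = params.shapes[limb]
        geom = params.limbs[limb]
        phase = _limb_phase(timing, limb)
        duty = timing.duty_factor[limb]

        # stance duration is duty * the limb's own stride interval, so the
        # whole stride (stance + swing) scales together under timing jitter
        ons = [boundaries[k] + phase * (boundaries[k + 1] - boundaries[k])
               for k in range(len(boundaries) - 1)]
        stances = []  # (on, dur, amp)
        for k, on in enumerate(ons):
            interval = (ons[k + 1] - on) if k + 1 < len(ons) else (
                timing.stride_duration
            )
            dur = duty * interval
            amp = float(_lognormal(rng, noise.stride_cv))
            stances.append((on, dur, amp))
            if on >= 0.0 and on + dur <= duration:
                ground_truth[limb].append((on, on + dur))

        # --- force trace and marker-rate normalised force -----------------
        for on, dur, amp in stances:
            i0, i1 = np.searchsorted(t_f, [on, on + dur])
            s = (t_f[i0:i1] - on) / dur
            forces[i0:i1, j] += params.body_mass * amp * grf_waveform(shape, params.gait, s)
            m0, m1 = np.searchsorted(t_m, [on, on + dur])
            sm = (t_m[m0:m1] - on) / dur
            fnorm_m[limb][m0:m1] += amp * grf_waveform(shape, params.gait, sm)

        # --- hoof trajectory ----------------------------------------------
        y = np.full(n_m, geom.hoof_home_y)
        z = np.full(n_m, geom.hoof_z)
        v = params.belt_speed
        for idx, (on, dur, amp) in enumerate(stances):
            y_on = geom.hoof_home_y + v * dur / 2.0
            m0, m1 = np.searchsorted(t_m, [on, on + dur])
            y[m0:m1] = y_on - v * (t_m[m0:m1] - on)
            z[m0:m1] = geom.hoof_z
            if idx + 1 < len(stances):
                on_next, dur_next, _ = stances[idx + 1]
                y_off = y_on - v * dur
                y_on_next = geom.hoof_home_y + v * dur_next / 2.0
                s0, s1 = np.searchsorted(t_m, [on + dur, on_next])
                u = (t_m[s0:s1] - (on + dur)) / (on_next - (on + dur))
                y[s0:s1] = y_off + (y_on_next - y_off) * swing_displacement(
                    u, geom.swing_exponent
                )
                z[s0:s1] = geom.hoof_z + geom.lift * swing_lift(u)
        hoof = np.column_stack([np.full(n_m, geom.hoof_x), y, z])

        # --- fetlock / proximal markers from the extension angle -----------
        e = np.radians(geom.fetlock_gain * fnorm_m[limb])
        pivot = np.array([geom.hoof_x, geom.pivot_y, geom.pivot_z])
        d = hoof - pivot[None, :]
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        half = e / 2.0

        def _rot(dy, dz, a):
            return dy * np.cos(a) - dz * np.sin(a), dy * np.sin(a) + dz * np.cos(a)

        dy1, dz1 = _rot(d[:, 1], d[:, 2], half)
        fetlock = hoof - geom.seg_hoof_fetlock * np.column_stack(
            [d[:, 0], dy1, dz1]
        )
        dy2, dz2 = _rot(d[:, 1], d[:, 2], -half)
        prox = fetlock - geom.seg_fetlock_prox * np.column_stack([d[:, 0], dy2, dz2])

        markers[f"hoof_{limb}"] = hoof
        markers[f"fetlock_{limb}"] = fetlock
        markers[f"prox_{limb}"] = prox
        markers[f"pivot_{limb}"] = np.tile(pivot, (n_m, 1))

    for name in BODY_LANDMARKS:
        markers[name] = landmark_xyz(theta_m, params.motion.landmarks[name])

    if noise.sigma_force > 0:
        forces = forces + rng.normal(0.0, noise.sigma_force * params.body_mass, forces.shape)
    if noise.sigma_marker > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, noise.sigma_marker, markers[name].shape
            )

    return Trial(
        horse_id=params.horse_id,
        gait=params.gait,
        condition=condition,
        lame_side=lame_side,
        body_mass=params.body_mass,
        belt_speed=params.belt_speed,
        force_rate=force_rate,
        marker_rate=marker_rate,
        duration=duration,
        forces=forces,
        markers=markers,
        ground_truth=ground_truth,
        seed=seed,
    )


def generate_cohort(
    n_horses: int,
    gait: str,
    profile: LamenessEffectProfile | str = "baseline",
    seed: int = 0,
    conditions: Sequence[str] = ("baseline", "lame"),
    duration: float = 20.0,
    noise: NoiseConfig = NoiseConfig(),
) -> List[Trial]:
    """Generate a cohort of paired baseline / induced-lameness trials.

    Each horse gets its own body mass, preferred belt speed and baseline
    parameter set; the 'lame' condition realizes the effect profile on that
    horse's own baseline.  Induction sides alternate left/right across horses
    (all data are later mirrored to a left-lame convention).  Fully
    reproducible from ``seed``.
    """
    if n_horses < 1:
        raise ConfigurationError("n_horses must be >= 1")
    if isinstance(profile, str):
        profile = get_profile(profile)
    speed_range = WALK_SPEED_RANGE if gait == "walk" else TROT_SPEED_RANGE
    ss = np.random.SeedSequence(seed)
    horse_seeds = ss.spawn(n_horses)

    trials: List[Trial] = []
    for i in range(n_horses):
        child = np.random.default_rng(horse_seeds[i])
        mass = float(child.uniform(*BODY_MASS_RANGE))
        speed = float(child.uniform(*speed_range))
        side = "left" if i % 2 == 0 else "right"
        base = default_params(gait, horse_id=f"H{i:02d}", body_mass=mass, belt_speed=speed)
        base = jitter_horse(base, child, noise.horse_cv)
        base = calibrate_weight_support(base)
        lame = apply_profile(base, profile, side)
        for condition in conditions:
            params = base if condition == "baseline" else lame
            trial_side = "none" if condition == "baseline" else side
            trials.append(
                synthesize_trial(
                    params,
                    condition=condition,
                    lame_side=trial_side,
                    duration=duration,
                    noise=noise,
                    rng=np.random.default_rng(child.integers(0, 2**31 - 1)),
                )
            )
    return trials


def induction_sides(trials: Sequence[Trial]) -> Dict[str, str]:
    """Per-horse induction side inferred from the cohort's lame trials."""
    sides: Dict[str, str] = {}
    for tr in trials:
        if tr.lame_side in ("left", "right"):
            sides[tr.horse_id] = tr.lame_side
    for tr in trials:
        sides.setdefault(tr.horse_id, "left")
    return sides
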