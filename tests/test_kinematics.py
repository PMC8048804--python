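"""Symmetry indices (against a dense-grid brute-force oracle) and limb
kinematics (hand-computed angle examples, swing metrics, generator oracle)."""

import numpy as np
import pytest

from lamegait.config import ExtractionConfig, NoiseConfig
from lamegait.events import detect_events
from lamegait.kinematics import (
    fetlock_angle,
    limb_angle,
    stride_limb_kinematics,
    vertical_symmetry,
)
from lamegait.profiles import analytic_swing_peak_speed

MRATE = 256.0
SD = 1.25


def _signal(a2, a1, phi1=0.0, n_strides=6):
    t = np.arange(int(n_strides * SD * MRATE)) / MRATE
    theta = 2 * np.pi * t / SD
    z = 1.5 + a2 * np.sin(2 * theta) + a1 * np.sin(theta + phi1)
    return t, z


def _oracle(a2, a1, phi1=0.0):
    """Brute-force symmetry indices on a dense grid of one stride."""
    th = np.linspace(0, 2 * np.pi, 2_000_001)
    z = 1.5 + a2 * np.sin(2 * th) + a1 * np.sin(th + phi1)
    d = np.sign(np.diff(z))
    turn = np.diff(d)
    mins = np.where(turn > 0)[0] + 1
    maxs = np.where(turn < 0)[0] + 1
    left_min = min((i for i in mins if th[i] < np.pi), key=lambda i: z[i])
    right_min = min((i for i in mins if th[i] >= np.pi), key=lambda i: z[i])
    max_after = lambda i: next(j for j in maxs if j > i)
    # trailing max may wrap into the next stride
    def max_after_wrap(i):
        later = [j for j in maxs if j > i]
        return later[0] if later else maxs[0]
    m_al = max_after(left_min)
    m_ar = max_after_wrap(right_min)
    max_before = lambda i: max(j for j in maxs if j < i) if any(j < i for j in maxs) else maxs[-1]
    m_bl = max_before(left_min)
    m_br = max_before(right_min)
    return {
        "MinDiff": z[right_min] - z[left_min],
        "RUD": (z[m_al] - z[left_min]) - (z[m_ar] - z[right_min]),
        "RDD": (z[m_bl] - z[left_min]) - (z[m_br] - z[right_min]),
        "ROMz": z.max() - z.min(),
    }


def test_symmetric_signal_has_zero_indices():
    t, z = _signal(a2=0.02, a1=0.0)
    out = vertical_symmetry(t, z, (2 * SD, 3 * SD), 2.5 * SD, MRATE)
    assert out["MinDiff"] == pytest.approx(0.0, abs=1e-6)
    assert out["RUD"] == pytest.approx(0.0, abs=1e-6)
    assert out["RDD"] == pytest.approx(0.0, abs=1e-6)
    assert out["ROMz"] == pytest.approx(0.04, abs=1e-4)


@pytest.mark.parametrize("a1,phi1", [(0.005, 0.0), (0.01, 3 * np.pi / 4)])
def test_indices_match_brute_force_oracle(a1, phi1):
    t, z = _signal(a2=0.02, a1=a1, phi1=phi1)
    out = vertical_symmetry(t, z, (2 * SD, 3 * SD), 2.5 * SD, MRATE)
    ref = _oracle(0.02, a1, phi1)
    for key in ("MinDiff", "RUD", "RDD", "ROMz"):
        assert out[key] == pytest.approx(ref[key], abs=1e-4), key


def test_mirrored_signal_flips_mindiff_keeps_rom():
    t, z = _signal(a2=0.02, a1=0.006, phi1=3 * np.pi / 4)
    out = vertical_symmetry(t, z, (2 * SD, 3 * SD), 2.5 * SD, MRATE)
    # swapping half-cycles = advancing the signal by half a stride
    t2, z2 = _signal(a2=0.02, a1=0.006, phi1=3 * np.pi / 4 + np.pi)
    out2 = vertical_symmetry(t2, z2, (2 * SD, 3 * SD), 2.5 * SD, MRATE)
    assert out2["MinDiff"] == pytest.approx(-out["MinDiff"], abs=1e-4)
    assert out2["ROMz"] == pytest.approx(out["ROMz"], abs=1e-4)


def test_mindiff_monotone_in_asymmetry_amplitude():
    mags = []
    for a1 in (0.0, 0.002, 0.004, 0.008, 0.012):
        t, z = _signal(a2=0.02, a1=a1, phi1=3 * np.pi / 4)
        out = vertical_symmetry(t, z, (2 * SD, 3 * SD), 2.5 * SD, MRATE)
        mags.append(abs(out["MinDiff"]))
    assert all(b >= a - 1e-9 for a, b in zip(mags[:-1], mags[1:]))


def test_limb_angle_hand_examples():
    pivot = np.array([[0.0, 0.0, 1.2]])
    assert limb_angle(pivot, np.array([[0.0, 0.0, 0.2]]))[0] == pytest.approx(0.0)
    # hoof 0.3 m cranial, 1.0 m below: atan(0.3/1.0) = 16.7 deg
    assert limb_angle(pivot, np.array([[0.0, 0.3, 0.2]]))[0] == pytest.approx(16.699, abs=0.01)
    assert limb_angle(pivot, np.array([[0.0, -0.3, 0.2]]))[0] == pytest.approx(-16.699, abs=0.01)
    with pytest.raises(ValueError):
        limb_angle(pivot, pivot)


def test_fetlock_angle_examples():
    # collinear markers: no hyperextension
    prox = np.array([[0.0, 0.0, 0.4]])
    fet = np.array([[0.0, 0.0, 0.1]])
    hoof = np.array([[0.0, 0.0, 0.0]])
    assert fetlock_angle(prox, fet, hoof)[0] == pytest.approx(0.0, abs=1e-9)
    # vertex angle of 150 deg -> hyperextension 30 deg
    # hoof straight down from the fetlock; proximal segment 150 deg away
    a = np.radians(150.0)
    prox2 = fet + 0.3 * np.array([[0.0, np.sin(a), -np.cos(a)]])
    hoof2 = fet + 0.1 * np.array([[0.0, 0.0, -1.0]])
    assert fetlock_angle(prox2, fet, hoof2)[0] == pytest.approx(30.0, abs=1e-9)
    with pytest.raises(ValueError):
        fetlock_angle(fet, fet, hoof)


def test_swing_metrics_on_generator_oracle(walk_trial_clean, walk_params):
    ev = detect_events(walk_trial_clean.forces, 512.0, walk_trial_clean.body_mass)
    t_m = walk_trial_clean.marker_time
    hoof = walk_trial_clean.markers["hoof_LF"]
    ang = limb_angle(walk_trial_clean.markers["pivot_LF"], hoof)
    hyp = fetlock_angle(
        walk_trial_clean.markers["prox_LF"], walk_trial_clean.markers["fetlock_LF"], hoof
    )
    on, off = ev.stances["LF"][3]
    nxt = ev.stances["LF"][4][0]
    out = stride_limb_kinematics(
        t_m, ang, hyp, hoof, (on, off), (off, nxt),
        walk_trial_clean.belt_speed, MRATE,
    )
    # slip-free stance: StL = belt speed x stance duration
    assert out["StL"] == pytest.approx(walk_trial_clean.belt_speed * (off - on), rel=0.01)
    v_ref = analytic_swing_peak_speed(
        walk_params.timing, walk_params.limbs["LF"], "LF", walk_params.belt_speed
    )
    assert out["Prot_speed"] == pytest.approx(v_ref, rel=0.02)
    assert out["ProtH"] == pytest.approx(
        walk_params.limbs["LF"].hoof_z + walk_params.limbs["LF"].lift, rel=0.02
    )
    assert out["Prot_max"] > 0 > out["Ret_max"]


def test_stationary_hoof_zero_swing_speed():
    t = np.arange(512) / MRATE
    hoof = np.tile([0.1, 0.5, 0.05], (len(t), 1))
    ang = np.zeros(len(t))
    out = stride_limb_kinematics(
        t, ang, ang, hoof, (0.2, 0.8), (0.8, 1.6), 1.68, MRATE
    )
    assert out["Prot_speed"] == pytest.approx(0.0, abs=1e-9)
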