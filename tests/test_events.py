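"""Event detection: slope-intercept oracle accuracy, stride segmentation,
temporal parameters and support-phase classification."""

import numpy as np
import pytest

from lamegait.config import ExtractionConfig, LIMBS, NoiseConfig
from lamegait.events import (
    StrideEvents,
    detect_events,
    detect_stances,
    segment_strides,
    support_phase_percentages,
    support_phases,
    temporal_parameters,
)
from lamegait.synthgen import generate_cohort

RATE = 512.0


def test_all_zero_trace_yields_no_stances():
    assert detect_stances(np.zeros(5000), RATE) == []


def test_half_sine_events_near_true_boundaries():
    # 3000 N half-sine, 0.7 s, starting at t = 1.0 s
    t = np.arange(int(3 * RATE)) / RATE
    f = np.where((t >= 1.0) & (t <= 1.7), 3000 * np.sin(np.pi * (t - 1.0) / 0.7), 0.0)
    stances = detect_stances(f, RATE)
    assert len(stances) == 1
    on, off = stances[0]
    assert 0.99 <= on <= 1.01
    assert 1.69 <= off <= 1.71


def test_noise_free_walk_matches_generator_oracle(walk_trial_clean):
    ev = detect_events(walk_trial_clean.forces, RATE, walk_trial_clean.body_mass)
    for j, limb in enumerate(LIMBS):
        gt = walk_trial_clean.ground_truth[limb]
        det = ev.stances[limb]
        assert len(det) == len(gt)
        for (on, off), (don, doff) in zip(gt, det):
            assert abs(don - on) < 2e-3 and abs(doff - off) < 2e-3


def test_translation_equivariance():
    t = np.arange(int(4 * RATE)) / RATE
    f = np.where((t >= 1.0) & (t <= 1.7), 3000 * np.sin(np.pi * (t - 1.0) / 0.7), 0.0)
    base = detect_stances(f, RATE)[0]
    shift = 256  # samples = 0.5 s
    shifted = detect_stances(np.concatenate([np.zeros(shift), f[:-shift]]), RATE)[0]
    assert shifted[0] - base[0] == pytest.approx(0.5, abs=1e-6)
    assert shifted[1] - base[1] == pytest.approx(0.5, abs=1e-6)


def _ideal_walk_events(sd=1.2, duty=0.625, n=4):
    """Exact events for quarter-phase walk; independent of the generator."""
    phases = {"LF": 0.0, "RH": 0.25, "RF": 0.5, "LH": 0.75}
    stances = {
        limb: [((k + ph) * sd, (k + ph + duty) * sd) for k in range(-1, n + 1)]
        for limb, ph in phases.items()
    }
    ev = StrideEvents(stances=stances)
    ev.stride_windows = segment_strides(ev)
    return ev


def test_stride_segmentation_counts():
    ev = _ideal_walk_events(n=14)
    assert len(ev.stride_windows) == len(ev.ons("LF")) - 1
    single = StrideEvents(stances={l: ([] if l != "LF" else [(0.0, 0.7)]) for l in LIMBS})
    assert segment_strides(single) == []


def test_temporal_parameters_ideal_walk():
    sd, duty = 1.2, 0.625
    ev = _ideal_walk_events(sd=sd, duty=duty)
    window = ev.stride_windows[1]
    out = temporal_parameters(ev, window, "walk")
    assert out["SD"] == pytest.approx(sd)
    for limb in LIMBS:
        assert out[f"StD_abs_{limb}"] == pytest.approx(duty * sd)
        assert out[f"StD_rel_{limb}"] == pytest.approx(duty)
    # quarter phases: ipsilateral hind->fore step is SD/4
    assert out["StpDi_left"] == pytest.approx(0.25 * sd)
    assert out["StpDi_right"] == pytest.approx(0.25 * sd)
    # fore -> contralateral fore step is SD/2
    assert out["StpDc_left"] == pytest.approx(0.5 * sd)
    # diagonal dissociation: forelimb-first negative (LF leads RH by SD/4)
    assert out["TAP_left"] == pytest.approx(-0.25 * sd)


def test_trot_tap_recovers_injected_dissociation(trot_params):
    from lamegait.config import clone
    from lamegait.synthgen import synthesize_trial

    p = clone(trot_params)
    p.timing.diagonal_dissociation = 0.010  # forelimb leads by 10 ms
    tr = synthesize_trial(p, "baseline", "none", duration=10.0,
                          noise=NoiseConfig.none(), seed=0)
    ev = detect_events(tr.forces, tr.force_rate, tr.body_mass)
    out = temporal_parameters(ev, ev.stride_windows[2], "trot")
    # measured TAP = fore_on - hind_on: forelimb-first => -10 ms
    assert out["TAP_left"] == pytest.approx(-0.010, abs=0.002)
    assert out["TAP_right"] == pytest.approx(-0.010, abs=0.002)


def test_support_phases_ideal_walk_eight_phases():
    ev = _ideal_walk_events(sd=1.2, duty=0.625)
    window = ev.stride_windows[1]
    seq = support_phases(ev, window, "walk")
    pct = support_phase_percentages(seq, window)
    assert set(pct) == {str(i) for i in range(1, 9)}
    for v in pct.values():
        assert v == pytest.approx(12.5, abs=1e-9)
    # brute-force oracle: count limbs in stance on a dense grid
    t0, t1 = window
    grid = np.linspace(t0, t1, 100_000, endpoint=False)
    n_in_stance = np.zeros_like(grid)
    for limb in LIMBS:
        for on, off in ev.stances[limb]:
            n_in_stance += (grid >= on) & (grid < off)
    assert np.mean(n_in_stance == 3) == pytest.approx(0.5, abs=1e-3)
    assert np.mean(n_in_stance == 2) == pytest.approx(0.5, abs=1e-3)


def test_support_phases_duty_half_bipedal_only():
    ev = _ideal_walk_events(sd=1.2, duty=0.5)
    seq = support_phases(ev, ev.stride_windows[1], "walk")
    labels = {lab for lab, _, _ in seq}
    assert labels <= {"2", "4", "6", "8"}  # bipedal phases only


def test_trot_support_alternates_diagonal_and_suspension(trot_trial_clean):
    ev = detect_events(trot_trial_clean.forces, RATE, trot_trial_clean.body_mass)
    seq = support_phases(ev, ev.stride_windows[2], "trot")
    labels = [lab for lab, _, _ in seq]
    assert set(labels) <= {"diag_left", "diag_right", "suspension"}
    assert "suspension" in labels
    for a, b in zip(labels[:-1], labels[1:]):
        assert a != b  # alternation


def test_phase_durations_tile_the_stride(walk_trial_clean):
    ev = detect_events(walk_trial_clean.forces, RATE, walk_trial_clean.body_mass)
    for window in ev.stride_windows[:5]:
        seq = support_phases(ev, window, "walk")
        total = sum(b - a for _, a, b in seq)
        assert total == pytest.approx(window[1] - window[0], abs=1 / RATE)
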