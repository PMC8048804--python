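"""COM proxy, centre of force and COF-COM path metrics: hand-computed
examples, convex-hull containment, resampling accuracy and path periodicity."""

import numpy as np
import pytest

from lamegait._signal import lowpass
from lamegait.comcof import cof, cof_com_metrics, com_proxy, com_rom, resample_markers
from lamegait.config import LIMBS
from lamegait.events import detect_events, support_phases
from lamegait.pipeline import extract_trial


def test_com_proxy_examples():
    sternum = np.array([[0.0, 0.0, 1.2]])
    l3 = np.array([[0.0, -0.5, 1.4]])
    np.testing.assert_allclose(com_proxy(sternum, l3, 0.5), [[0.0, -0.25, 1.3]])
    np.testing.assert_allclose(com_proxy(sternum, l3, 1.0), sternum)
    np.testing.assert_allclose(
        com_proxy(sternum, l3, 0.6), [[0.0, -0.2, 1.28]], atol=1e-12
    )
    with pytest.raises(ValueError):
        com_proxy(sternum, l3, 1.2)


def test_cof_examples():
    # equal forces at rectangle corners -> centre
    pos = np.array([[[-0.1, 1.0], [0.1, 1.0], [-0.1, -1.0], [0.1, -1.0]]])
    out = cof(np.array([[500.0, 500.0, 500.0, 500.0]]), pos)
    np.testing.assert_allclose(out, [[0.0, 0.0]], atol=1e-12)
    # single supporting limb -> that hoof exactly
    out = cof(np.array([[0.0, 800.0, 0.0, 0.0]]), pos)
    np.testing.assert_allclose(out, [[0.1, 1.0]], atol=1e-12)
    # LF 300 N at (-0.1, 1.0), RH 100 N at (0.1, -1.0) -> (-0.05, 0.5)
    out = cof(np.array([[300.0, 0.0, 0.0, 100.0]]), pos)
    np.testing.assert_allclose(out, [[-0.05, 0.5]], atol=1e-12)
    # zero total force -> undefined (NaN)
    out = cof(np.zeros((1, 4)), pos)
    assert np.all(np.isnan(out))


def test_cof_inside_support_hull_random_frames():
    rng = np.random.default_rng(11)
    forces = rng.uniform(0, 2000, (500, 4))
    forces[rng.random((500, 4)) < 0.3] = 0.0
    pos = rng.uniform(-1, 1, (500, 4, 2))
    out = cof(forces, pos)
    ok = ~np.isnan(out[:, 0])
    for k in range(2):
        coords = np.where(forces[ok] > 0, pos[ok, :, k], np.nan)
        assert np.all(out[ok, k] >= np.nanmin(coords, axis=1) - 1e-9)
        assert np.all(out[ok, k] <= np.nanmax(coords, axis=1) + 1e-9)
    # invariance to uniform force scaling
    np.testing.assert_allclose(cof(3.7 * forces, pos), out, equal_nan=True)


def test_resampling_exact_for_linear_and_tight_for_sine():
    t_m = np.arange(0, 2, 1 / 256)
    t_f = np.arange(0, 2, 1 / 512)
    const = resample_markers(t_m, np.full_like(t_m, 3.3), t_f)
    np.testing.assert_allclose(const, 3.3)
    lin = resample_markers(t_m, 0.7 * t_m - 0.2, t_f)
    inside = t_f <= t_m[-1]  # beyond the marker span values are clamped
    np.testing.assert_allclose(lin[inside], (0.7 * t_f - 0.2)[inside], atol=1e-12)
    assert lin[-1] == pytest.approx(0.7 * t_m[-1] - 0.2, abs=1e-12)
    sine = resample_markers(t_m, np.sin(2 * np.pi * 2 * t_m), t_f)
    assert np.max(np.abs((sine - np.sin(2 * np.pi * 2 * t_f))[inside])) < 1e-3
    with pytest.raises(ValueError):
        resample_markers(t_m, t_m, t_f + 100.0)


def test_com_rom_pure_lateral_sinusoid():
    t = np.arange(0, 1.25, 1 / 256)
    a = 0.03
    com = np.column_stack([a * np.sin(2 * np.pi * t / 1.25), 0 * t, 0 * t + 1.2])
    rom = com_rom(com)
    assert rom["COM_ROM_x"] == pytest.approx(2 * a, rel=1e-3)
    assert rom["COM_ROM_y"] == pytest.approx(0.0, abs=1e-12)
    assert rom["COM_ROM_z"] == pytest.approx(0.0, abs=1e-12)


def test_constructed_path_shift_changes_asymmetry():
    t = np.linspace(0, 1, 1000)
    phases = [("1", 0.0, 0.125), ("2", 0.125, 0.25), ("5", 0.5, 0.625), ("6", 0.625, 0.75)]
    com = np.zeros((1000, 2))
    cof_xy = np.zeros((1000, 2))
    cof_xy[:, 1] = 0.3 * np.sin(2 * np.pi * t)  # symmetric cranial oscillation
    base = cof_com_metrics(t, cof_xy, com, phases)
    # shift the path cranially by delta during the left-side window only
    delta = 0.07
    shifted = cof_xy.copy()
    shifted[(t >= 0.0) & (t <= 0.25), 1] += delta
    out = cof_com_metrics(t, shifted, com, phases)
    assert out["COF_asym"] - base["COF_asym"] == pytest.approx(delta, abs=1e-6)
    assert out["COF_cranial_max_right"] == base["COF_cranial_max_right"]


def test_walk_cof_path_periodic(walk_trial_clean):
    """On noise-free walk data the COF-COM path closes stride to stride."""
    tr = walk_trial_clean
    ev = detect_events(tr.forces, tr.force_rate, tr.body_mass)
    t_f = tr.force_time
    t_m = tr.marker_time
    gated = np.zeros_like(tr.forces)
    for j, limb in enumerate(LIMBS):
        for on, off in ev.stances[limb]:
            i0, i1 = np.searchsorted(t_f, [on, off])
            gated[i0:i1, j] = tr.forces[i0:i1, j]
    pos = np.stack(
        [resample_markers(t_m, tr.markers[f"hoof_{l}"][:, :2], t_f) for l in LIMBS],
        axis=1,
    )
    path = cof(gated, pos)
    com = resample_markers(t_m, com_proxy(tr.markers["sternum"], tr.markers["L3"])[:, :2], t_f)
    rel = path - com
    (t0, t1), (t0b, t1b) = ev.stride_windows[3], ev.stride_windows[4]
    i = np.searchsorted(t_f, t0 + 0.1)
    j = np.searchsorted(t_f, t0b + 0.1)
    closure = np.hypot(*(rel[i] - rel[j]))
    extent = np.nanmax(rel[:, 1]) - np.nanmin(rel[:, 1])
    assert closure < 0.05 * extent
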