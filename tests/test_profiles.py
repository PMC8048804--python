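"""Effect profiles: preset encodings, role mapping, and the realization
contract (noise-free analytic measurements change by exactly the factors)."""

import numpy as np
import pytest

from lamegait.config import ConfigurationError
from lamegait.profiles import (
    LamenessEffectProfile,
    TROT_MODERATE,
    WALK_MODERATE,
    analytic_swing_peak_speed,
    apply_profile,
    get_profile,
    role_map,
)
from lamegait.waveforms import RISE_SLOPE, unit_stance_mean, vertical_rom


def test_preset_encodes_reported_effects():
    assert WALK_MODERATE.factors[("Iz", "lame_fore")] == pytest.approx(0.949)
    assert WALK_MODERATE.factors[("Fz_peak2", "lame_fore")] == pytest.approx(0.939)
    assert WALK_MODERATE.factors[("dFz_load", "contralateral_fore")] == pytest.approx(1.165)
    assert TROT_MODERATE.factors[("Fz_peak", "lame_fore")] == pytest.approx(0.823)
    assert TROT_MODERATE.factors[("Iz", "lame_fore")] == pytest.approx(0.857)


def test_identity_profile_is_noop(walk_params):
    out = apply_profile(walk_params, get_profile("baseline"), "left")
    assert out == walk_params
    assert out is not walk_params


def test_role_mirroring():
    left = role_map("left")
    right = role_map("right")
    assert left["lame_fore"] == "LF" and left["diagonal_hind"] == "RH"
    assert right["lame_fore"] == "RF" and right["contralateral_fore"] == "LF"
    with pytest.raises(ConfigurationError):
        role_map("none")


def test_unknown_parameter_rejected():
    with pytest.raises(ConfigurationError):
        LamenessEffectProfile(name="bad", factors={("NotAParam", "lame_fore"): 0.9})
    with pytest.raises(ConfigurationError):
        LamenessEffectProfile(name="bad", factors={("Iz", "left_hind"): 0.9})
    with pytest.raises(ConfigurationError):
        LamenessEffectProfile(name="bad", factors={("Iz", "lame_fore"): -1.0})


def _stance(params, limb):
    return params.timing.duty_factor[limb] * params.timing.stride_duration


def test_walk_realization_hits_analytic_targets(walk_params):
    lame = apply_profile(walk_params, WALK_MODERATE, "left")
    # vertical impulse of the lame limb: M * stance scales by 0.949
    iz_base = unit_stance_mean(walk_params.shapes["LF"], "walk") * _stance(walk_params, "LF")
    iz_lame = unit_stance_mean(lame.shapes["LF"], "walk") * _stance(lame, "LF")
    assert iz_lame / iz_base == pytest.approx(0.949, rel=1e-6)
    # loading-rate chord of the contralateral limb scales by 1.165
    def rate(p, limb):
        s = p.shapes[limb]
        return RISE_SLOPE * s.peak1 / (s.t_peak1 * _stance(p, limb))
    assert rate(lame, "RF") / rate(walk_params, "RF") == pytest.approx(1.165, rel=1e-9)
    # peak factors applied directly; peaks elsewhere untouched
    assert lame.shapes["LF"].peak2 / walk_params.shapes["LF"].peak2 == pytest.approx(0.939)
    assert lame.shapes["RH"].peak1 / walk_params.shapes["RH"].peak1 == pytest.approx(1.048)
    assert lame.shapes["RF"].peak1 == walk_params.shapes["RF"].peak1
    # first-peak timing of the lame limb delayed by 8.4%
    assert lame.shapes["LF"].t_peak1 / walk_params.shapes["LF"].t_peak1 == pytest.approx(1.084)
    # swing peak speed of the lame limb reduced by 4.6% (measured estimator)
    v0 = analytic_swing_peak_speed(walk_params.timing, walk_params.limbs["LF"], "LF",
                                   walk_params.belt_speed)
    v1 = analytic_swing_peak_speed(lame.timing, lame.limbs["LF"], "LF", lame.belt_speed)
    assert v1 / v0 == pytest.approx(0.954, rel=2e-3)


def test_trot_realization_hits_analytic_targets(trot_params):
    lame = apply_profile(trot_params, TROT_MODERATE, "left")
    assert lame.shapes["LF"].peak / trot_params.shapes["LF"].peak == pytest.approx(0.823)
    iz_base = unit_stance_mean(trot_params.shapes["LF"], "trot") * _stance(trot_params, "LF")
    iz_lame = unit_stance_mean(lame.shapes["LF"], "trot") * _stance(lame, "LF")
    assert iz_lame / iz_base == pytest.approx(0.857, rel=1e-6)
    # head vertical range of motion increased by 50.5%
    rom0 = vertical_rom(trot_params.motion.landmarks["poll"])
    rom1 = vertical_rom(lame.motion.landmarks["poll"])
    assert rom1 / rom0 == pytest.approx(1.505, rel=1e-4)


def test_right_side_realization_mirrors_limbs(walk_params):
    lame = apply_profile(walk_params, WALK_MODERATE, "right")
    # the lame forelimb is now RF; LF is contralateral (loading-rate target)
    assert lame.shapes["RF"].peak2 / walk_params.shapes["RF"].peak2 == pytest.approx(0.939)
    assert lame.shapes["LF"].peak2 == walk_params.shapes["LF"].peak2
    assert lame.shapes["LH"].peak1 / walk_params.shapes["LH"].peak1 == pytest.approx(1.048)
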