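"""Youden-index discrimination: brute-force oracle equivalence, monotone
invariance, tie rules, side selection and left-lame mirroring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lamegait.discrim import (
    heatmap_table,
    mirror_right,
    select_induction_side,
    youden,
    youden_table,
)


def brute_force_j(baseline, lame):
    """Independent oracle: exhaustive search over every pooled value."""
    best = 0.0
    for c in np.concatenate([baseline, lame]):
        for direction in ("greater", "less"):
            if direction == "greater":
                j = np.mean(lame > c) + np.mean(baseline <= c) - 1
            else:
                j = np.mean(lame < c) + np.mean(baseline >= c) - 1
            best = max(best, j)
    return best


def test_perfect_separation():
    cell = youden([1, 2, 3], [10, 11, 12])
    assert cell.sensitivity == 1.0 and cell.specificity == 1.0
    assert cell.youden_j == 1.0 and cell.direction == "greater"


def test_identical_samples_zero_j():
    cell = youden([1, 2, 3, 4], [1, 2, 3, 4])
    assert cell.youden_j == pytest.approx(0.0, abs=1e-12)


def test_worked_example_overlapping_samples():
    cell = youden([1, 2, 3, 4], [3, 4, 5, 6])
    assert cell.youden_j == pytest.approx(0.5)
    assert cell.youden_j == pytest.approx(brute_force_j(np.array([1, 2, 3, 4]),
                                                        np.array([3, 4, 5, 6])))
    assert cell.sensitivity + cell.specificity - 1 == pytest.approx(cell.youden_j)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    b=st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=25),
    l=st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=25),
)
def test_matches_brute_force_oracle(b, l):
    cell = youden(b, l)
    assert cell.youden_j == pytest.approx(
        brute_force_j(np.asarray(b, float), np.asarray(l, float)), abs=1e-9
    )


def test_invariant_under_monotone_transform():
    rng = np.random.default_rng(5)
    b = rng.normal(0, 1, 20)
    l = rng.normal(0.8, 1, 18)
    j0 = youden(b, l).youden_j
    assert youden(np.exp(b), np.exp(l)).youden_j == pytest.approx(j0)
    assert youden(b**3, l**3).youden_j == pytest.approx(j0)


def test_requires_two_values_per_condition():
    with pytest.raises(ValueError):
        youden([1.0], [2.0, 3.0])


def test_heatmap_medians():
    cells = pd.DataFrame(
        {
            "horse_id": ["H1", "H2", "H3"],
            "variable": ["Iz_lame"] * 3,
            "sensitivity": [0.2, 0.8, 1.0],
            "specificity": [0.5, 0.6, 0.7],
            "cutoff": [0, 0, 0],
            "direction": ["greater"] * 3,
            "youden_j": [0.1, 0.4, 0.7],
            "n_baseline": [10] * 3,
            "n_lame": [10] * 3,
        }
    )
    _, summary = heatmap_table(cells)
    row = summary.iloc[0]
    assert row["median_sens"] == pytest.approx(0.8)
    assert row["median_spec"] == pytest.approx(0.6)
    assert row["n_horses"] == 3


def test_select_induction_side_rules():
    # larger |MinDiff| wins
    assert select_induction_side({"min_diff": 0.008, "dfz_peak": 0.1},
                                 {"min_diff": 0.003, "dfz_peak": 0.9}) == "left"
    # within the equivalence band the larger force difference decides
    assert select_induction_side({"min_diff": 0.0100, "dfz_peak": 0.9},
                                 {"min_diff": 0.0098, "dfz_peak": 0.4}) == "left"
    assert select_induction_side({"min_diff": 0.0098, "dfz_peak": 0.4},
                                 {"min_diff": 0.0100, "dfz_peak": 0.9}) == "right"
    # exact tie -> left by convention
    assert select_induction_side({"min_diff": 0.005, "dfz_peak": 0.5},
                                 {"min_diff": 0.005, "dfz_peak": 0.5}) == "left"
    # missing side -> the other
    assert select_induction_side(None, {"min_diff": 0.005, "dfz_peak": 0.5}) == "right"


def _records(**vars_values):
    rows = []
    for var, val in vars_values.items():
        rows.append(dict(horse_id="H1", gait="walk", condition="lame",
                         stride_index=0, variable=var, value=val, units="x"))
    return pd.DataFrame(rows)


def test_mirror_left_is_identity_on_values():
    df = _records(MinDiff_poll=0.004, Iz_LF=4.2, StpDi_left=0.3)
    out = mirror_right(df, "left")
    assert set(out["variable"]) == {"MinDiff_poll", "Iz_lame", "StpDi_lame"}
    assert out.loc[out["variable"] == "MinDiff_poll", "value"].iloc[0] == 0.004


def test_mirror_right_negates_signed_and_maps_roles():
    df = _records(MinDiff_poll=0.004, Iz_RF=4.2, Iz_LF=5.0, StpDi_right=0.3,
                  supp1=12.5, supp5=14.0, COF_cranial_max_left=0.2)
    out = mirror_right(df, "right").set_index("variable")["value"]
    assert out["MinDiff_poll"] == -0.004
    assert out["Iz_lame"] == 4.2 and out["Iz_contra"] == 5.0
    assert out["StpDi_lame"] == 0.3
    assert out["supp5"] == 12.5 and out["supp1"] == 14.0
    assert out["COF_cranial_max_contra"] == 0.2


def test_double_mirror_is_identity_for_signed_variables():
    df = _records(MinDiff_poll=0.004, RUD_withers=-0.002)
    once = mirror_right(df, "right")
    twice = mirror_right(once, "right")
    np.testing.assert_allclose(twice["value"].to_numpy(), df["value"].to_numpy())
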