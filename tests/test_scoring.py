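"""Cutoff calibration, the tanh score transform, AUC weights and the
Total Score classifier."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tepscore import (
    PanelModel,
    PanelVariable,
    calibrate_scoring_cutoffs,
    classify,
    compute_weights,
    compute_x,
    fit_panel,
    mann_whitney_auc,
    score_samples,
    total_score,
    transform_f,
)
from tepscore.scoring import build_variables, compute_variable_values


def labeled(benign, oc, name="v"):
    values = pd.DataFrame({name: list(benign) + list(oc)})
    labels = pd.Series(["Benign"] * len(benign) + ["OC"] * len(oc))
    return values, labels


# ---------------------------------------------------------------------------
# variables

def test_composite_variable_sums_member_delta_cq():
    dcq = pd.DataFrame(
        {"a": [2.0], "b": [3.0], "c": [4.0], "d": [5.0], "e": [6.0], "solo": [12.0]},
        index=["s"],
    )
    variables = build_variables(["solo"], ["a", "b", "c", "d", "e"], 5.0)
    vals = compute_variable_values(dcq, variables)
    assert vals.at["s", "composite"] == 20.0
    assert vals.at["s", "solo"] == 12.0
    with pytest.raises(ValueError, match="missing members"):
        compute_variable_values(dcq.drop(columns="a"), variables)


# ---------------------------------------------------------------------------
# calibration

def test_cutoff_midpoint_between_benign_boundary_and_nearest_cancer():
    values, labels = labeled([8.0, 9.0, 10.0], [5.0, 6.0])
    assert calibrate_scoring_cutoffs(values, labels)["v"] == 7.0


def test_cutoff_fallback_when_no_cancer_below_boundary():
    values, labels = labeled([8.0, 9.0, 10.0], [12.0, 13.0])
    assert calibrate_scoring_cutoffs(values, labels)["v"] == 7.5


def test_shared_boundary_value_is_treated_as_benign_side():
    values, labels = labeled([8.0, 9.0], [8.0, 12.0])
    # cancer value equal to the benign minimum must stay above the cutoff
    assert calibrate_scoring_cutoffs(values, labels)["v"] == 7.5


def test_constant_variable_dropped_with_warning():
    values, labels = labeled([5.0, 5.0], [5.0])
    with pytest.warns(UserWarning, match="constant"):
        assert calibrate_scoring_cutoffs(values, labels) == {}


def test_calibrated_cutoffs_guarantee_training_specificity():
    rng = np.random.default_rng(7)
    for _ in range(25):
        benign = rng.normal(20, 2, 16)
        oc = rng.normal(17, 3, 13)
        values, labels = labeled(benign, oc)
        cut = calibrate_scoring_cutoffs(values, labels, 0.99)["v"]
        # a benign sample is called positive iff its value < cutoff
        assert (benign >= cut).mean() >= 0.99


# ---------------------------------------------------------------------------
# transform and weights

def test_x_is_scaled_cutoff_distance():
    variables = [PanelVariable("i", ("i",), 1.0), PanelVariable("c", ("c", "c2"), 5.0)]
    values = pd.DataFrame({"i": [5.0, 7.0], "c": [20.0, 30.0]}, index=["s1", "s2"])
    x = compute_x(values, {"i": 7.0, "c": 30.0}, variables)
    assert x.loc["s1"].tolist() == [2.0, 2.0]
    assert x.loc["s2"].tolist() == [0.0, 0.0]


def test_transform_f_branches():
    assert transform_f(0.0) == 0.0
    assert transform_f(-1.0) == pytest.approx(-0.1)
    assert transform_f(1.0) == pytest.approx(math.tanh(1.0))


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.floats(-1e6, 1e6, allow_nan=False))
def test_transform_f_shape(x):
    f = transform_f(x)
    assert f <= 1.0  # tanh saturates to 1.0 in float for very large x
    if x >= 0:
        assert 0 <= f == pytest.approx(math.tanh(x))
    else:
        assert f == pytest.approx(x / 10)
    # continuity at zero
    assert abs(transform_f(1e-12) - transform_f(-1e-12)) < 1e-11


@pytest.mark.parametrize(
    "pos, neg, expected",
    [
        ([2, 3], [-1, -2], 1.0),
        ([0, 0], [0, 0], 0.5),
        ([1, 3], [2, 4], 0.25),   # one concordant pair of four
        ([2, -1], [0, 1], 0.5),   # two concordant pairs of four
    ],
)
def test_pair_counting_auc_examples(pos, neg, expected):
    assert mann_whitney_auc(pos, neg) == expected


def test_auc_weights_require_both_classes():
    x = pd.DataFrame({"v": [1.0, 2.0]})
    with pytest.raises(ValueError):
        compute_weights(x, pd.Series(["OC", "OC"]))


def test_auc_matches_rank_statistic_and_sklearn():
    from scipy.stats import mannwhitneyu
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(11)
    for _ in range(20):
        pos = rng.normal(0.5, 1, rng.integers(2, 30))
        neg = rng.normal(0.0, 1, rng.integers(2, 30))
        ours = mann_whitney_auc(pos, neg)
        u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert ours == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)
        y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        assert ours == pytest.approx(roc_auc_score(y, np.r_[pos, neg]), abs=1e-12)


# ---------------------------------------------------------------------------
# total score and classification

def test_total_score_zero_replacement_trace():
    score, f_used, contributing = total_score(
        pd.Series({"v1": 0.5, "v2": -0.2}), {"v1": 0.9, "v2": 0.8}
    )
    assert f_used.tolist() == [0.5, 0.0]
    assert contributing == ["v1"]
    assert score == pytest.approx(0.45)


def test_total_score_all_negative_trace():
    score, f_used, contributing = total_score(
        pd.Series({"v1": -0.1, "v2": -0.3}), {"v1": 0.9, "v2": 0.8}
    )
    assert contributing == ["v1", "v2"]
    assert score == pytest.approx((-0.09 - 0.24) / 2)


def test_total_score_degenerate_and_errors():
    score, _, contributing = total_score(
        pd.Series({"v1": 0.0, "v2": 0.0}), {"v1": 0.9, "v2": 0.8}
    )
    assert score == 0.0 and contributing == []
    with pytest.raises(ValueError):
        total_score(pd.Series(dtype=float), {})
    with pytest.raises(ValueError):
        total_score(pd.Series({"v": 0.5}), {})


def test_classification_boundary():
    assert classify(0.45) == "OC"
    assert classify(-0.165) == "non-OC"
    assert classify(0.0) == "non-OC"
    assert classify(0.0, zero_is_cancer=True) == "OC"


def random_panel(rng, n_vars=4):
    names = [f"v{i}" for i in range(n_vars)]
    variables = [PanelVariable(n, (n,), 1.0) for n in names]
    return PanelModel(
        variables=variables,
        scoring_cutoffs={n: float(rng.normal(20, 2)) for n in names},
        weights={n: float(rng.uniform(0.5, 1.0)) for n in names},
        nonspecific_cutoffs={n: 38.0 for n in names},
    )


def test_classification_equivalent_to_any_marker_below_cutoff_oracle():
    rng = np.random.default_rng(42)
    panel = random_panel(rng)
    dcq = pd.DataFrame(
        rng.normal(20, 4, (10_000, 4)),
        columns=[v.name for v in panel.variables],
        index=[f"s{i}" for i in range(10_000)],
    )
    scores = score_samples(dcq, panel)
    cutoffs = pd.Series(panel.scoring_cutoffs)
    oracle = dcq.lt(cutoffs, axis=1).any(axis=1).map({True: "OC", False: "non-OC"})
    assert (scores["predicted"] == oracle).all()


def test_score_bounded_above_by_max_weight():
    rng = np.random.default_rng(5)
    panel = random_panel(rng)
    dcq = pd.DataFrame(
        rng.normal(20, 6, (500, 4)), columns=[v.name for v in panel.variables]
    )
    scores = score_samples(dcq, panel)
    assert (scores["total_score"] <= max(panel.weights.values()) + 1e-12).all()
    assert (scores["total_score"] < 1.0).all()


def test_call_monotone_in_delta_cq():
    """Increasing expression (lower ΔCq) can never flip a cancer call back
    to non-cancer. The raw Total Score itself is *not* monotone: a marker
    whose F turns weakly positive joins the contributing set and can dilute
    the weighted average — but the sign, hence the call, is preserved."""
    rng = np.random.default_rng(6)
    panel = random_panel(rng)
    cols = [v.name for v in panel.variables]
    dcq = pd.DataFrame(rng.normal(20, 3, (200, 4)), columns=cols)
    base = score_samples(dcq, panel)
    for col in cols:
        lower = dcq.copy()
        lower[col] -= 2.0  # more expression
        bumped = score_samples(lower, panel)
        was_oc = base["predicted"] == "OC"
        assert (bumped.loc[was_oc, "predicted"] == "OC").all()
        # per-variable transformed values are monotone
        for c in cols:
            assert (bumped[f"F_raw_{c}"] >= base[f"F_raw_{c}"] - 1e-12).all()


def test_fit_panel_round_trips_through_yaml(tmp_path):
    rng = np.random.default_rng(8)
    cols = ["m1", "m2", "a", "b"]
    dcq = pd.DataFrame(rng.normal(20, 3, (29, 4)), columns=cols)
    dcq.iloc[:13] -= 4.0
    labels = pd.Series(["OC"] * 13 + ["Benign"] * 16, index=dcq.index)
    variables = build_variables(["m1", "m2"], ["a", "b"], 5.0)
    panel = fit_panel(dcq, labels, variables, {c: 38.0 for c in cols})
    path = tmp_path / "panel.yaml"
    panel.to_yaml(path)
    loaded = PanelModel.from_yaml(path)
    assert loaded.scoring_cutoffs == panel.scoring_cutoffs
    assert loaded.weights == panel.weights
    assert loaded.variables == panel.variables
    pd.testing.assert_frame_equal(
        score_samples(dcq, loaded), score_samples(dcq, panel)
    )
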