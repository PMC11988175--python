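"""Replicate collapsing, non-specific censoring, and ΔCq derivation."""

import numpy as np
import pandas as pd
import pytest

from tepscore import (
    apply_nonspecific_cutoff,
    collapse_replicates,
    compute_delta_cq,
    derive_nonspecific_cutoffs,
    preprocess_cq,
)
from tepscore.qpcr import (
    FLAG_CENSORED,
    FLAG_MEASURED,
    FLAG_UNDETECTED,
    VACUOUS_EPS,
    CollapsedCq,
)


def long_cq(rows):
    """rows: (sample, marker, replicate, cq-or-None)."""
    return pd.DataFrame(
        [
            {
                "sample_id": s,
                "marker": m,
                "replicate": r,
                "cq": np.nan if c is None else c,
                "undetected": c is None,
            }
            for s, m, r, c in rows
        ]
    )


@pytest.mark.parametrize(
    "reps, expected, fully_undetected",
    [
        ((33.0, 35.0), 34.0, False),
        ((30.0, None), 35.5, False),  # undetected replicate enters as 41
        ((None, None), 41.0, True),
    ],
)
def test_collapse_replicates_sentinel_averaging(reps, expected, fully_undetected):
    rows = [("s1", "m", i + 1, c) for i, c in enumerate(reps)]
    out = collapse_replicates(long_cq(rows), undetected_value=41.0)
    assert out.values.at["s1", "m"] == expected
    assert bool(out.undetected.at["s1", "m"]) is fully_undetected


def test_collapse_missing_cell_for_required_marker_errors():
    table = long_cq([("s1", "m1", 1, 30.0)])
    with pytest.raises(ValueError, match="m2"):
        collapse_replicates(table, required_markers=["m1", "m2"])


def collapsed(values: dict, undetected: dict | None = None) -> CollapsedCq:
    v = pd.DataFrame(values)
    u = pd.DataFrame(undetected) if undetected else pd.DataFrame(
        False, index=v.index, columns=v.columns
    )
    return CollapsedCq(values=v, undetected=u)


def test_cutoff_derivation_max_and_vacuous():
    c = collapsed(
        {"m": {"b1": 34.0, "b2": 36.0, "b3": 37.0}, "silent": {"b1": 41.0, "b2": 41.0, "b3": 41.0}},
        {"m": {"b1": False, "b2": False, "b3": False},
         "silent": {"b1": True, "b2": True, "b3": True}},
    )
    cut = derive_nonspecific_cutoffs(c, ["b1", "b2", "b3"], ["m", "silent"])
    assert cut["m"] == 37.0
    assert cut["silent"] == pytest.approx(41.0 - VACUOUS_EPS)
    with pytest.raises(ValueError):
        derive_nonspecific_cutoffs(c, [], ["m"])


def test_cutoff_derivation_percentile_matches_quantile_oracle():
    vals = {f"b{i}": float(v) for i, v in enumerate(range(30, 40))}
    c = collapsed({"m": vals})
    cut = derive_nonspecific_cutoffs(
        c, list(vals), ["m"], strategy="percentile", percentile=0.95
    )
    assert cut["m"] == pytest.approx(np.quantile(np.arange(30.0, 40.0), 0.95))


@pytest.mark.parametrize(
    "cq, expect_value, expect_flag",
    [
        (38.2, 41.0, FLAG_CENSORED),   # exceeds the 37 cutoff
        (36.9, 36.9, FLAG_MEASURED),
        (37.0, 37.0, FLAG_MEASURED),   # boundary: strictly "exceeding" only
    ],
)
def test_nonspecific_censoring_boundary(cq, expect_value, expect_flag):
    c = collapsed({"m": {"s": cq}})
    values, flags = apply_nonspecific_cutoff(c, pd.Series({"m": 37.0}))
    assert values.at["s", "m"] == expect_value
    assert flags.at["s", "m"] == expect_flag


def test_censoring_is_idempotent_and_requires_cutoffs():
    c = collapsed({"m": {"s1": 38.2, "s2": 35.0}})
    cut = pd.Series({"m": 37.0})
    v1, f1 = apply_nonspecific_cutoff(c, cut)
    v2, f2 = apply_nonspecific_cutoff(CollapsedCq(v1, c.undetected), cut)
    pd.testing.assert_frame_equal(v1, v2)
    with pytest.raises(ValueError, match="other"):
        apply_nonspecific_cutoff(collapsed({"other": {"s": 30.0}}), cut)


def test_delta_cq_subtraction_and_sentinel_propagation():
    values = pd.DataFrame({"m": {"s": 30.0}, "late": {"s": 41.0}, "ACTB": {"s": 18.0}})
    flags = pd.DataFrame(
        {"m": {"s": FLAG_MEASURED}, "late": {"s": FLAG_CENSORED},
         "ACTB": {"s": FLAG_MEASURED}}
    )
    delta, out_flags = compute_delta_cq(values, flags, "ACTB", actb_window=None)
    assert delta.at["s", "m"] == 12.0
    assert delta.at["s", "late"] == 23.0
    assert "ACTB" not in delta.columns
    assert out_flags.at["s", "late"] == FLAG_CENSORED


def test_undetected_reference_is_a_sample_level_error():
    values = pd.DataFrame({"m": {"s": 30.0}, "ACTB": {"s": 41.0}})
    flags = pd.DataFrame({"m": {"s": FLAG_MEASURED}, "ACTB": {"s": FLAG_UNDETECTED}})
    with pytest.raises(ValueError, match="s"):
        compute_delta_cq(values, flags, "ACTB", actb_window=None)


def test_reference_outside_plausibility_window_warns():
    values = pd.DataFrame({"m": {"s": 30.0}, "ACTB": {"s": 25.0}})
    flags = pd.DataFrame({"m": {"s": FLAG_MEASURED}, "ACTB": {"s": FLAG_MEASURED}})
    with pytest.warns(UserWarning, match="window"):
        compute_delta_cq(values, flags, "ACTB")


def test_delta_cq_monotone_in_raw_cq():
    base = long_cq(
        [("s", "ACTB", 1, 18.0), ("s", "ACTB", 2, 18.0),
         ("s", "m", 1, 30.0), ("s", "m", 2, 31.0),
         ("b", "ACTB", 1, 18.0), ("b", "ACTB", 2, 18.0),
         ("b", "m", 1, 39.0), ("b", "m", 2, 39.0)]
    )
    deltas = []
    for bump in (0.0, 1.0, 6.0, 12.0):
        table = base.copy()
        sel = (table.sample_id == "s") & (table.marker == "m") & (table.replicate == 1)
        table.loc[sel, "cq"] += bump
        delta, _, _ = preprocess_cq(
            table, benign_train_samples=["b"], markers=["m"], actb_window=None
        )
        deltas.append(delta.at["s", "m"])
    assert deltas == sorted(deltas)
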