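"""Cancer-specific junction marker screening and qPCR validation.

The screen looks for junctions that are near-silent in control samples
(asymptomatic + benign) yet clearly expressed in at least one ovarian
cancer sample, over a grid of log2CPM thresholds × control fractions.
Candidates are then validated against qPCR: a marker passes if it is
entirely undetected in control samples, or if the linear fit of reversed
ΔCq on ACTB-scaled log2CPM reaches R² ≥ 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MarkerValidation:
    marker_id: str
    r_squared: float | None
    absent_in_controls: bool
    selected: bool
    reason: str = ""


def select_candidates(
    log2cpm: pd.DataFrame,
    control_samples: list[str],
    case_samples: list[str],
    thresholds: list[float] = (0.2, 0.3, 0.4, 0.5),
    control_fractions: list[float] = (0.70, 0.75, 0.80, 0.85, 0.90, 0.95),
    case_rule: str = "above_threshold",
    case_margin: float = 1.0,
    min_case_count: int = 1,
) -> pd.DataFrame:
    """Screen junctions over the threshold × control-fraction grid.

    A junction is admitted by a (threshold, fraction) pair when at least
    ``fraction`` of controls have log2CPM strictly below ``threshold``
    (ties at the threshold count as not below) and at least
    ``min_case_count`` cancer samples satisfy the case rule:

    - ``above_threshold``: case value ≥ threshold + margin;
    - ``outlier``: case value > control Q3 + 1.5·IQR (Tukey upper fence).

    Returns a frame with one row per admitting (junction, threshold,
    fraction) triple; the distinct junction ids are the candidate set
    (union over the grid).
    """
    if not control_samples or not case_samples:
        raise ValueError("control and case sample sets must both be non-empty")
    controls = log2cpm[list(control_samples)]
    cases = log2cpm[list(case_samples)]

    if case_rule == "outlier":
        q1 = controls.quantile(0.25, axis=1)
        q3 = controls.quantile(0.75, axis=1)
        fence = q3 + 1.5 * (q3 - q1)
        n_cases_ok = cases.gt(fence, axis=0).sum(axis=1)

    rows = []
    for thr in thresholds:
        frac_below = controls.lt(thr).mean(axis=1)
        if case_rule == "above_threshold":
            n_cases_ok = cases.ge(thr + case_margin).sum(axis=1)
        elif case_rule != "outlier":
            raise ValueError(f"unknown case_rule {case_rule!r}")
        case_ok = n_cases_ok >= min_case_count
        for frac in control_fractions:
            admitted = log2cpm.index[(frac_below >= frac) & case_ok]
            rows += [
                {"junction_id": j, "threshold": thr, "control_fraction": frac}
                for j in admitted
            ]
    return pd.DataFrame(rows, columns=["junction_id", "threshold", "control_fraction"])


def candidate_ids(admissions: pd.DataFrame) -> list[str]:
    """Deduplicated candidate junction ids, in first-admission order."""
    return list(dict.fromkeys(admissions["junction_id"]))


def scale_log2cpm(marker_values: pd.Series, actb_values: pd.Series) -> pd.Series:
    """Scaled log2CPM: marker minus the ACTB reference, per sample."""
    missing = marker_values.index.difference(actb_values.dropna().index)
    if len(missing):
        raise ValueError(f"missing ACTB log2CPM for samples: {missing.tolist()}")
    return marker_values - actb_values.reindex(marker_values.index)


def reverse_delta_cq(delta_cq: pd.Series) -> pd.Series:
    """Reversed ΔCq: per-marker maximum minus each value.

    Computed over the non-missing entries; the sample attaining the maximum
    maps to 0 and higher expression (lower ΔCq) maps to larger values.
    """
    present = delta_cq.dropna()
    if present.empty:
        raise ValueError("all ΔCq values are missing")
    return present.max() - delta_cq


def validate_marker(
    marker_id: str,
    scaled_seq: pd.Series,
    reversed_dcq: pd.Series,
    r2_min: float = 0.4,
    controls_absent: bool = False,
) -> MarkerValidation:
    """Validate one candidate against qPCR.

    Ordinary least squares of reversed ΔCq on scaled log2CPM over the
    paired, non-missing samples; for the simple regression the coefficient
    of determination equals the squared sample correlation. A marker with
    no control-group expression bypasses the R² requirement.
    """
    pairs = pd.DataFrame({"x": scaled_seq, "y": reversed_dcq}).dropna()
    if len(pairs) < 3:
        if controls_absent:
            return MarkerValidation(marker_id, None, True, True, "absent in controls")
        return MarkerValidation(
            marker_id, None, False, False,
            f"only {len(pairs)} paired observations (<3)",
        )
    x = pairs["x"].to_numpy()
    y = pairs["y"].to_numpy()
    sxx = ((x - x.mean()) ** 2).sum()
    syy = ((y - y.mean()) ** 2).sum()
    if sxx == 0 or syy == 0:
        r2: float | None = 0.0 if syy > 0 or sxx > 0 else None
    else:
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        r2 = float(sxy * sxy / (sxx * syy))
    selected = controls_absent or (r2 is not None and r2 >= r2_min)
    reason = "absent in controls" if controls_absent else (
        f"R^2 = {r2}" if r2 is not None else "degenerate fit"
    )
    return MarkerValidation(marker_id, r2, controls_absent, selected, reason)


def validation_table(validations: list[MarkerValidation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "marker": v.marker_id,
                "r_squared": np.nan if v.r_squared is None else v.r_squared,
                "absent_in_controls": v.absent_in_controls,
                "selected": v.selected,
                "reason": v.reason,
            }
            for v in validations
        ]
    )
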