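"""Panel calibration and the weighted tanh scoring classifier.

Each panel variable is either one marker's ΔCq or a composite (the sum of
several markers' ΔCq). For every variable a scoring cutoff is calibrated on
the training set so that benign specificity meets the 99% target by
construction, and the cutoff distance x = (cutoff − observed)/divisor is
pushed through a piecewise transform,

    F(x) = tanh(x)   if x ≥ 0
    F(x) = x / 10    if x < 0,

bounded above by 1 and gently linear below 0. Variables are weighted by
their training ROC AUC (w = AUC), negative F values are zeroed whenever any
variable is positive, and the final Total Score is the weighted mean of the
non-zero F values. A positive Total Score calls ovarian cancer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

LABEL_OC = "OC"
LABEL_NON_OC = "non-OC"


@dataclass(frozen=True)
class PanelVariable:
    """One scoring variable: an individual marker or a composite sum."""

    name: str
    members: tuple[str, ...]
    divisor: float = 1.0

    def __post_init__(self) -> None:
        if self.divisor <= 0:
            raise ValueError(f"variable {self.name}: divisor must be positive")
        if not self.members:
            raise ValueError(f"variable {self.name}: no members")

    @property
    def is_composite(self) -> bool:
        return len(self.members) > 1


@dataclass
class PanelModel:
    """The fitted classifier: variables, cutoffs, AUC weights, constants."""

    variables: list[PanelVariable]
    scoring_cutoffs: dict[str, float]
    weights: dict[str, float]
    nonspecific_cutoffs: dict[str, float]
    undetected_value: float = 41.0
    reference_marker: str = "ACTB"
    negative_slope: float = 0.1
    zero_score_is_cancer: bool = False

    def __post_init__(self) -> None:
        for name, w in self.weights.items():
            if not 0 <= w <= 1:
                raise ValueError(f"weight for {name} outside [0, 1]: {w}")
        for v in self.variables:
            if v.name not in self.scoring_cutoffs or v.name not in self.weights:
                raise ValueError(f"variable {v.name} lacks a cutoff or weight")

    @property
    def marker_universe(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.variables:
            for m in v.members:
                seen.setdefault(m)
        return list(seen)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "variables": [
                {"name": v.name, "members": list(v.members), "divisor": v.divisor}
                for v in self.variables
            ],
            "scoring_cutoffs": {k: float(v) for k, v in self.scoring_cutoffs.items()},
            "weights": {k: float(v) for k, v in self.weights.items()},
            "nonspecific_cutoffs": {
                k: float(v) for k, v in self.nonspecific_cutoffs.items()
            },
            "undetected_value": float(self.undetected_value),
            "reference_marker": self.reference_marker,
            "negative_slope": float(self.negative_slope),
            "zero_score_is_cancer": bool(self.zero_score_is_cancer),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelModel":
        doc = yaml.safe_load(Path(path).read_text())
        variables = [
            PanelVariable(v["name"], tuple(v["members"]), float(v["divisor"]))
            for v in doc["variables"]
        ]
        return cls(
            variables=variables,
            scoring_cutoffs=doc["scoring_cutoffs"],
            weights=doc["weights"],
            nonspecific_cutoffs=doc["nonspecific_cutoffs"],
            undetected_value=doc["undetected_value"],
            reference_marker=doc["reference_marker"],
            negative_slope=doc["negative_slope"],
            zero_score_is_cancer=doc.get("zero_score_is_cancer", False),
        )


def build_variables(
    individual_markers: Sequence[str],
    composite_members: Sequence[str],
    composite_divisor: float = 5.0,
    composite_name: str = "composite",
    available_markers: Iterable[str] | None = None,
) -> list[PanelVariable]:
    """Assemble the panel variable partition, optionally restricted to the
    markers that survived validation."""
    avail = None if available_markers is None else set(available_markers)
    keep = lambda m: avail is None or m in avail
    variables = [
        PanelVariable(m, (m,), 1.0) for m in individual_markers if keep(m)
    ]
    members = tuple(m for m in composite_members if keep(m))
    if members:
        variables.append(PanelVariable(composite_name, members, composite_divisor))
    if not variables:
        raise ValueError("no panel variables remain")
    return variables


def compute_variable_values(
    delta_cq: pd.DataFrame, variables: Sequence[PanelVariable]
) -> pd.DataFrame:
    """Observed value per sample × variable: the marker's ΔCq, or the sum of
    member ΔCq for a composite."""
    cols = {}
    for v in variables:
        missing = [m for m in v.members if m not in delta_cq.columns]
        if missing:
            raise ValueError(f"variable {v.name}: missing members {missing}")
        sub = delta_cq[list(v.members)]
        if sub.isna().any().any():
            bad = sub.index[sub.isna().any(axis=1)].tolist()
            raise ValueError(f"variable {v.name}: missing ΔCq for samples {bad}")
        cols[v.name] = sub.sum(axis=1)
    return pd.DataFrame(cols)


def calibrate_scoring_cutoffs(
    values: pd.DataFrame,
    labels: pd.Series,
    target_specificity: float = 0.99,
    delta: float = 0.5,
) -> dict[str, float]:
    """Per-variable scoring cutoffs guaranteeing training specificity.

    With specificity target s and n benign values, at most ⌊n(1−s)⌋ benign
    values may fall at or below the cutoff; let q be the smallest benign
    value that must stay above it (with n ≤ 100 and s = 0.99 this is the
    benign minimum). The cutoff is the midpoint between q and the largest
    cancer value strictly below q, or q − delta when no cancer value lies
    below. A benign value equal to a cancer value is treated as benign-side,
    preserving the guarantee. Constant variables are dropped with a warning.
    """
    cutoffs: dict[str, float] = {}
    for name in values.columns:
        col = values[name]
        benign = col[labels == "Benign"].dropna().to_numpy()
        cancer = col[labels == "OC"].dropna().to_numpy()
        if len(benign) == 0 or len(cancer) == 0:
            raise ValueError(f"variable {name}: both classes required")
        if np.ptp(np.concatenate([benign, cancer])) == 0:
            warnings.warn(f"variable {name} is constant on training; dropped")
            continue
        allowed = int(np.floor(len(benign) * (1 - target_specificity)))
        q = float(np.sort(benign)[allowed])
        below = cancer[cancer < q]
        cutoffs[name] = (q + float(below.max())) / 2 if len(below) else q - delta
    return cutoffs


def compute_x(
    values: pd.DataFrame,
    cutoffs: dict[str, float],
    variables: Sequence[PanelVariable],
) -> pd.DataFrame:
    """x = (cutoff − observed) / divisor; positive means expression beyond
    the calibrated boundary (lower ΔCq than the cutoff)."""
    divisors = {v.name: v.divisor for v in variables}
    out = {}
    for name in values.columns:
        out[name] = (cutoffs[name] - values[name]) / divisors.get(name, 1.0)
    return pd.DataFrame(out)


def transform_f(x, negative_slope: float = 0.1):
    """F(x) = tanh(x) for x ≥ 0, negative_slope · x for x < 0."""
    arr = np.asarray(x, dtype=float)
    res = np.where(arr >= 0, np.tanh(arr), negative_slope * arr)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(res)
    if isinstance(x, (pd.Series, pd.DataFrame)):
        return type(x)(res, index=x.index, **(
            {"columns": x.columns} if isinstance(x, pd.DataFrame) else {}
        ))
    return res


def mann_whitney_auc(positive, negative) -> float:
    """ROC AUC by pair counting: the fraction of (positive, negative) pairs
    where the positive scores higher, ties counted one half."""
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (pos.size * neg.size))


def compute_weights(x_values: pd.DataFrame, labels: pd.Series) -> dict[str, float]:
    """w = training ROC AUC of each variable's x (higher x ⇒ more cancer-like)."""
    oc = labels == "OC"
    benign = labels == "Benign"
    if not oc.any() or not benign.any():
        raise ValueError("both classes required to compute AUC weights")
    return {
        name: mann_whitney_auc(x_values[name][oc], x_values[name][benign])
        for name in x_values.columns
    }


def total_score(
    f_raw: pd.Series, weights: dict[str, float]
) -> tuple[float, pd.Series, list[str]]:
    """Zero-replacement, contributing-set selection and weighted averaging
    for one sample.

    If any F is positive, negatives are replaced by 0; the contributing set
    M_s holds the variables with non-zero (post-replacement) F, and the
    Total Score is Σ F·w / |M_s| (0 when M_s is empty).
    """
    if f_raw.empty:
        raise ValueError("empty variable set")
    missing = [v for v in f_raw.index if v not in weights]
    if missing:
        raise ValueError(f"no weight for variables: {missing}")
    f_used = f_raw.clip(lower=0) if (f_raw > 0).any() else f_raw.copy()
    contributing = f_used.index[f_used != 0].tolist()
    if not contributing:
        return 0.0, f_used, []
    w = pd.Series(weights)[contributing]
    score = float((f_used[contributing] * w).sum() / len(contributing))
    return score, f_used, contributing


def classify(score: float, zero_is_cancer: bool = False) -> str:
    """Sign-based call. The boundary score of 0 arises only when no marker
    exceeds its cutoff, so it defaults to the non-cancer class."""
    if score > 0:
        return LABEL_OC
    if score < 0:
        return LABEL_NON_OC
    return LABEL_OC if zero_is_cancer else LABEL_NON_OC


def score_samples(delta_cq: pd.DataFrame, panel: PanelModel) -> pd.DataFrame:
    """Apply a fitted panel to a ΔCq matrix (samples × markers).

    Returns the full per-sample breakdown: observed value, x, raw and
    zero-replaced F per variable, the contributing-set size, the Total
    Score and the predicted label.
    """
    values = compute_variable_values(delta_cq, panel.variables)
    x = compute_x(values, panel.scoring_cutoffs, panel.variables)
    f_raw = transform_f(x, panel.negative_slope)
    rows = []
    for sample in values.index:
        score, f_used, contributing = total_score(f_raw.loc[sample], panel.weights)
        row: dict[str, object] = {}
        for v in panel.variables:
            row[f"value_{v.name}"] = values.at[sample, v.name]
            row[f"x_{v.name}"] = x.at[sample, v.name]
            row[f"F_raw_{v.name}"] = f_raw.at[sample, v.name]
            row[f"F_used_{v.name}"] = f_used[v.name]
        row["n_contributing"] = len(contributing)
        row["total_score"] = score
        row["predicted"] = classify(score, panel.zero_score_is_cancer)
        rows.append(row)
    return pd.DataFrame(rows, index=values.index).rename_axis("sample_id")


def fit_panel(
    delta_cq_train: pd.DataFrame,
    labels_train: pd.Series,
    variables: Sequence[PanelVariable],
    nonspecific_cutoffs: pd.Series | dict[str, float],
    target_specificity: float = 0.99,
    cutoff_delta: float = 0.5,
    undetected_value: float = 41.0,
    reference_marker: str = "ACTB",
    negative_slope: float = 0.1,
    zero_score_is_cancer: bool = False,
) -> PanelModel:
    """Calibrate scoring cutoffs and AUC weights on the training split."""
    values = compute_variable_values(delta_cq_train, variables)
    cutoffs = calibrate_scoring_cutoffs(
        values, labels_train, target_specificity, cutoff_delta
    )
    kept = [v for v in variables if v.name in cutoffs]
    x = compute_x(values[[v.name for v in kept]], cutoffs, kept)
    weights = compute_weights(x, labels_train)
    return PanelModel(
        variables=list(kept),
        scoring_cutoffs=cutoffs,
        weights=weights,
        nonspecific_cutoffs=dict(pd.Series(nonspecific_cutoffs).astype(float)),
        undetected_value=undetected_value,
        reference_marker=reference_marker,
        negative_slope=negative_slope,
        zero_score_is_cancer=zero_score_is_cancer,
    )
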