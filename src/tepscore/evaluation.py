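"""Classifier evaluation: confusion matrices, binary metrics, ROC AUC and
Wilson 95% confidence intervals.

Ovarian cancer (OC) is the positive class; benign tumors and asymptomatic
controls are negative. Borderline ovarian tumors are excluded from the 2×2
tables and reported separately as the number called cancer. The AUC is the
Mann–Whitney pair-counting estimator, and — following the diagnostic
convention adopted here — its confidence interval is the Wilson score
interval with n equal to the number of evaluated samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .scoring import LABEL_OC, mann_whitney_auc

roc_auc = mann_whitney_auc


@dataclass
class ConfusionMatrix2x2:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class EvalReport:
    confusion: ConfusionMatrix2x2
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    balanced_accuracy: float | None
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    n: int = 0
    bot_total: int = 0
    bot_called_oc: int = 0

    def to_dict(self) -> dict:
        cm = self.confusion
        return {
            "n": self.n,
            "tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "auc": self.auc,
            "auc_ci_low": None if self.auc_ci is None else self.auc_ci[0],
            "auc_ci_high": None if self.auc_ci is None else self.auc_ci[1],
            "bot_total": self.bot_total,
            "bot_called_oc": self.bot_called_oc,
        }


def confusion(
    predicted: pd.Series,
    groups: pd.Series,
    positive_group: str = "OC",
    exclude_groups: tuple[str, ...] = ("BOT",),
) -> tuple[ConfusionMatrix2x2, dict[str, int]]:
    """Tabulate predictions against clinical groups.

    ``predicted`` holds OC / non-OC labels indexed by sample; ``groups``
    the clinical group per sample. Groups in ``exclude_groups`` are kept
    out of the 2×2 and summarised as a side count of positive calls.
    """
    mismatch = predicted.index.symmetric_difference(groups.index)
    if len(mismatch):
        raise ValueError(f"sample ids do not align: {mismatch.tolist()}")
    groups = groups.reindex(predicted.index)
    excluded = groups.isin(exclude_groups)
    pred_pos = predicted[~excluded] == LABEL_OC
    actual_pos = groups[~excluded] == positive_group
    cm = ConfusionMatrix2x2(
        tp=int((pred_pos & actual_pos).sum()),
        fn=int((~pred_pos & actual_pos).sum()),
        fp=int((pred_pos & ~actual_pos).sum()),
        tn=int((~pred_pos & ~actual_pos).sum()),
    )
    side = {
        g: int((predicted[groups == g] == LABEL_OC).sum())
        for g in exclude_groups
        if (groups == g).any()
    }
    return cm, side


def binary_metrics(cm: ConfusionMatrix2x2) -> dict[str, float | None]:
    """Sensitivity, specificity, accuracy and balanced accuracy.

    A metric whose class is empty is reported as None (undefined), never 0.
    """
    sens = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else None
    spec = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp > 0 else None
    acc = (cm.tp + cm.tn) / cm.n if cm.n > 0 else None
    bal = (sens + spec) / 2 if sens is not None and spec is not None else None
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "balanced_accuracy": bal,
    }


def wilson_interval(
    p: float, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a proportion-scale quantity.

    center = (p + z²/2n) / (1 + z²/n),
    half-width = z·sqrt(p(1−p)/n + z²/4n²) / (1 + z²/n).

    Always a sub-interval of [0, 1] with non-zero width even at p ∈ {0, 1}.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    z = norm.ppf(0.5 + confidence / 2)
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return float(center - half), float(center + half)


def evaluate(
    scores: pd.DataFrame,
    groups: pd.Series,
    positive_group: str = "OC",
    exclude_groups: tuple[str, ...] = ("BOT",),
    confidence: float = 0.95,
) -> EvalReport:
    """Full report for one evaluation set.

    ``scores`` is the breakdown from :func:`tepscore.scoring.score_samples`
    (columns total_score and predicted). The AUC compares OC against all
    non-excluded, non-OC samples; its Wilson interval uses n = number of
    samples entering the 2×2.
    """
    cm, side = confusion(scores["predicted"], groups, positive_group, exclude_groups)
    metrics = binary_metrics(cm)
    groups = groups.reindex(scores.index)
    mask = ~groups.isin(exclude_groups)
    pos = scores.loc[mask & (groups == positive_group), "total_score"]
    neg = scores.loc[mask & (groups != positive_group), "total_score"]
    auc = auc_ci = None
    if len(pos) and len(neg):
        auc = mann_whitney_auc(pos, neg)
        auc_ci = wilson_interval(auc, cm.n, confidence)
    return EvalReport(
        confusion=cm,
        **metrics,
        auc=auc,
        auc_ci=auc_ci,
        n=cm.n,
        bot_total=int(groups.isin(exclude_groups).sum()),
        bot_called_oc=sum(side.values()),
    )
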