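"""qPCR ΔCq preprocessing.

Raw duplicate Cq measurements are collapsed to one value per (sample,
marker): undetected reactions are assigned the sentinel of 41 cycles before
averaging. Per-marker non-specific signal cutoffs, fitted on benign-tumor
training samples, censor late weak signal to the same sentinel, and the
result is normalised within-sample against the ACTB reference:
ΔCq = Cq_target − Cq_ACTB. Lower ΔCq means more template.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

FLAG_MEASURED = "measured"
FLAG_CENSORED = "censored_nonspecific"
FLAG_UNDETECTED = "undetected"

#: ε subtracted from the sentinel for markers never detected in benign
#: training samples, so genuine detections are never censored.
VACUOUS_EPS = 1e-6


@dataclass
class CollapsedCq:
    """Per (sample, marker) mean Cq plus detection provenance."""

    values: pd.DataFrame   # sample × marker mean Cq
    undetected: pd.DataFrame  # bool: all replicates undetected


def collapse_replicates(
    measurements: pd.DataFrame,
    undetected_value: float = 41.0,
    required_markers: list[str] | None = None,
) -> CollapsedCq:
    """Average duplicate Cq measurements with sentinel substitution.

    ``measurements`` is the long table produced by
    :func:`tepscore.io.read_cq_table` (columns sample_id, marker, replicate,
    cq, undetected). Undetected replicates contribute the sentinel value to
    the mean; a cell whose replicates are all undetected is flagged. A cell
    with no replicates at all for a required marker is an error — assay
    dropout is distinct from no-amplification.
    """
    work = measurements.copy()
    work["cq_filled"] = work["cq"].where(~work["undetected"], undetected_value)
    if work["cq_filled"].isna().any():
        raise ValueError("detected measurement with missing Cq value")
    grouped = work.groupby(["sample_id", "marker"], sort=True)
    values = grouped["cq_filled"].mean().unstack()
    undet = grouped["undetected"].all().unstack()

    if required_markers is not None:
        samples = values.index
        missing = []
        for m in required_markers:
            if m not in values.columns:
                missing += [(s, m) for s in samples]
            else:
                missing += [(s, m) for s in samples[values[m].isna()]]
        if missing:
            raise ValueError(f"missing Cq cells for (sample, marker): {missing}")
        values = values[required_markers]
        undet = undet[required_markers]
    undet = undet.fillna(False).astype(bool)
    return CollapsedCq(values=values, undetected=undet)


def derive_nonspecific_cutoffs(
    collapsed: CollapsedCq,
    benign_train_samples: list[str],
    markers: list[str],
    strategy: str = "max",
    percentile: float = 0.95,
    undetected_value: float = 41.0,
) -> pd.Series:
    """Fit one non-specific Cq cutoff per marker from benign training samples.

    The default strategy takes the maximum Cq among benign samples where the
    marker was detected: any later (weaker) signal than every benign signal
    is deemed non-specific. Markers never detected in benign get the vacuous
    cutoff ``undetected_value − ε`` so that no real detection is censored.
    """
    if not benign_train_samples:
        raise ValueError("empty benign training set")
    values = collapsed.values.loc[benign_train_samples, markers]
    detected = ~collapsed.undetected.loc[benign_train_samples, markers]
    cutoffs = {}
    for m in markers:
        numeric = values[m][detected[m]]
        if numeric.empty:
            cutoffs[m] = undetected_value - VACUOUS_EPS
        elif strategy == "max":
            cutoffs[m] = float(numeric.max())
        elif strategy == "percentile":
            cutoffs[m] = float(numeric.quantile(percentile))
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
    return pd.Series(cutoffs, name="nonspecific_cutoff")


def apply_nonspecific_cutoff(
    collapsed: CollapsedCq,
    cutoffs: pd.Series,
    undetected_value: float = 41.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Censor Cq values strictly exceeding their marker's cutoff to the sentinel.

    Returns (censored values, flags); flags mark each cell as measured,
    censored_nonspecific, or undetected. Idempotent: the sentinel exceeds
    every finite cutoff and simply stays put.
    """
    missing = [m for m in collapsed.values.columns if m not in cutoffs.index]
    if missing:
        raise ValueError(f"no non-specific cutoff for markers: {missing}")
    values = collapsed.values.copy()
    exceed = values.gt(cutoffs[values.columns], axis=1)
    censored = values.mask(exceed, undetected_value)
    flags = pd.DataFrame(FLAG_MEASURED, index=values.index, columns=values.columns)
    flags = flags.mask(exceed, FLAG_CENSORED)
    flags = flags.mask(collapsed.undetected, FLAG_UNDETECTED)
    return censored, flags


def compute_delta_cq(
    censored: pd.DataFrame,
    flags: pd.DataFrame,
    reference_marker: str = "ACTB",
    undetected: pd.DataFrame | None = None,
    actb_window: tuple[float, float] | None = (17.25, 20.88),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ΔCq(s, m) = Cq(s, m) − Cq(s, ACTB); the reference column is dropped.

    The reference must be detected in every sample — an undetected reference
    invalidates the sample outright. Reference Cq values far outside the
    plausible window (defaults to the observed qPCR efficiency range) raise
    a warning, not an error.
    """
    if reference_marker not in censored.columns:
        raise ValueError(f"reference marker {reference_marker!r} not measured")
    ref = censored[reference_marker]
    bad = ref.isna()
    if undetected is not None and reference_marker in undetected.columns:
        bad |= undetected[reference_marker]
    if flags is not None and reference_marker in flags.columns:
        bad |= flags[reference_marker] != FLAG_MEASURED
    if bad.any():
        raise ValueError(
            f"reference marker undetected/censored in samples: "
            f"{ref.index[bad].tolist()}"
        )
    if actb_window is not None:
        outside = ref[(ref < actb_window[0]) | (ref > actb_window[1])]
        if len(outside):
            warnings.warn(
                f"reference Cq outside plausibility window {actb_window} for "
                f"samples {outside.index.tolist()}",
                stacklevel=2,
            )
    delta = censored.sub(ref, axis=0).drop(columns=reference_marker)
    out_flags = flags.drop(columns=reference_marker)
    return delta, out_flags


def preprocess_cq(
    measurements: pd.DataFrame,
    benign_train_samples: list[str],
    markers: list[str],
    reference_marker: str = "ACTB",
    undetected_value: float = 41.0,
    strategy: str = "max",
    percentile: float = 0.95,
    actb_window: tuple[float, float] | None = (17.25, 20.88),
    cutoffs: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Full preprocessing: collapse → censor → ΔCq.

    When ``cutoffs`` is supplied (a previously fitted panel), they are
    applied as-is; otherwise they are fitted from ``benign_train_samples``.
    Returns (ΔCq matrix, flags, cutoffs).
    """
    collapsed = collapse_replicates(
        measurements, undetected_value, required_markers=markers + [reference_marker]
    )
    if cutoffs is None:
        cutoffs = derive_nonspecific_cutoffs(
            collapsed, benign_train_samples, markers,
            strategy=strategy, percentile=percentile,
            undetected_value=undetected_value,
        )
    # the reference is never censored; give it a vacuous cutoff
    full_cutoffs = cutoffs.copy()
    full_cutoffs[reference_marker] = np.inf
    censored, flags = apply_nonspecific_cutoff(
        CollapsedCq(collapsed.values, collapsed.undetected),
        full_cutoffs,
        undetected_value,
    )
    delta, out_flags = compute_delta_cq(
        censored, flags, reference_marker,
        undetected=collapsed.undetected, actb_window=actb_window,
    )
    return delta, out_flags, cutoffs
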