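"""End-to-end orchestration: screen → validate → preprocess → calibrate →
score → evaluate.

The data flow honors the study design: the candidate screen sees only
training-split sequencing data (asymptomatic + benign controls vs cancer
cases); non-specific cutoffs and scoring cutoffs are fitted on training
benign (and cancer) samples only; asymptomatic controls never enter model
fitting and are evaluated as a pure validation set.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import markers as mk
from . import qpcr, scoring
from .config import PipelineConfig
from .evaluation import EvalReport, evaluate
from .scoring import PanelModel


@dataclass
class PipelineResult:
    admissions: pd.DataFrame          # candidate screen provenance
    validations: pd.DataFrame         # marker, R², absent flag, selected
    panel: PanelModel
    delta_cq: pd.DataFrame
    flags: pd.DataFrame
    scores: pd.DataFrame
    reports: dict[str, EvalReport]

    @property
    def selected_markers(self) -> list[str]:
        return self.validations.loc[self.validations["selected"], "marker"].tolist()


def split_samples(meta: pd.DataFrame, group: str | list[str], split: str) -> list[str]:
    groups = [group] if isinstance(group, str) else list(group)
    sel = meta["group"].isin(groups) & (meta["split"] == split)
    return meta.index[sel].tolist()


def screen_candidates(
    log2cpm: pd.DataFrame, meta: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Run the candidate screen on the training split (controls = AC ∪
    Benign, cases = OC)."""
    controls = [
        s for s in split_samples(meta, ["AC", "Benign"], "train")
        if s in log2cpm.columns
    ]
    cases = [s for s in split_samples(meta, "OC", "train") if s in log2cpm.columns]
    return mk.select_candidates(
        log2cpm,
        controls,
        cases,
        thresholds=list(config.thresholds),
        control_fractions=list(config.control_fractions),
        case_rule=config.case_rule,
        case_margin=config.case_margin,
        min_case_count=config.min_case_count,
    )


def validate_candidates(
    candidates: list[str],
    log2cpm: pd.DataFrame,
    delta_cq: pd.DataFrame,
    flags: pd.DataFrame,
    meta: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """qPCR validation of screened candidates that were assayed.

    R² pairs sequencing (scaled log2CPM, training samples) with qPCR
    (reversed ΔCq) over samples with genuinely measured signal; a marker
    undetected in every control sample bypasses the R² requirement.
    """
    seq_samples = [s for s in meta.index[meta["split"] == "train"]
                   if s in log2cpm.columns]
    control_ids = meta.index[meta["group"].isin(["AC", "Benign"])]
    results = []
    actb = log2cpm.loc[config.reference_marker, seq_samples]
    for m in candidates:
        if m not in delta_cq.columns:
            continue  # screened but never assayed
        controls_absent = bool(
            (flags.loc[flags.index.intersection(control_ids), m]
             == qpcr.FLAG_UNDETECTED).all()
        )
        scaled = mk.scale_log2cpm(log2cpm.loc[m, seq_samples], actb)
        measured = flags.index[flags[m] == qpcr.FLAG_MEASURED]
        dcq = delta_cq.loc[delta_cq.index.intersection(measured), m]
        dcq = dcq[dcq.index.intersection(seq_samples)]
        if dcq.empty:
            results.append(
                mk.MarkerValidation(
                    m, None, controls_absent, controls_absent,
                    "no detected qPCR signal" if not controls_absent else
                    "absent in controls",
                )
            )
            continue
        reversed_dcq = mk.reverse_delta_cq(dcq)
        results.append(
            mk.validate_marker(
                m, scaled, reversed_dcq,
                r2_min=config.r2_min, controls_absent=controls_absent,
            )
        )
    return mk.validation_table(results)


def run_pipeline(
    log2cpm: pd.DataFrame,
    meta: pd.DataFrame,
    cq_measurements: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """The full analysis from matrices to the evaluation report.

    ``log2cpm`` is a junction × sample matrix including the reference
    junction; ``cq_measurements`` the long replicate table for the assayed
    markers plus the reference.
    """
    config = config or PipelineConfig()
    admissions = screen_candidates(log2cpm, meta, config)
    candidates = mk.candidate_ids(admissions)

    assayed = [
        m for m in cq_measurements["marker"].unique()
        if m != config.reference_marker
    ]
    benign_train = split_samples(meta, "Benign", "train")
    delta_cq, flags, cutoffs = qpcr.preprocess_cq(
        cq_measurements,
        benign_train_samples=benign_train,
        markers=list(assayed),
        reference_marker=config.reference_marker,
        undetected_value=config.undetected_value,
        strategy=config.nonspecific_strategy,
        percentile=config.nonspecific_percentile,
        actb_window=tuple(config.actb_window),
    )

    validations = validate_candidates(
        candidates, log2cpm, delta_cq, flags, meta, config
    )
    selected = validations.loc[validations["selected"], "marker"].tolist()

    variables = scoring.build_variables(
        config.individual_markers,
        config.composite_members,
        config.composite_divisor,
        available_markers=selected,
    )
    train_ids = split_samples(meta, ["OC", "Benign"], "train")
    panel = scoring.fit_panel(
        delta_cq.loc[train_ids],
        meta.loc[train_ids, "group"],
        variables,
        nonspecific_cutoffs=cutoffs,
        target_specificity=config.target_specificity,
        cutoff_delta=config.cutoff_delta,
        undetected_value=config.undetected_value,
        reference_marker=config.reference_marker,
        negative_slope=config.negative_slope,
        zero_score_is_cancer=config.zero_score_is_cancer,
    )

    scores = scoring.score_samples(delta_cq, panel)
    reports = evaluate_splits(scores, meta)
    return PipelineResult(
        admissions=admissions,
        validations=validations,
        panel=panel,
        delta_cq=delta_cq,
        flags=flags,
        scores=scores,
        reports=reports,
    )


def evaluate_splits(scores: pd.DataFrame, meta: pd.DataFrame) -> dict[str, EvalReport]:
    """Reports for the training 2×2, the test 2×2 (borderline tumors kept
    aside), the pooled asymptomatic-control specificity and the pooled
    total over everything but the borderline tumors."""
    groups = meta["group"]
    train_ids = split_samples(meta, ["OC", "Benign"], "train")
    test_ids = split_samples(meta, ["OC", "Benign", "BOT"], "test")
    ac_ids = meta.index[groups == "AC"].tolist()
    reports = {
        "train": evaluate(scores.loc[train_ids], groups.loc[train_ids]),
        "test": evaluate(scores.loc[test_ids], groups.loc[test_ids]),
        "ac_validation": evaluate(scores.loc[ac_ids], groups.loc[ac_ids]),
        "total": evaluate(scores, groups),
    }
    return reports
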