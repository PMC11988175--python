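"""Pipeline configuration.

Every constant of the scoring algorithm (the 41-cycle undetected sentinel,
the 99% target specificity, the candidate-screen threshold grid, the R²
floor, the composite divisor, the tanh / x/10 transform) is surfaced here
so that a single declarative file fully determines a run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

GROUPS = ("AC", "Benign", "OC", "BOT")
SPLITS = ("train", "test", "validation")

#: Default panel partition: five individual variables plus one composite
#: variable that sums the ΔCq of the IL1R2/DEFA marker family.
DEFAULT_INDIVIDUAL_MARKERS = ("FMO2_a", "CD177_a", "TCN2_a", "NPRL3_a", "GCKR_a")
DEFAULT_COMPOSITE_MEMBERS = ("IL1R2_a", "IL1R2_b", "DEFA1_a", "DEFA1B_a", "DEFA3_a")


@dataclass
class PipelineConfig:
    """All tunable parameters of the junction-marker qPCR pipeline.

    Attributes
    ----------
    thresholds
        log2CPM thresholds of the candidate screen (controls must sit below).
    control_fractions
        Required fractions of control samples below the threshold; the screen
        takes the union over the ``thresholds × control_fractions`` grid.
    case_margin, min_case_count, case_rule
        Operationalisation of "at least one cancer sample with distinctly
        high expression": with ``case_rule='above_threshold'`` a case counts
        if its log2CPM ≥ threshold + margin; ``'outlier'`` uses the Tukey
        upper fence of the control distribution instead.
    r2_min
        Minimum coefficient of determination between scaled log2CPM and
        reversed ΔCq for a marker to validate (bypassed when the marker is
        entirely undetected in controls).
    target_specificity
        Training specificity the per-variable scoring cutoffs must guarantee.
    undetected_value
        Cq sentinel assigned to undetected / censored reactions (cycles).
    composite_divisor
        Divisor applied to the composite variable's cutoff distance.
    negative_slope
        Slope of the linear branch of the score transform for x < 0.
    flank, span_mode
        Intron-spanning-read criteria: exonic window length on each side of
        the junction and whether aligned blocks must merely overlap the
        windows or contain them.
    cpm_denominator
        ``'junction_reads'`` (annotation-matched spliced reads, default) or
        ``'primary_reads'`` (all primary mapped reads).
    """

    thresholds: Sequence[float] = (0.2, 0.3, 0.4, 0.5)
    control_fractions: Sequence[float] = (0.70, 0.75, 0.80, 0.85, 0.90, 0.95)
    case_rule: str = "above_threshold"
    case_margin: float = 1.0
    min_case_count: int = 1
    r2_min: float = 0.4
    target_specificity: float = 0.99
    cutoff_delta: float = 0.5
    undetected_value: float = 41.0
    undetected_token: str = "ND"
    nonspecific_strategy: str = "max"
    nonspecific_percentile: float = 0.95
    reference_marker: str = "ACTB"
    individual_markers: Sequence[str] = DEFAULT_INDIVIDUAL_MARKERS
    composite_members: Sequence[str] = DEFAULT_COMPOSITE_MEMBERS
    composite_divisor: float = 5.0
    negative_slope: float = 0.1
    pseudocount: float = 1.0
    flank: int = 150
    span_mode: str = "overlap"
    cpm_denominator: str = "junction_reads"
    enforce_strand: bool = False
    censor_before_average: bool = False
    zero_score_is_cancer: bool = False
    actb_window: Sequence[float] = (17.25, 20.88)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.thresholds or any(t <= 0 for t in self.thresholds):
            raise ValueError("thresholds must be non-empty and positive")
        if any(not 0 < f <= 1 for f in self.control_fractions):
            raise ValueError("control_fractions must lie in (0, 1]")
        if not 0 < self.target_specificity <= 1:
            raise ValueError("target_specificity must lie in (0, 1]")
        if not 0 <= self.r2_min <= 1:
            raise ValueError("r2_min must lie in [0, 1]")
        if self.min_case_count < 1:
            raise ValueError("min_case_count must be >= 1")
        if self.undetected_value <= 0:
            raise ValueError("undetected_value must be positive")
        if self.composite_divisor <= 0:
            raise ValueError("composite_divisor must be positive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.case_rule not in ("above_threshold", "outlier"):
            raise ValueError(f"unknown case_rule {self.case_rule!r}")
        if self.span_mode not in ("overlap", "containment"):
            raise ValueError(f"unknown span_mode {self.span_mode!r}")
        if self.cpm_denominator not in ("junction_reads", "primary_reads"):
            raise ValueError(f"unknown cpm_denominator {self.cpm_denominator!r}")
        if self.nonspecific_strategy not in ("max", "percentile"):
            raise ValueError(f"unknown nonspecific_strategy {self.nonspecific_strategy!r}")
        overlap = set(self.individual_markers) & set(self.composite_members)
        if overlap:
            raise ValueError(f"markers assigned to both partitions: {sorted(overlap)}")

    @property
    def panel_markers(self) -> list[str]:
        return list(self.individual_markers) + list(self.composite_members)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
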