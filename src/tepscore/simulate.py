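"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the study design end to end: a 90-sample cohort
(13 OC / 16 Benign / 32 AC in training, 4 OC / 21 Benign / 2 BOT in test,
2 held-out AC completing the 34-control validation set), junction count
matrices in which planted cancer-specific junctions are silent in controls
apart from a small leak rate but strongly expressed in a subset of cancer
samples, spliced SAM alignments that reproduce exactly the planted counts
under the intron-spanning-read criteria, and duplicate qPCR Cq measurements
linearly coupled to sequencing expression with noise and late-cycle
dropout. Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .config import DEFAULT_COMPOSITE_MEMBERS, DEFAULT_INDIVIDUAL_MARKERS
from .junctions import JunctionCountMatrix, SpliceJunction

#: Cohort partition mirroring the study: 90 samples in total; the 32
#: training AC plus 2 validation AC form the 34-control validation set.
DEFAULT_GROUP_SIZES: dict[tuple[str, str], int] = {
    ("OC", "train"): 13,
    ("Benign", "train"): 16,
    ("AC", "train"): 32,
    ("OC", "test"): 4,
    ("Benign", "test"): 21,
    ("BOT", "test"): 2,
    ("AC", "validation"): 2,
}

DEFAULT_MARKER_NAMES = DEFAULT_INDIVIDUAL_MARKERS + DEFAULT_COMPOSITE_MEMBERS


@dataclass
class SyntheticCohortConfig:
    """Generator parameters; defaults are the study conditions.

    ``marker_effect`` is the mean log2CPM of a planted marker in an
    expressing cancer sample (multiplicative log-normal spread), so 0 turns
    the markers off entirely — the null configuration. The seq→Cq link is
    linear in log2 expression with slope ``seq_pcr_slope`` (cycles per
    doubling), and replicates above ``dropout_cq`` cycles are undetected.
    """

    group_sizes: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_background_junctions: int = 500
    marker_names: tuple[str, ...] = DEFAULT_MARKER_NAMES
    marker_effect: float = 5.0          # log2CPM in expressing cancer samples
    marker_effect_log_sd: float = 0.3   # log-normal spread of that level
    expressing_fraction: float = 0.75   # P(an OC sample expresses a marker)
    control_leak_rate: float = 0.05     # P(a control shows trace expression)
    leak_level: float = 0.5             # mean trace log2CPM
    leak_level_sd: float = 0.3
    bot_oc_like_prob: float = 0.5       # BOT samples draw OC-like expression
    background_cpm_range: tuple[float, float] = (2.0, 500.0)
    background_dispersion: float = 10.0  # negative-binomial size parameter
    library_size_mean: float = 2.0e6    # junction-supporting reads per sample
    library_size_log_sd: float = 0.2
    actb_log2cpm_mean: float = 13.3     # reference junction expression
    actb_log2cpm_sd: float = 0.2
    actb_cq_mean: float = 19.0          # within the plausible 17.25-20.88 window
    actb_cq_sd: float = 0.6
    cq_baseline: float = 9.0            # Cq offset of a marker at ACTB-level expression
    seq_pcr_slope: float = 1.0          # cycles per log2CPM unit
    seq_pcr_noise_sd: float = 0.8       # per (sample, marker) latent Cq noise
    replicate_noise_sd: float = 0.15    # per-replicate technical noise
    dropout_cq: float = 40.0            # latent Cq above which signal is undetected
    reference_marker: str = "ACTB"
    chrom: str = "chr1"
    intron_length: int = 100
    junction_spacing: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be non-negative")
        for frac in (self.expressing_fraction, self.control_leak_rate,
                     self.bot_oc_like_prob):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.marker_effect < 0 or self.seq_pcr_noise_sd < 0:
            raise ValueError("effect and noise parameters must be non-negative")


@dataclass
class SimulatedDataset:
    meta: pd.DataFrame
    counts: JunctionCountMatrix
    junctions: list[SpliceJunction]
    cq: pd.DataFrame
    expressing: pd.DataFrame  # bool, marker × sample ground truth


def generate_cohort(config: SyntheticCohortConfig) -> pd.DataFrame:
    """Sample metadata; ids encode group and split, institutions follow the
    study's collection pattern (controls from one site)."""
    rows = []
    for (group, split), n in sorted(config.group_sizes.items()):
        for i in range(1, n + 1):
            inst = "HGU" if group == "AC" else ("SNUH" if i % 2 else "MJH")
            rows.append(
                {
                    "sample_id": f"{group}-{split}-{i:02d}",
                    "group": group,
                    "split": split,
                    "institution": inst,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def _expressing_states(
    meta: pd.DataFrame, config: SyntheticCohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Ground-truth marker expression states per (marker, sample)."""
    markers = list(config.marker_names)
    states = pd.DataFrame(False, index=markers, columns=meta.index)
    oc_like = {}
    for sample, rec in meta.iterrows():
        if rec["group"] == "OC":
            oc_like[sample] = True
        elif rec["group"] == "BOT":
            oc_like[sample] = bool(rng.random() < config.bot_oc_like_prob)
        else:
            oc_like[sample] = False
    for sample in meta.index:
        p = config.expressing_fraction if oc_like[sample] else config.control_leak_rate
        states[sample] = rng.random(len(markers)) < p
    return states


def simulate_junction_counts(
    meta: pd.DataFrame,
    config: SyntheticCohortConfig,
    rng: np.random.Generator | None = None,
) -> tuple[JunctionCountMatrix, pd.DataFrame]:
    """Junction × sample ISR counts.

    Background junctions share one over-dispersed negative-binomial model
    across groups; planted marker junctions are zero in non-expressing
    samples, trace-level in leaking controls and elevated (mean
    ``marker_effect`` log2CPM) in expressing cancer-like samples; the
    reference junction is highly expressed everywhere. The recorded library
    size is the nominal genome-wide junction-read total: the simulated
    junctions stand for a small subset of the annotation, so normalising
    against their column sum alone would inflate every CPM value.
    Returns (matrix, ground-truth expressing states).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    samples = list(meta.index)
    n_s = len(samples)
    markers = list(config.marker_names)
    expressing = _expressing_states(meta, config, rng)

    nominal_lib = np.exp(
        rng.normal(np.log(config.library_size_mean), config.library_size_log_sd, n_s)
    )

    def level_to_counts(level: np.ndarray) -> np.ndarray:
        lam = (2.0 ** level - 1.0) * nominal_lib / 1e6
        return rng.poisson(np.clip(lam, 0, None))

    # reference junction
    actb_level = rng.normal(config.actb_log2cpm_mean, config.actb_log2cpm_sd, n_s)
    rows = {config.reference_marker: level_to_counts(actb_level)}

    # planted markers
    for m in markers:
        expr = expressing.loc[m].to_numpy()
        oc_like = meta["group"].isin(["OC", "BOT"]).to_numpy()
        level = np.zeros(n_s)
        is_marker = expr & oc_like
        is_leak = expr & ~oc_like
        level[is_marker] = config.marker_effect * np.exp(
            rng.normal(0.0, config.marker_effect_log_sd, int(is_marker.sum()))
        )
        level[is_leak] = np.clip(
            rng.normal(config.leak_level, config.leak_level_sd, int(is_leak.sum())),
            0.0, None,
        )
        rows[m] = level_to_counts(level)

    # background junctions: identical model in every group
    n_bg = config.n_background_junctions
    lo, hi = config.background_cpm_range
    mean_cpm = np.exp(rng.uniform(np.log(lo), np.log(hi), n_bg))
    lam = mean_cpm[:, None] * nominal_lib[None, :] / 1e6
    r = config.background_dispersion
    bg = rng.negative_binomial(r, r / (r + lam))
    counts = pd.DataFrame(rows, index=samples).T
    bg_ids = [f"bg_{i:05d}" for i in range(n_bg)]
    counts = pd.concat(
        [counts, pd.DataFrame(bg, index=bg_ids, columns=samples)]
    ).astype(np.int64)

    library = pd.Series(np.round(nominal_lib).astype(np.int64), index=samples)
    matrix = JunctionCountMatrix(counts=counts, library_size=library)
    return matrix, expressing


def junction_annotation(config: SyntheticCohortConfig) -> list[SpliceJunction]:
    """Genomic coordinates for every simulated junction, evenly spaced on
    one synthetic chromosome."""
    ids = [config.reference_marker, *config.marker_names] + [
        f"bg_{i:05d}" for i in range(config.n_background_junctions)
    ]
    juncs = []
    for i, jid in enumerate(ids):
        start = 10_000 + i * config.junction_spacing
        juncs.append(
            SpliceJunction(
                chrom=config.chrom,
                intron_start=start,
                intron_end=start + config.intron_length - 1,
                strand="+",
                junction_id=jid,
            )
        )
    return juncs


def generate_spliced_alignments(
    junctions: list[SpliceJunction],
    planted_counts: pd.Series,
    path: str | Path,
    read_length: int = 150,
    decoys: bool = True,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> None:
    """Write a SAM file holding exactly the planted intron-spanning reads.

    Per junction, ``planted_counts[junction_id]`` reads are emitted whose N
    gap equals the intron and whose aligned blocks overlap both flank
    windows. With ``decoys=True`` each junction additionally receives reads
    that must *not* be counted: gap shifted by ±1 bp, a gapless read over
    the same locus, and a secondary-flagged copy of a valid read.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    if read_length < 2:
        raise ValueError("read_length must be >= 2")
    max_pos = max(j.intron_end for j in junctions) + read_length + 1000
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": c, "LN": max_pos}
                for c in dict.fromkeys(j.chrom for j in junctions)
            ],
        }
    )
    tid = {sq["SN"]: i for i, sq in enumerate(header.to_dict()["SQ"])}

    def segment(name, chrom, pos1, cigar, flag=0):
        a = pysam.AlignedSegment(header)
        a.query_name = name
        a.flag = flag
        a.reference_id = tid[chrom]
        a.reference_start = pos1 - 1
        a.mapping_quality = 60
        a.cigarstring = cigar
        qlen = sum(l for op, l in a.cigartuples if op in (0, 1, 4, 7, 8))
        a.query_sequence = "A" * qlen
        return a

    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for j in junctions:
            n = int(planted_counts.get(j.junction_id, 0))
            intron_len = j.intron_end - j.intron_start + 1
            min_left = 1
            if j.intron_start - min_left < 1:
                raise ValueError(
                    f"junction {j.junction_id}: no room to place a read upstream"
                )
            lo = max(1, min(20, read_length - 1))
            hi = min(read_length - 1, j.intron_start - 1)
            if lo > hi:
                raise ValueError(
                    f"junction {j.junction_id}: read placement impossible"
                )
            for i in range(n):
                a_len = int(rng.integers(lo, hi + 1))
                b_len = read_length - a_len
                pos = j.intron_start - a_len
                out.write(
                    segment(
                        f"{j.junction_id}.r{i}", j.chrom, pos,
                        f"{a_len}M{intron_len}N{b_len}M",
                    )
                )
            if decoys:
                a_len = min(75, hi)
                b_len = read_length - a_len
                pos = j.intron_start - a_len
                cigar = f"{a_len}M{intron_len}N{b_len}M"
                out.write(segment(f"{j.junction_id}.shift+1", j.chrom, pos + 1, cigar))
                if pos > 1:
                    out.write(
                        segment(f"{j.junction_id}.shift-1", j.chrom, pos - 1, cigar)
                    )
                out.write(
                    segment(f"{j.junction_id}.gapless", j.chrom, pos, f"{read_length}M")
                )
                out.write(
                    segment(f"{j.junction_id}.secondary", j.chrom, pos, cigar, flag=256)
                )


def simulate_cq(
    meta: pd.DataFrame,
    log2cpm: pd.DataFrame,
    config: SyntheticCohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Duplicate qPCR Cq measurements coupled to sequencing expression.

    The latent Cq of marker m in sample s is

        Cq_ACTB(s) + baseline − slope · (log2CPM_m(s) − log2CPM_ACTB(s)) + ε,

    with ε ~ N(0, seq_pcr_noise_sd); each of the two replicates adds
    independent technical noise, and a replicate above ``dropout_cq`` is
    reported undetected. The reference marker is always detected.
    Returns the long replicate table (sample_id, marker, replicate, cq,
    undetected).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    markers = list(config.marker_names)
    ref = config.reference_marker
    missing = [m for m in markers + [ref] if m not in log2cpm.index]
    if missing:
        raise ValueError(f"expression missing for markers: {missing}")

    records = []
    for sample in meta.index:
        actb_cq = rng.normal(config.actb_cq_mean, config.actb_cq_sd)
        for rep in (1, 2):
            records.append(
                {
                    "sample_id": sample, "marker": ref, "replicate": rep,
                    "cq": actb_cq + rng.normal(0, config.replicate_noise_sd),
                    "undetected": False,
                }
            )
        for m in markers:
            scaled = log2cpm.at[m, sample] - log2cpm.at[ref, sample]
            latent = (
                actb_cq
                + config.cq_baseline
                - config.seq_pcr_slope * scaled
                + rng.normal(0, config.seq_pcr_noise_sd)
            )
            for rep in (1, 2):
                value = latent + rng.normal(0, config.replicate_noise_sd)
                undet = value > config.dropout_cq
                records.append(
                    {
                        "sample_id": sample, "marker": m, "replicate": rep,
                        "cq": np.nan if undet else value,
                        "undetected": undet,
                    }
                )
    return pd.DataFrame(records)


def simulate_dataset(config: SyntheticCohortConfig) -> SimulatedDataset:
    """One complete synthetic study: metadata, counts, junction coordinates
    and the replicate Cq table, deterministic in ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    meta = generate_cohort(config)
    counts, expressing = simulate_junction_counts(meta, config, rng)
    juncs = junction_annotation(config)
    log2cpm = counts.log2cpm()
    cq = simulate_cq(meta, log2cpm, config, rng)
    return SimulatedDataset(
        meta=meta, counts=counts, junctions=juncs, cq=cq, expressing=expressing
    )
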