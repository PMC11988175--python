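"""Intron-spanning-read (ISR) quantification of annotated splice junctions.

A read counts toward a junction when three criteria hold simultaneously:

1. its CIGAR contains at least one ``N`` operation (a splicing gap);
2. some ``N`` gap's genomic interval equals the junction's intron exactly;
3. its aligned blocks reach into the exonic flank window (default 150 bp)
   on both sides of the junction.

Only primary alignments are eligible. Counts are normalised to CPM against
a per-sample library size and log2-transformed with a pseudocount, which is
the scale on which the candidate-marker screen operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

STRANDS = ("+", "-", ".")

# CIGAR operation codes (pysam numeric encoding)
_REF_CONSUMING = {0, 2, 7, 8}  # M, D, =, X
_N_OP = 3


@dataclass(frozen=True)
class SpliceJunction:
    """One intron: 1-based inclusive genomic interval of the removed sequence."""

    chrom: str
    intron_start: int
    intron_end: int
    strand: str = "."
    junction_id: str = ""

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise ValueError(
                f"junction {self.junction_id or self.key}: intron_start > intron_end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.intron_start, self.intron_end)


@dataclass
class JunctionCountMatrix:
    """Junction × sample ISR counts with per-sample library sizes."""

    counts: pd.DataFrame          # junction_id × sample_id, integer
    library_size: pd.Series       # per sample

    def __post_init__(self) -> None:
        self.library_size = self.library_size.reindex(self.counts.columns)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.library_size.isna().any():
            missing = self.library_size[self.library_size.isna()].index.tolist()
            raise ValueError(f"missing library size for samples: {missing}")

    @property
    def junction_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def cpm(self) -> pd.DataFrame:
        return compute_cpm(self)

    def log2cpm(self, pseudocount: float = 1.0) -> pd.DataFrame:
        return log2_cpm(self.cpm(), pseudocount)


@dataclass
class CountingStats:
    """Bookkeeping from one counting pass over an alignment file."""

    primary_reads: int = 0
    junction_reads: int = 0            # distinct reads with >= 1 matched gap
    unknown_chrom_reads: int = 0       # skipped with a warning count, not an error
    gapped_reads: int = 0              # primary reads with an N in the CIGAR


def _gaps_and_blocks(
    ref_start0: int, cigartuples: Sequence[tuple[int, int]]
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Walk a CIGAR from a 0-based reference start.

    Returns (gaps, blocks), both as 1-based inclusive intervals: ``gaps`` are
    the N-skipped intron intervals, ``blocks`` the maximal aligned segments
    between them (deletions do not split a block).
    """
    gaps: list[tuple[int, int]] = []
    blocks: list[tuple[int, int]] = []
    pos = ref_start0  # 0-based
    block_start: int | None = None
    for op, length in cigartuples:
        if op == _N_OP:
            if block_start is not None:
                blocks.append((block_start + 1, pos))
                block_start = None
            gaps.append((pos + 1, pos + length))
            pos += length
        elif op in _REF_CONSUMING:
            if block_start is None:
                block_start = pos
            pos += length
        # I, S, H, P: no reference consumption
    if block_start is not None:
        blocks.append((block_start + 1, pos))
    return gaps, blocks


def _spans_flanks(
    blocks: Sequence[tuple[int, int]],
    junction: SpliceJunction,
    flank: int,
    mode: str,
) -> bool:
    donor_lo = max(1, junction.intron_start - flank)
    donor = (donor_lo, junction.intron_start - 1)
    acceptor = (junction.intron_end + 1, junction.intron_end + flank)
    if donor[0] > donor[1]:  # junction at the chromosome edge
        return False

    def overlap(window: tuple[int, int]) -> int:
        return sum(
            max(0, min(b_end, window[1]) - max(b_start, window[0]) + 1)
            for b_start, b_end in blocks
        )

    if mode == "overlap":
        return overlap(donor) >= 1 and overlap(acceptor) >= 1
    # containment: the aligned blocks must cover each window entirely
    return overlap(donor) == donor[1] - donor[0] + 1 and overlap(acceptor) == flank


def count_isr(
    alignments: str | Path | pysam.AlignmentFile,
    junctions: Iterable[SpliceJunction],
    flank: int = 150,
    span_mode: str = "overlap",
    enforce_strand: bool = False,
    cpm_denominator: str = "junction_reads",
) -> tuple[pd.Series, CountingStats]:
    """Count intron-spanning reads per junction for one sample.

    Parameters
    ----------
    alignments
        SAM/BAM path or an open :class:`pysam.AlignmentFile`.
    flank
        Length of the exonic window on each side of the junction (bp).
    span_mode
        ``'overlap'``: aligned blocks must overlap each flank window by at
        least one base; ``'containment'``: they must cover it entirely.
    cpm_denominator
        What the accompanying library size counts: annotation-matched
        junction-supporting reads (default) or all primary mapped reads.

    Returns
    -------
    counts
        Series indexed by junction_id.
    stats
        :class:`CountingStats`; ``stats.junction_reads`` or
        ``stats.primary_reads`` is the CPM denominator.
    """
    junctions = list(junctions)
    index: dict[tuple[str, int, int], list[SpliceJunction]] = {}
    for j in junctions:
        index.setdefault(j.key, []).append(j)
    known_chroms = {j.chrom for j in junctions}

    counts = pd.Series(0, index=[j.junction_id for j in junctions], dtype=np.int64)
    if counts.index.has_duplicates:
        dups = counts.index[counts.index.duplicated()].tolist()
        raise ValueError(f"duplicate junction_id: {dups}")
    stats = CountingStats()

    own_handle = not isinstance(alignments, pysam.AlignmentFile)
    af = (
        pysam.AlignmentFile(str(alignments), check_sq=False)
        if own_handle
        else alignments
    )
    try:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            stats.primary_reads += 1
            if read.reference_name not in known_chroms:
                stats.unknown_chrom_reads += 1
                continue
            cig = read.cigartuples
            if cig is None:
                raise ValueError(f"read {read.query_name}: mapped but no CIGAR")
            if not any(op == _N_OP for op, _ in cig):
                continue
            stats.gapped_reads += 1
            read_strand = "-" if read.is_reverse else "+"
            matched = False
            gaps, blocks = _gaps_and_blocks(read.reference_start, cig)
            for gap in gaps:
                for j in index.get((read.reference_name, gap[0], gap[1]), ()):
                    if enforce_strand and j.strand in "+-" and j.strand != read_strand:
                        continue
                    if _spans_flanks(blocks, j, flank, span_mode):
                        counts[j.junction_id] += 1
                        matched = True
            if matched:
                stats.junction_reads += 1
    finally:
        if own_handle:
            af.close()
    return counts, stats


def count_isr_matrix(
    sample_files: Mapping[str, str | Path],
    junctions: Iterable[SpliceJunction],
    **kwargs,
) -> JunctionCountMatrix:
    """Run :func:`count_isr` over several samples and assemble the matrix."""
    junctions = list(junctions)
    denominator = kwargs.get("cpm_denominator", "junction_reads")
    cols, libs = {}, {}
    for sample_id, path in sample_files.items():
        counts, stats = count_isr(path, junctions, **kwargs)
        cols[sample_id] = counts
        libs[sample_id] = (
            stats.junction_reads
            if denominator == "junction_reads"
            else stats.primary_reads
        )
    counts = pd.DataFrame(cols)
    return JunctionCountMatrix(counts=counts, library_size=pd.Series(libs))


def compute_cpm(matrix: JunctionCountMatrix) -> pd.DataFrame:
    """Counts per million: count / library_size × 1e6, per sample column."""
    zero = matrix.library_size[matrix.library_size == 0]
    if len(zero):
        raise ValueError(f"library size is zero for samples: {zero.index.tolist()}")
    return matrix.counts.div(matrix.library_size, axis=1) * 1e6


def log2_cpm(cpm: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(CPM + pseudocount); with the default pseudocount zero maps to 0."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (cpm.to_numpy() < 0).any():
        raise ValueError("CPM values must be non-negative")
    return np.log2(cpm + pseudocount)
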