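"""Readers and writers for the pipeline's external formats.

All tabular formats are plain delimited text (TSV by default, CSV detected
by extension): sample metadata, replicate Cq tables, junction count and
log2CPM matrices, ΔCq matrices, score tables and metric reports. Junction
annotations are read from BED6 (0-based half-open intron intervals) or GTF
(introns derived between consecutive exons of each transcript). The fitted
panel model is serialised as human-readable YAML.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .config import GROUPS, SPLITS
from .junctions import JunctionCountMatrix, SpliceJunction


def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# sample metadata

def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata; index = sample_id, columns group/split[/institution].

    Group must be one of AC / Benign / OC / BOT and split one of
    train / test / validation; violations raise naming the offending row.
    """
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    required = {"sample_id", "group", "split"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        if rec.group not in GROUPS:
            raise ValueError(f"metadata row {row}: unknown group {rec.group!r}")
        if rec.split not in SPLITS:
            raise ValueError(f"metadata row {row}: unknown split {rec.split!r}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id in metadata: {dup.tolist()}")
    if "institution" not in df.columns:
        df["institution"] = ""
    return df.set_index("sample_id")[["group", "split", "institution"]]


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep=_sep(path), index_label="sample_id")


# ---------------------------------------------------------------------------
# replicate Cq tables

def read_cq_table(path: str | Path, undetected_token: str = "ND") -> pd.DataFrame:
    """Read a replicate-level Cq table.

    Columns: sample_id, marker, replicate, cq. The undetected token becomes
    an explicit boolean ``undetected`` column with NaN in ``cq`` — the
    41-cycle sentinel is a preprocessing decision, not a storage format.
    """
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    required = {"sample_id", "marker", "replicate", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Cq table is missing columns: {sorted(missing)}")
    undetected = df["cq"].str.strip() == undetected_token
    cq = pd.to_numeric(df["cq"].where(~undetected), errors="coerce")
    bad = ~undetected & cq.isna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise ValueError(f"Cq table row {row}: non-numeric Cq {df['cq'][bad].iloc[0]!r}")
    if (cq <= 0).any():
        row = int(np.flatnonzero((cq <= 0).to_numpy())[0]) + 1
        raise ValueError(f"Cq table row {row}: Cq must be positive")
    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"],
            "marker": df["marker"],
            "replicate": pd.to_numeric(df["replicate"]).astype(int),
            "cq": cq,
            "undetected": undetected,
        }
    )
    return out


def write_cq_table(
    cq: pd.DataFrame, path: str | Path, undetected_token: str = "ND"
) -> None:
    out = cq.copy()
    text = out["cq"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out["cq"] = text.where(~out["undetected"], undetected_token)
    out[["sample_id", "marker", "replicate", "cq"]].to_csv(
        path, sep=_sep(path), index=False
    )


# ---------------------------------------------------------------------------
# junction annotation

def read_junction_annotation(
    path: str | Path, dialect: str = "bed"
) -> list[SpliceJunction]:
    """Read junctions from BED6 intron intervals or GTF exon records.

    Either way junctions are normalised to the internal 1-based inclusive
    intron convention and deduplicated on (chrom, start, end, strand).
    """
    if dialect == "bed":
        juncs = _read_bed_junctions(path)
    elif dialect == "gtf":
        juncs = _read_gtf_junctions(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    seen: dict[tuple, SpliceJunction] = {}
    for j in juncs:
        seen.setdefault((j.chrom, j.intron_start, j.intron_end, j.strand), j)
    return list(seen.values())


def _read_bed_junctions(path: str | Path) -> Iterable[SpliceJunction]:
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
        chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else f"{chrom}:{start0 + 1}-{end0}"
        strand = fields[5] if len(fields) > 5 else "."
        if strand not in "+-.":
            raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
        # BED 0-based half-open -> 1-based inclusive
        intron_start, intron_end = start0 + 1, end0
        if intron_start > intron_end:
            raise ValueError(f"{path}:{lineno}: empty interval after normalisation")
        yield SpliceJunction(chrom, intron_start, intron_end, strand, name)


def _read_gtf_junctions(path: str | Path) -> Iterable[SpliceJunction]:
    # exons grouped per transcript_id; introns are the gaps between
    # consecutive exons in genomic order
    exons: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise ValueError(f"{path}:{lineno}: fewer than 9 GTF fields")
        chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
        if feature != "exon":
            continue
        if strand not in "+-.":
            raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
        tid = None
        for attr in attrs.split(";"):
            attr = attr.strip()
            if attr.startswith("transcript_id"):
                tid = attr.split(None, 1)[1].strip().strip('"')
                break
        if tid is None:
            raise ValueError(f"{path}:{lineno}: exon without transcript_id")
        exons.setdefault((chrom, strand, tid), []).append((int(start), int(end)))
    for (chrom, strand, tid), spans in exons.items():
        spans.sort()
        for i, ((_, left_end), (right_start, _)) in enumerate(
            zip(spans, spans[1:]), start=1
        ):
            intron_start, intron_end = left_end + 1, right_start - 1
            if intron_start > intron_end:
                raise ValueError(
                    f"transcript {tid}: empty intron between exons {i} and {i + 1}"
                )
            yield SpliceJunction(
                chrom, intron_start, intron_end, strand,
                f"{chrom}:{intron_start}-{intron_end}:{strand}",
            )


def write_junction_bed(junctions: Iterable[SpliceJunction], path: str | Path) -> None:
    lines = [
        f"{j.chrom}\t{j.intron_start - 1}\t{j.intron_end}\t{j.junction_id}\t0\t{j.strand}"
        for j in junctions
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# matrices

def write_count_matrix(matrix: JunctionCountMatrix, path: str | Path) -> None:
    """Counts with a trailing library_size row, junction_id key column."""
    out = matrix.counts.copy()
    out.loc["__library_size__"] = matrix.library_size
    out.to_csv(path, sep=_sep(path), index_label="junction_id")


def read_count_matrix(path: str | Path) -> JunctionCountMatrix:
    df = pd.read_csv(path, sep=_sep(path), index_col="junction_id")
    if "__library_size__" not in df.index:
        raise ValueError("count matrix lacks the __library_size__ row")
    lib = df.loc["__library_size__"].astype(np.int64)
    counts = df.drop(index="__library_size__").astype(np.int64)
    return JunctionCountMatrix(counts=counts, library_size=lib)


def write_value_matrix(values: pd.DataFrame, path: str | Path, index_label: str) -> None:
    values.to_csv(path, sep=_sep(path), index_label=index_label)


def read_value_matrix(path: str | Path, index_label: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep(path), index_col=index_label)


def write_delta_cq(values: pd.DataFrame, flags: pd.DataFrame, path: str | Path) -> None:
    """ΔCq matrix (samples × markers) with per-cell provenance flags."""
    stacked = values.stack().rename("delta_cq").to_frame()
    stacked["flag"] = flags.stack()
    stacked.index.names = ["sample_id", "marker"]
    stacked.reset_index().to_csv(path, sep=_sep(path), index=False)


def read_delta_cq(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    long = pd.read_csv(path, sep=_sep(path))
    values = long.pivot(index="sample_id", columns="marker", values="delta_cq")
    flags = long.pivot(index="sample_id", columns="marker", values="flag")
    return values, flags


# ---------------------------------------------------------------------------
# report

def write_report(
    out_dir: str | Path,
    scores: pd.DataFrame,
    reports: dict,
    config: dict | None = None,
) -> None:
    """Write per-sample scores, per-split confusion matrices and metrics.

    ``reports`` maps a split name to an :class:`~tepscore.evaluation.EvalReport`.
    Deterministic content: rerunning with the same inputs reproduces the
    files byte for byte.
    """
    if scores.empty:
        raise ValueError("no samples to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scores.to_csv(out / "scores.tsv", sep="\t", index_label="sample_id")

    rows = []
    cm_lines = []
    for name in sorted(reports):
        rep = reports[name]
        d = rep.to_dict()
        d["dataset"] = name
        rows.append(d)
        cm = rep.confusion
        cm_lines += [
            f"# {name}",
            "\tactual_OC\tactual_nonOC",
            f"pred_OC\t{cm.tp}\t{cm.fp}",
            f"pred_nonOC\t{cm.fn}\t{cm.tn}",
            "",
        ]
    metrics = pd.DataFrame(rows).set_index("dataset")
    metrics.to_csv(out / "metrics.tsv", sep="\t", float_format="%.6f")
    (out / "confusion_matrices.tsv").write_text("\n".join(cm_lines))
    if config is not None:
        (out / "run_config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
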