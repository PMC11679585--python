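"""Readers and writers for the text formats the pipeline touches.

Methylation call tables come in the methylKit text dialect (``chrBase chr
base strand coverage freqC freqT``) or the bsmap-methratio dialect.  Call
tables use 1-based cytosine coordinates; every interval format (BED,
bedGraph) is 0-based half-open.  Conversion between the two conventions
happens here, at the I/O boundary, and nowhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, UsageError, ValidationError

CONDITIONS = ("S", "R", "RC")

GENE_TYPES = frozenset(
    {"protein_coding", "lncRNA", "miRNA", "rRNA", "tRNA", "pseudogene", "other"}
)

_METHYLKIT_HEADER = ["chrBase", "chr", "base", "strand", "coverage", "freqC", "freqT"]

#: columns of a SampleTable's backing frame
CALL_COLUMNS = ["chrom", "pos", "strand", "coverage", "meth_count", "meth_pct"]


def pos_to_zero(pos):
    """1-based cytosine coordinate -> 0-based offset."""
    return pos - 1


def zero_to_pos(start):
    """0-based offset -> 1-based cytosine coordinate."""
    return start + 1


class MethCall(NamedTuple):
    """A single cytosine methylation call."""

    chrom: str
    pos: int  # 1-based
    strand: str  # F or R
    coverage: int
    meth_count: int
    meth_pct: float


@dataclass
class SampleTable:
    """Per-sample methylation calls, sorted by (chrom, pos).

    ``data`` holds one row per call with columns :data:`CALL_COLUMNS`.
    """

    sample_id: str
    condition: str
    replicate: int
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def calls(self) -> Iterator[MethCall]:
        for row in self.data.itertuples(index=False):
            yield MethCall(*row)


@dataclass
class AnnotationTrack:
    """A named set of genomic intervals in 0-based half-open coordinates."""

    name: str
    intervals: pd.DataFrame  # chrom, start, end, label, strand

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class GeneModel:
    """A gene with TSS, exon structure and a gene-type class."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str  # + or -
    start: int  # 0-based gene span
    end: int
    tss: int  # 1-based
    exons: list[tuple[int, int]]  # 0-based half-open
    gene_type: str

    def __post_init__(self) -> None:
        if self.gene_type not in GENE_TYPES:
            raise ValidationError(
                f"gene_type {self.gene_type!r} not in {sorted(GENE_TYPES)}"
            )


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def read_meth_calls(
    path: str | Path,
    dialect: str = "methylkit",
    sample_id: str | None = None,
    condition: str = "S",
    replicate: int = 1,
    freq_tolerance: float = 0.5,
) -> SampleTable:
    """Read a per-sample methylation call table.

    Parameters
    ----------
    dialect
        ``methylkit`` expects the header ``chrBase chr base strand coverage
        freqC freqT`` with strand F/R and percentages; the methylated-read
        count is recovered as round-half-up(coverage * freqC / 100).
        ``methratio`` expects bsmap-methratio columns (``chr pos strand
        context ratio eff_CT_count C_count CT_count ...``) with strand +/-.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    if dialect == "methylkit":
        df = _read_methylkit(path, freq_tolerance)
    elif dialect == "methratio":
        df = _read_methratio(path)
    else:
        raise UsageError(f"unknown dialect {dialect!r}")

    dup = df.duplicated(subset=["chrom", "pos", "strand"])
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate call at {first.chrom}:{first.pos} ({first.strand})"
        )
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return SampleTable(sample_id, condition, replicate, df[CALL_COLUMNS])


def _read_methylkit(path: Path, freq_tolerance: float) -> pd.DataFrame:
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    if list(raw.columns) != _METHYLKIT_HEADER:
        raise ParseError(
            f"{path}: header {list(raw.columns)} does not match the "
            f"methylKit dialect {_METHYLKIT_HEADER}"
        )
    try:
        pos = pd.to_numeric(raw["base"], errors="raise").astype(np.int64)
        cov = pd.to_numeric(raw["coverage"], errors="raise").astype(np.int64)
        freq_c = pd.to_numeric(raw["freqC"], errors="raise").astype(float)
        freq_t = pd.to_numeric(raw["freqT"], errors="raise").astype(float)
    except (ValueError, TypeError) as exc:
        line = _first_bad_line(raw, exc)
        raise ParseError(f"{path}: malformed row at line {line}: {exc}") from None
    bad_strand = ~raw["strand"].isin(["F", "R"])
    if bad_strand.any():
        line = int(np.flatnonzero(bad_strand)[0]) + 2
        raise ParseError(f"{path}: malformed strand at line {line}")
    if (pos < 1).any():
        line = int(np.flatnonzero(pos < 1)[0]) + 2
        raise ParseError(f"{path}: non-positive coordinate at line {line}")
    off = np.abs(freq_c + freq_t - 100.0) > freq_tolerance
    if off.any():
        line = int(np.flatnonzero(off)[0]) + 2
        raise ValidationError(
            f"{path}: freqC + freqT deviates from 100 by more than "
            f"{freq_tolerance} at line {line}"
        )
    keep = cov.values >= 1  # coverage-0 rows carry no information
    meth = _round_half_up(cov.values[keep] * freq_c.values[keep] / 100.0)
    cov_k = cov.values[keep]
    return pd.DataFrame(
        {
            "chrom": raw["chr"].values[keep],
            "pos": pos.values[keep],
            "strand": raw["strand"].values[keep],
            "coverage": cov_k,
            "meth_count": meth,
            "meth_pct": 100.0 * meth / cov_k,
        }
    )


def _read_methratio(path: Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    required = {"chr", "pos", "strand", "C_count", "CT_count"}
    if not required.issubset(raw.columns):
        raise ParseError(
            f"{path}: methratio dialect needs columns {sorted(required)}"
        )
    strand = raw["strand"].map({"+": "F", "-": "R"})
    if strand.isna().any():
        line = int(np.flatnonzero(strand.isna())[0]) + 2
        raise ParseError(f"{path}: malformed strand at line {line}")
    cov = raw["CT_count"].astype(np.int64)
    meth = raw["C_count"].astype(np.int64)
    if (meth > cov).any():
        line = int(np.flatnonzero(meth > cov)[0]) + 2
        raise ValidationError(f"{path}: C_count exceeds CT_count at line {line}")
    keep = cov.values >= 1
    return pd.DataFrame(
        {
            "chrom": raw["chr"].values[keep],
            "pos": raw["pos"].values[keep].astype(np.int64),
            "strand": strand.values[keep],
            "coverage": cov.values[keep],
            "meth_count": meth.values[keep],
            "meth_pct": 100.0 * meth.values[keep] / cov.values[keep],
        }
    )


def _first_bad_line(raw: pd.DataFrame, exc: Exception) -> int:
    for i, row in enumerate(raw.itertuples(index=False)):
        try:
            int(row.base), int(row.coverage), float(row.freqC), float(row.freqT)
        except (ValueError, TypeError):
            return i + 2  # 1 for the header, 1 for 1-based lines
    return -1


def write_meth_calls(table: SampleTable, path: str | Path) -> Path:
    """Write a SampleTable in the methylKit text dialect (round-trip safe)."""
    path = Path(path)
    df = table.data
    freq_c = 100.0 * df["meth_count"] / df["coverage"]
    out = pd.DataFrame(
        {
            "chrBase": df["chrom"].astype(str) + "." + df["pos"].astype(str),
            "chr": df["chrom"],
            "base": df["pos"],
            "strand": df["strand"],
            "coverage": df["coverage"],
            "freqC": freq_c.map(lambda v: f"{v:.6f}"),
            "freqT": (100.0 - freq_c).map(lambda v: f"{v:.6f}"),
        }
    )
    out.to_csv(path, sep="\t", index=False)
    return path


def read_intervals(path: str | Path, name: str | None = None) -> AnnotationTrack:
    """Read a BED3+ file into an AnnotationTrack (sorted by chrom, start)."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        empty = pd.DataFrame(columns=["chrom", "start", "end", "label", "strand"])
        return AnnotationTrack(name or path.stem, empty)
    if raw.shape[1] < 3:
        raise ParseError(f"{path}: BED needs at least 3 columns")
    try:
        start = pd.to_numeric(raw[1], errors="raise").astype(np.int64)
        end = pd.to_numeric(raw[2], errors="raise").astype(np.int64)
    except (ValueError, TypeError):
        raise ParseError(f"{path}: non-numeric coordinates") from None
    bad = start >= end
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 1
        raise ValidationError(f"{path}: start >= end at line {line}")
    df = pd.DataFrame(
        {
            "chrom": raw[0],
            "start": start,
            "end": end,
            "label": raw[3] if raw.shape[1] > 3 else "",
            "strand": raw[5] if raw.shape[1] > 5 else ".",
        }
    )
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )
    return AnnotationTrack(name or path.stem, df)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 with gene_type appended as column 13."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if raw.shape[1] < 13:
        raise ParseError(f"{path}: expected BED12 + gene_type (13 columns)")
    genes: list[GeneModel] = []
    for i, row in enumerate(raw.itertuples(index=False), start=1):
        try:
            start, end = int(row[1]), int(row[2])
            n_blocks = int(row[9])
            sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
            offsets = [int(x) for x in str(row[11]).rstrip(",").split(",")]
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: malformed row at line {i}: {exc}") from None
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise ValidationError(
                f"{path}: blockCount inconsistent with blockSizes/blockStarts "
                f"at line {i}"
            )
        strand = str(row[5])
        if strand not in "+-":
            raise ValidationError(f"{path}: strand must be + or - at line {i}")
        exons = sorted((start + o, start + o + s) for o, s in zip(offsets, sizes))
        for (a, b), (c, d) in zip(exons, exons[1:]):
            if b > c:
                raise ValidationError(f"{path}: overlapping exons at line {i}")
        tss = start + 1 if strand == "+" else end
        genes.append(
            GeneModel(
                gene_id=str(row[3]),
                gene_name=str(row[3]),
                chrom=str(row[0]),
                strand=strand,
                start=start,
                end=end,
                tss=tss,
                exons=exons,
                gene_type=str(row[12]),
            )
        )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> Path:
    """Write gene models as BED12 + gene_type (inverse of read_gene_models)."""
    path = Path(path)
    rows = []
    for g in genes:
        sizes = ",".join(str(e - s) for s, e in g.exons)
        offsets = ",".join(str(s - g.start) for s, e in g.exons)
        rows.append(
            "\t".join(
                str(x)
                for x in (
                    g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                    g.start, g.end, "0,0,0", len(g.exons), sizes, offsets,
                    g.gene_type,
                )
            )
        )
    path.write_text("\n".join(rows) + ("\n" if rows else ""))
    return path


def write_outputs(product: pd.DataFrame, path: str | Path, kind: str) -> Path:
    """Serialise a pipeline product as bedGraph, BED or TSV.

    bedGraph rows are ``chrom start end value`` on the product's diff column
    (``diff_mean`` if present, else ``meth_diff``); BED rows carry the DMR
    direction in the name field.  Row order is deterministic (chrom, start).
    """
    path = Path(path)
    if kind == "tsv":
        product.to_csv(path, sep="\t", index=False)
        return path
    for col in ("chrom", "start", "end"):
        if col not in product.columns:
            raise UsageError(f"kind={kind!r} needs genomic coordinates ({col})")
    df = product.sort_values(["chrom", "start"], kind="mergesort")
    if kind == "bedgraph":
        value_col = "diff_mean" if "diff_mean" in df.columns else "meth_diff"
        if value_col not in df.columns:
            raise UsageError("bedgraph output needs a diff_mean/meth_diff column")
        out = df[["chrom", "start", "end", value_col]].copy()
        out[value_col] = out[value_col].astype(float)
        out.to_csv(path, sep="\t", index=False, header=False)
    elif kind == "bed":
        name = (
            df["direction"]
            if "direction" in df.columns
            else pd.Series(["region"] * len(df), index=df.index)
        )
        score_col = "diff_mean" if "diff_mean" in df.columns else "meth_diff"
        score = df[score_col] if score_col in df.columns else 0
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"],
                "end": df["end"],
                "name": name,
                "score": score,
                "strand": ".",
            }
        )
        out.to_csv(path, sep="\t", index=False, header=False)
    else:
        raise UsageError(f"unknown output kind {kind!r}")
    return path
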