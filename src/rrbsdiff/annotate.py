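"""Annotate DMRs against promoters, gene features, CpG islands and cCREs.

Feature assignment uses whole-DMR overlap with the precedence
promoter > exon > intron > intergenic; the promoter is the strand-agnostic
window of +-flank around the TSS.  CpG-island assignment uses the DMR
midpoint with the precedence island > shore > open sea (a shore is the
flank of configurable width on each side of an island, minus island
territory).  A cCRE flag is set on any >= 1 bp overlap.
"""

from __future__ import annotations

from intervaltree import IntervalTree

import numpy as np
import pandas as pd

from .errors import UsageError
from .io import AnnotationTrack, GeneModel

__all__ = [
    "annotate_genes",
    "annotate_cgi",
    "annotate_ccre",
    "annotate_dmrs",
    "gene_class_breakdown",
]


def _trees_from_frame(df: pd.DataFrame, data_col: str | None = None):
    trees: dict[str, IntervalTree] = {}
    for row in df.itertuples(index=False):
        payload = getattr(row, data_col) if data_col else None
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, payload
        )
    return trees


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals per chromosome."""
    if len(df) == 0:
        return df[["chrom", "start", "end"]].copy()
    df = df.sort_values(["chrom", "start"], kind="mergesort")
    out = []
    for chrom, grp in df.groupby("chrom", sort=False):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def annotate_genes(
    dmrs: pd.DataFrame,
    genes: list[GeneModel],
    promoter_flank: int = 1000,
) -> pd.DataFrame:
    """Assign each DMR a gene-feature label and collect overlapping genes.

    The promoter of a gene is [tss0 - flank, tss0 + flank) around the
    0-based TSS regardless of strand, clipped at the chromosome start.
    Precedence when a DMR touches several features: promoter > exon >
    intron > intergenic.  ``gene_hits`` lists every gene whose territory
    (promoter plus gene span) the DMR overlaps; it is empty exactly for
    intergenic DMRs.
    """
    prom_rows, exon_rows, intron_rows, hit_rows = [], [], [], []
    for g in genes:
        tss0 = g.tss - 1
        ps, pe = max(0, tss0 - promoter_flank), tss0 + promoter_flank
        prom_rows.append((g.chrom, ps, pe, g.gene_id))
        for s, e in g.exons:
            exon_rows.append((g.chrom, s, e, g.gene_id))
        prev = g.start
        for s, e in g.exons:
            if s > prev:
                intron_rows.append((g.chrom, prev, s, g.gene_id))
            prev = max(prev, e)
        if g.end > prev:
            intron_rows.append((g.chrom, prev, g.end, g.gene_id))
        hit_rows.append((g.chrom, min(ps, g.start), max(pe, g.end), g.gene_id))

    def tree_of(rows):
        trees: dict[str, IntervalTree] = {}
        for chrom, s, e, gid in rows:
            if s < e:
                trees.setdefault(chrom, IntervalTree()).addi(s, e, gid)
        return trees

    prom_t, exon_t, intron_t, hit_t = map(
        tree_of, (prom_rows, exon_rows, intron_rows, hit_rows)
    )

    features, gene_hits = [], []
    for row in dmrs.itertuples(index=False):
        s, e = row.start, row.end
        hits = sorted(
            {iv.data for iv in hit_t.get(row.chrom, IntervalTree()).overlap(s, e)}
        )
        if prom_t.get(row.chrom, IntervalTree()).overlap(s, e):
            feat = "promoter"
        elif exon_t.get(row.chrom, IntervalTree()).overlap(s, e):
            feat = "exon"
        elif intron_t.get(row.chrom, IntervalTree()).overlap(s, e):
            feat = "intron"
        else:
            feat = "intergenic"
            hits = []
        features.append(feat)
        gene_hits.append(hits)
    out = dmrs.copy()
    out["feature"] = features
    out["gene_hits"] = gene_hits
    return out


def annotate_cgi(
    dmrs: pd.DataFrame, cgi: AnnotationTrack, shore_flank: int = 2000
) -> pd.DataFrame:
    """Label each DMR island / shore / open_sea by its midpoint.

    Islands are merged before shores are derived, so shore territory never
    overlaps an island.
    """
    islands = _merge_intervals(cgi.intervals)
    shores = []
    for row in islands.itertuples(index=False):
        shores.append((row.chrom, max(0, row.start - shore_flank), row.start))
        shores.append((row.chrom, row.end, row.end + shore_flank))
    shore_df = pd.DataFrame(shores, columns=["chrom", "start", "end"])
    shore_df = shore_df[shore_df["start"] < shore_df["end"]]
    island_t = _trees_from_frame(islands)
    shore_t = _trees_from_frame(_merge_intervals(shore_df))

    labels = []
    for row in dmrs.itertuples(index=False):
        mid = (row.start + row.end) // 2
        if island_t.get(row.chrom, IntervalTree()).overlap(mid, mid + 1):
            labels.append("island")
        elif shore_t.get(row.chrom, IntervalTree()).overlap(mid, mid + 1):
            labels.append("shore")
        else:
            labels.append("open_sea")
    out = dmrs.copy()
    out["cgi"] = labels
    return out


def annotate_ccre(dmrs: pd.DataFrame, ccre: AnnotationTrack) -> pd.DataFrame:
    """Flag DMRs overlapping any candidate cis-regulatory element (>= 1 bp).

    The cCRE class label from BED column 4 is carried along when present
    (joined with ',' on multiple overlaps).
    """
    trees = _trees_from_frame(
        ccre.intervals.assign(
            label=ccre.intervals.get("label", pd.Series(dtype=str))
        ),
        data_col="label",
    ) if len(ccre.intervals) else {}
    flags, labels = [], []
    for row in dmrs.itertuples(index=False):
        ivs = trees.get(row.chrom, IntervalTree()).overlap(row.start, row.end)
        flags.append(bool(ivs))
        labels.append(",".join(sorted({str(iv.data) for iv in ivs if iv.data})))
    out = dmrs.copy()
    out["ccre"] = flags
    out["ccre_label"] = labels
    return out


def annotate_dmrs(
    dmrs: pd.DataFrame,
    genes: list[GeneModel] | None = None,
    cgi: AnnotationTrack | None = None,
    ccre: AnnotationTrack | None = None,
    promoter_flank: int = 1000,
    shore_flank: int = 2000,
) -> pd.DataFrame:
    """Apply all available annotation facets to a DMR table."""
    out = dmrs.copy()
    if genes is not None:
        out = annotate_genes(out, genes, promoter_flank=promoter_flank)
    if cgi is not None:
        out = annotate_cgi(out, cgi, shore_flank=shore_flank)
    if ccre is not None:
        out = annotate_ccre(out, ccre)
    return out


def gene_class_breakdown(
    annotated: pd.DataFrame, genes: list[GeneModel]
) -> pd.DataFrame:
    """Count unique genes hit by (significant) DMRs, by gene type.

    A gene hit by several DMRs is counted once.  Returns a table with
    counts and fractions per gene_type (fractions sum to 1).
    """
    if "gene_hits" not in annotated.columns:
        raise UsageError("run annotate_genes first (gene_hits missing)")
    rows = annotated
    if "significant" in rows.columns:
        rows = rows.loc[rows["significant"]]
    hit_ids: set[str] = set()
    for hits in rows["gene_hits"]:
        hit_ids.update(hits)
    type_of = {g.gene_id: g.gene_type for g in genes}
    counts: dict[str, int] = {}
    for gid in hit_ids:
        gt = type_of.get(gid, "other")
        counts[gt] = counts.get(gt, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["gene_type", "n_genes", "fraction"])
    out = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene_type", "n_genes"],
    )
    out["fraction"] = out["n_genes"] / out["n_genes"].sum()
    return out
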