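"""200-bp DMR construction, reversion classification and region summaries.

Significant single-CpG calls (DMCs) are aggregated onto the fixed 200-bp
genome grid and merged with the significant 200-bp tile results; the
region's methylation difference is the average of the two analyses where
both exist.  A region is a significant DMR when |averaged difference| >= 25
percentage points and it contains more than 3 DMCs.  Comparing the two
contrasts (resistant vs sensitive, treated vs resistant) per window yields
the reversion classification.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import UsageError

__all__ = [
    "aggregate_dmcs",
    "combine_dmc_tile",
    "call_dmrs",
    "direction_summary",
    "classify_reversion",
    "cross_overlap_fraction",
    "chrom_dmc_distribution",
    "merge_hotspots",
]

REVERSION_LABELS = (
    "reverted_hyper",
    "reverted_hypo",
    "resistance_only",
    "treatment_only",
    "concordant",
    "none",
)


def aggregate_dmcs(dmcs: pd.DataFrame, win: int = 200) -> pd.DataFrame:
    """Assign each DMC to its genome-aligned window and average diffs.

    Input rows are significant single-CpG records of one comparison.
    Each DMC falls in exactly one window [k*win, (k+1)*win); the output has
    one row per occupied window with the DMC count and the unweighted mean
    of their methylation differences.
    """
    if win <= 0:
        raise UsageError("win must be positive")
    if len(dmcs) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_dmc", "dmc_mean_diff"]
        )
    wstart = (dmcs["start"].values // win) * win
    work = pd.DataFrame(
        {
            "chrom": dmcs["chrom"].values,
            "start": wstart,
            "meth_diff": dmcs["meth_diff"].values,
        }
    )
    agg = work.groupby(["chrom", "start"], sort=True, as_index=False).agg(
        n_dmc=("meth_diff", "size"), dmc_mean_diff=("meth_diff", "mean")
    )
    agg.insert(2, "end", agg["start"] + win)
    return agg


def combine_dmc_tile(
    dmc_regions: pd.DataFrame, tiles: pd.DataFrame
) -> pd.DataFrame:
    """Union the DMC-window and significant-tile analyses on the 200-bp grid.

    The output has a row for every window appearing in either analysis;
    ``diff_mean`` is the average of the DMC-mean and tile differences where
    both exist, else the single available value.  Windows where the two
    analyses disagree in sign are flagged ``discordant`` and can never be
    called significant.
    """
    left = dmc_regions.copy()
    right = tiles.rename(columns={"meth_diff": "tile_diff"})[
        ["chrom", "start", "end", "tile_diff"]
    ].copy() if len(tiles) else pd.DataFrame(
        columns=["chrom", "start", "end", "tile_diff"]
    )
    if len(left) == 0:
        left = pd.DataFrame(columns=["chrom", "start", "end", "n_dmc",
                                     "dmc_mean_diff"])
    merged = left.merge(right, on=["chrom", "start", "end"], how="outer")
    merged["n_dmc"] = (
        pd.to_numeric(merged["n_dmc"]).fillna(0).astype(np.int64)
    )
    dmc_d = merged["dmc_mean_diff"].values.astype(float)
    tile_d = merged["tile_diff"].values.astype(float)
    both = ~np.isnan(dmc_d) & ~np.isnan(tile_d)
    diff_mean = np.where(np.isnan(dmc_d), tile_d, dmc_d)
    diff_mean = np.where(both, (dmc_d + tile_d) / 2.0, diff_mean)
    merged["diff_mean"] = diff_mean
    merged["discordant"] = both & (dmc_d * tile_d < 0)
    merged = merged.sort_values(["chrom", "start"], kind="mergesort")
    return merged.reset_index(drop=True)


def call_dmrs(
    candidates: pd.DataFrame, diff_cutoff: float = 25.0, min_dmc: int = 4
) -> pd.DataFrame:
    """Mark significant DMRs: |diff_mean| >= cutoff and n_dmc >= min_dmc.

    ``min_dmc`` = 4 realises the "more than 3 DMCs" rule.  Sign-discordant
    windows are never significant.  Adds ``significant`` and ``direction``
    columns; rows are returned unfiltered so that non-significant windows
    remain available to downstream classification.
    """
    out = candidates.copy()
    absd = out["diff_mean"].abs()
    sig = (absd >= diff_cutoff) & (out["n_dmc"] >= min_dmc)
    if "discordant" in out.columns:
        sig &= ~out["discordant"]
    out["significant"] = sig.values
    direction = np.where(
        out["diff_mean"].values > 0,
        "hyper",
        np.where(out["diff_mean"].values < 0, "hypo", "none"),
    )
    out["direction"] = direction
    return out


def direction_summary(dmrs: pd.DataFrame) -> tuple[float, float]:
    """Fractions of significant DMRs that are hypo- and hypermethylated."""
    sig = dmrs.loc[dmrs["significant"]] if "significant" in dmrs.columns else dmrs
    if len(sig) == 0:
        raise UsageError("direction_summary: no significant DMRs")
    d = sig["diff_mean"].values
    return float(np.mean(d < 0)), float(np.mean(d > 0))


def classify_reversion(
    dmrs_rs: pd.DataFrame, dmrs_rcr: pd.DataFrame
) -> pd.DataFrame:
    """Per-window three-condition classification on the shared 200-bp grid.

    ``reverted_hyper``: significant hypermethylation on acquiring resistance
    (R vs S) that is significantly lost after treatment (RC vs R);
    ``reverted_hypo`` is the mirror.  Windows significant in only one
    comparison are ``resistance_only`` / ``treatment_only``; both
    significant with the same sign is ``concordant``; else ``none``.
    """
    def prep(df: pd.DataFrame, suffix: str) -> pd.DataFrame:
        cols = ["chrom", "start", "end", "diff_mean", "significant", "direction"]
        out = df[cols].copy()
        return out.rename(
            columns={
                "diff_mean": f"diff_{suffix}",
                "significant": f"sig_{suffix}",
                "direction": f"dir_{suffix}",
            }
        )

    merged = prep(dmrs_rs, "RS").merge(
        prep(dmrs_rcr, "RCR"), on=["chrom", "start", "end"], how="outer"
    )
    for suffix in ("RS", "RCR"):
        merged[f"sig_{suffix}"] = (
            merged[f"sig_{suffix}"].astype("boolean").fillna(False).astype(bool)
        )
        merged[f"dir_{suffix}"] = merged[f"dir_{suffix}"].fillna("none")

    sig_rs = merged["sig_RS"].values
    sig_rcr = merged["sig_RCR"].values
    hyper_rs = sig_rs & (merged["dir_RS"].values == "hyper")
    hypo_rs = sig_rs & (merged["dir_RS"].values == "hypo")
    hyper_rcr = sig_rcr & (merged["dir_RCR"].values == "hyper")
    hypo_rcr = sig_rcr & (merged["dir_RCR"].values == "hypo")

    label = np.full(len(merged), "none", dtype=object)
    label[sig_rs & ~sig_rcr] = "resistance_only"
    label[~sig_rs & sig_rcr] = "treatment_only"
    label[(hyper_rs & hyper_rcr) | (hypo_rs & hypo_rcr)] = "concordant"
    label[hyper_rs & hypo_rcr] = "reverted_hyper"
    label[hypo_rs & hyper_rcr] = "reverted_hypo"
    merged["label"] = label
    merged = merged.sort_values(["chrom", "start"], kind="mergesort")
    return merged.reset_index(drop=True)


def cross_overlap_fraction(
    dmrs_rcr: pd.DataFrame, dmrs_rs: pd.DataFrame
) -> float:
    """Fraction of treatment-demethylated windows hypermethylated in R vs S.

    Numerator: windows significantly hypomethylated after treatment
    (RC vs R) that are also significantly hypermethylated with resistance
    (R vs S); denominator: all treatment-hypomethylated windows.
    """
    hypo = dmrs_rcr.loc[
        dmrs_rcr["significant"] & (dmrs_rcr["direction"] == "hypo"),
        ["chrom", "start", "end"],
    ]
    if len(hypo) == 0:
        raise UsageError("cross_overlap_fraction: no treatment-hypo windows")
    hyper = dmrs_rs.loc[
        dmrs_rs["significant"] & (dmrs_rs["direction"] == "hyper"),
        ["chrom", "start", "end"],
    ]
    joined = hypo.merge(hyper, on=["chrom", "start", "end"], how="inner")
    return len(joined) / len(hypo)


def chrom_dmc_distribution(
    dmcs: pd.DataFrame, tested: pd.DataFrame
) -> pd.DataFrame:
    """Per-chromosome percentage of tested CpGs called as (hypo-)DMCs.

    ``dmcs`` are the significant DMCs of interest (typically the
    treatment-demethylated ones), ``tested`` every CpG that entered the
    test.  For each chromosome the pooled percentage over all other
    chromosomes is reported alongside, so locus concentration (the
    repeat-array contrast) is directly readable.
    """
    tested_counts = tested.groupby("chrom").size()
    dmc_counts = dmcs.groupby("chrom").size()
    zero = tested_counts.index[tested_counts == 0]
    if len(zero):
        warnings.warn(f"chromosomes with zero tested sites omitted: {list(zero)}",
                      stacklevel=2)
        tested_counts = tested_counts.drop(zero)
    orphan = dmc_counts.index.difference(tested_counts.index)
    if len(orphan):
        raise UsageError(f"DMCs on chromosomes without tested sites: {list(orphan)}")
    n_dmc = dmc_counts.reindex(tested_counts.index, fill_value=0)
    total_dmc, total_tested = int(n_dmc.sum()), int(tested_counts.sum())
    rows = []
    for chrom in tested_counts.index:
        nt, nd = int(tested_counts[chrom]), int(n_dmc[chrom])
        rest_t = total_tested - nt
        rows.append(
            {
                "chrom": chrom,
                "n_dmc": nd,
                "n_tested": nt,
                "pct": 100.0 * nd / nt,
                "pct_rest": 100.0 * (total_dmc - nd) / rest_t if rest_t else np.nan,
            }
        )
    out = pd.DataFrame(rows).sort_values("pct", ascending=False)
    return out.reset_index(drop=True)


def merge_hotspots(dmrs: pd.DataFrame, max_gap: int = 1000) -> pd.DataFrame:
    """Merge nearby same-direction significant windows into maximal loci.

    Windows of one chromosome and direction whose gap is <= max_gap are
    chained; loci are reported sorted by DMR count (descending), mirroring
    hotspot detection such as a tandem-repeat array covered by a run of
    demethylated windows.
    """
    sig = dmrs.loc[dmrs["significant"]] if "significant" in dmrs.columns else dmrs
    if len(sig) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "direction", "n_dmr", "mean_diff"]
        )
    sig = sig.sort_values(["chrom", "direction", "start"], kind="mergesort")
    loci = []
    for (chrom, direction), grp in sig.groupby(["chrom", "direction"], sort=False):
        start = end = None
        diffs: list[float] = []
        for row in grp.itertuples(index=False):
            if start is None:
                start, end, diffs = row.start, row.end, [row.diff_mean]
            elif row.start - end <= max_gap:
                end = max(end, row.end)
                diffs.append(row.diff_mean)
            else:
                loci.append((chrom, start, end, direction, len(diffs),
                             float(np.mean(diffs))))
                start, end, diffs = row.start, row.end, [row.diff_mean]
        loci.append((chrom, start, end, direction, len(diffs),
                     float(np.mean(diffs))))
    out = pd.DataFrame(
        loci, columns=["chrom", "start", "end", "direction", "n_dmr", "mean_diff"]
    )
    out = out.sort_values(
        ["n_dmr", "chrom", "start"], ascending=[False, True, True],
        kind="mergesort",
    )
    return out.reset_index(drop=True)
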