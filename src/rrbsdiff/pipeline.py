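"""End-to-end run: filter -> unite -> DMC -> tiles -> DMR -> reversion ->
annotation, with a stage log that conserves record counts.

Each stage writes its table under the run directory, so stages are
re-runnable and the summary can be rebuilt from files alone.  The two
comparisons are resistant vs sensitive (R_vs_S) and treated-resistant vs
resistant (RC_vs_R).
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import diff, regions
from .config import RunConfig
from .errors import RrbsError, UsageError
from .io import (
    SampleTable,
    read_gene_models,
    read_intervals,
    read_meth_calls,
    write_outputs,
)

logger = logging.getLogger("rrbsdiff")

COMPARISONS = (("R", "S"), ("RC", "R"))

#: artifacts a completed run directory must contain
REQUIRED_ARTIFACTS = [
    "config.txt",
    "profiles.tsv",
    "correlation.tsv",
    "stage_counts.tsv",
    "reversion.tsv",
    "chrom_distribution.tsv",
] + [
    f"{stem}_{t}_vs_{r}.tsv"
    for t, r in COMPARISONS
    for stem in ("dmc", "dmc_sig", "tiles", "tiles_sig", "dmr", "hotspots")
]


def load_dataset(data_dir: str | Path) -> dict:
    """Load samples and annotation tracks from a dataset directory.

    Prefers the ``manifest.json`` a simulation writes; without one, files
    matching ``{S,R,RC}{n}.txt`` are taken as samples.  Missing annotation
    tracks degrade to None with a warning; missing samples are an error.
    """
    data_dir = Path(data_dir)
    manifest = None
    if (data_dir / "manifest.json").exists():
        manifest = json.loads((data_dir / "manifest.json").read_text())
    samples: list[SampleTable] = []
    if manifest:
        for entry in manifest["samples"]:
            samples.append(
                read_meth_calls(
                    data_dir / entry["file"],
                    sample_id=entry["sample_id"],
                    condition=entry["condition"],
                    replicate=entry["replicate"],
                )
            )
    else:
        import re

        for path in sorted(data_dir.glob("*.txt")):
            m = re.fullmatch(r"(S|R|RC)(\d+)", path.stem)
            if m:
                samples.append(
                    read_meth_calls(
                        path,
                        sample_id=path.stem,
                        condition=m.group(1),
                        replicate=int(m.group(2)),
                    )
                )
    if not samples:
        raise RrbsError(f"no sample call tables found in {data_dir}")
    present = {s.condition for s in samples}
    missing = {"S", "R", "RC"} - present
    if missing:
        raise RrbsError(f"missing samples for condition(s) {sorted(missing)}")

    def optional_track(name: str, reader):
        path = data_dir / name
        if path.exists():
            return reader(path)
        warnings.warn(f"track {name} not found; annotation facet skipped",
                      stacklevel=2)
        return None

    return {
        "samples": samples,
        "cgi": optional_track("cgi.bed", read_intervals),
        "ccre": optional_track("ccre.bed", read_intervals),
        "genes": optional_track("genes.bed", read_gene_models),
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage for both comparisons and write all artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_file(outdir / "config.txt")
    stage_rows: list[tuple[str, int, int, int]] = []

    def log_stage(stage: str, n_in: int, n_kept: int) -> None:
        stage_rows.append((stage, n_in, n_kept, n_in - n_kept))
        logger.info("[%s] in=%d kept=%d dropped=%d",
                    stage, n_in, n_kept, n_in - n_kept)

    data = load_dataset(config.data_dir)
    samples = data["samples"]

    # descriptive profiles on lightly filtered calls
    prof_rows = []
    for s in samples:
        filtered = diff.filter_by_coverage(s, config.min_cov_stats)
        log_stage(f"filter_stats:{s.sample_id}", len(s), len(filtered))
        p = diff.methylation_profile(
            filtered, config.low_threshold, config.high_threshold
        )
        prof_rows.append(
            {
                "sample_id": s.sample_id,
                "condition": s.condition,
                "n_sites": p.n_sites,
                "frac_demethylated": p.frac_demethylated,
                "frac_strongly_methylated": p.frac_strongly_methylated,
                **{f"bin_{i*10}_{i*10+10}": int(c)
                   for i, c in enumerate(p.histogram)},
            }
        )
    write_outputs(pd.DataFrame(prof_rows), outdir / "profiles.tsv", "tsv")

    # CpG-level united matrix and sample correlation
    filtered = [diff.filter_by_coverage(s, config.min_cov) for s in samples]
    for raw, f in zip(samples, filtered):
        log_stage(f"filter_test:{raw.sample_id}", len(raw), len(f))
    united = diff.unite(filtered, min_cov=config.min_cov,
                        destrand=config.destrand)
    log_stage("unite", min(len(f) for f in filtered), len(united))
    corr = diff.sample_correlation(united)
    corr.to_csv(outdir / "correlation.tsv", sep="\t")

    tiles_matrix = diff.tile_counts(
        samples, win=config.tile_width, min_cov=config.min_cov,
        destrand=config.destrand,
    )

    dmr_tables: dict[str, pd.DataFrame] = {}
    for test, ref in COMPARISONS:
        cmp_name = f"{test}_vs_{ref}"
        dmc_all = diff.diff_test(united, test, ref, method=config.method)
        write_outputs(dmc_all, outdir / f"dmc_{cmp_name}.tsv", "tsv")
        dmc_sig = diff.select_significant(
            dmc_all, config.q_cutoff, config.dmc_diff_cutoff, unit="cpg"
        )
        log_stage(f"dmc_select:{cmp_name}", len(dmc_all), len(dmc_sig))
        write_outputs(dmc_sig, outdir / f"dmc_sig_{cmp_name}.tsv", "tsv")

        tile_all = diff.diff_test(tiles_matrix, test, ref, method=config.method)
        write_outputs(tile_all, outdir / f"tiles_{cmp_name}.tsv", "tsv")
        tile_sig = diff.select_significant(
            tile_all, config.q_cutoff, config.tile_diff_cutoff, unit="tile"
        )
        log_stage(f"tile_select:{cmp_name}", len(tile_all), len(tile_sig))
        write_outputs(tile_sig, outdir / f"tiles_sig_{cmp_name}.tsv", "tsv")

        dmc_regions = regions.aggregate_dmcs(dmc_sig, win=config.tile_width)
        candidates = regions.combine_dmc_tile(dmc_regions, tile_sig)
        dmrs = regions.call_dmrs(
            candidates, diff_cutoff=config.dmc_diff_cutoff,
            min_dmc=config.min_dmc,
        )
        log_stage(f"call_dmrs:{cmp_name}", len(dmrs),
                  int(dmrs["significant"].sum()))
        write_outputs(dmrs, outdir / f"dmr_{cmp_name}.tsv", "tsv")
        sig = dmrs.loc[dmrs["significant"]]
        write_outputs(sig, outdir / f"dmr_sig_{cmp_name}.bed", "bed")
        write_outputs(sig, outdir / f"dmr_sig_{cmp_name}.bedgraph", "bedgraph")
        hotspots = regions.merge_hotspots(dmrs, max_gap=config.hotspot_gap)
        write_outputs(hotspots, outdir / f"hotspots_{cmp_name}.tsv", "tsv")
        dmr_tables[cmp_name] = dmrs

        annotated = ann.annotate_dmrs(
            sig.reset_index(drop=True),
            genes=data["genes"],
            cgi=data["cgi"],
            ccre=data["ccre"],
            promoter_flank=config.promoter_flank,
            shore_flank=config.shore_flank,
        )
        out = annotated.copy()
        if "gene_hits" in out.columns:
            out["gene_hits"] = out["gene_hits"].map(",".join)
        write_outputs(out, outdir / f"annotated_{cmp_name}.tsv", "tsv")
        if data["genes"] is not None and "gene_hits" in annotated.columns:
            breakdown = ann.gene_class_breakdown(annotated, data["genes"])
            write_outputs(
                breakdown, outdir / f"gene_class_{cmp_name}.tsv", "tsv"
            )

    reversion = regions.classify_reversion(
        dmr_tables["R_vs_S"], dmr_tables["RC_vs_R"]
    )
    write_outputs(reversion, outdir / "reversion.tsv", "tsv")

    rcr_sig = dmr_tables["RC_vs_R"]
    hypo_dmcs = pd.read_csv(outdir / "dmc_sig_RC_vs_R.tsv", sep="\t")
    hypo_dmcs = hypo_dmcs.loc[hypo_dmcs["meth_diff"] < 0]
    dist = regions.chrom_dmc_distribution(hypo_dmcs, united.sites)
    write_outputs(dist, outdir / "chrom_distribution.tsv", "tsv")
    _ = rcr_sig

    pd.DataFrame(
        stage_rows, columns=["stage", "n_in", "n_kept", "n_dropped"]
    ).to_csv(outdir / "stage_counts.tsv", sep="\t", index=False)

    summarize_run(outdir)
    return outdir


def summarize_run(run_dir: str | Path) -> dict:
    """Assemble the run report from the artifacts on disk.

    Returns the summary as a dict and writes ``report.txt``.  An
    incomplete run directory raises with the explicit list of missing
    artifacts.
    """
    run_dir = Path(run_dir)
    missing = [a for a in REQUIRED_ARTIFACTS if not (run_dir / a).exists()]
    if missing:
        raise UsageError(
            f"incomplete run directory {run_dir}; missing: {missing}"
        )

    profiles = pd.read_csv(run_dir / "profiles.tsv", sep="\t")
    corr = pd.read_csv(run_dir / "correlation.tsv", sep="\t", index_col=0)
    summary: dict = {"profiles": profiles, "correlation": corr}
    lines = ["# RRBS differential methylation run summary", ""]

    lines.append("## Per-sample methylation profiles")
    for row in profiles.itertuples(index=False):
        lines.append(
            f"  {row.sample_id} ({row.condition}): {row.n_sites} CpGs, "
            f"{100 * row.frac_demethylated:.1f}% demethylated, "
            f"{100 * row.frac_strongly_methylated:.1f}% strongly methylated"
        )
    lines.append("")
    lines.append("## Sample correlation (Pearson, common CpGs)")
    lines.append(corr.round(3).to_string())
    lines.append("")

    counts = {}
    for test, ref in COMPARISONS:
        cmp_name = f"{test}_vs_{ref}"
        dmc = pd.read_csv(run_dir / f"dmc_{cmp_name}.tsv", sep="\t")
        dmc_sig = pd.read_csv(run_dir / f"dmc_sig_{cmp_name}.tsv", sep="\t")
        tile_sig = pd.read_csv(run_dir / f"tiles_sig_{cmp_name}.tsv", sep="\t")
        dmrs = pd.read_csv(run_dir / f"dmr_{cmp_name}.tsv", sep="\t")
        sig = dmrs.loc[dmrs["significant"]]
        counts[cmp_name] = {
            "tested_cpgs": len(dmc),
            "dmcs": len(dmc_sig),
            "sig_tiles": len(tile_sig),
            "dmr_candidates": len(dmrs),
            "sig_dmrs": len(sig),
        }
        lines.append(f"## Comparison {cmp_name}")
        lines.append(
            f"  tested CpGs: {len(dmc)}; DMCs: {len(dmc_sig)}; "
            f"significant tiles: {len(tile_sig)}; DMR candidate windows: "
            f"{len(dmrs)}; significant DMRs: {len(sig)}"
        )
        if len(sig):
            frac_hypo, frac_hyper = regions.direction_summary(dmrs)
            counts[cmp_name]["frac_hypo"] = frac_hypo
            counts[cmp_name]["frac_hyper"] = frac_hyper
            lines.append(
                f"  direction: {100 * frac_hypo:.1f}% hypomethylated, "
                f"{100 * frac_hyper:.1f}% hypermethylated"
            )
        else:
            lines.append("  direction: no significant DMRs (section empty)")
        hotspots = pd.read_csv(run_dir / f"hotspots_{cmp_name}.tsv", sep="\t")
        if len(hotspots):
            top = hotspots.iloc[0]
            lines.append(
                f"  top hotspot: {top.chrom}:{top.start}-{top.end} "
                f"({top.direction}, {top.n_dmr} DMRs, "
                f"mean diff {top.mean_diff:.1f})"
            )
        else:
            lines.append("  hotspots: none (section empty)")
        lines.append("")
    summary["counts"] = counts

    reversion = pd.read_csv(run_dir / "reversion.tsv", sep="\t")
    label_counts = reversion["label"].value_counts().to_dict()
    summary["reversion_labels"] = label_counts
    lines.append("## Reversion classification (windows)")
    for label in regions.REVERSION_LABELS:
        lines.append(f"  {label}: {label_counts.get(label, 0)}")
    rcr = pd.read_csv(run_dir / "dmr_RC_vs_R.tsv", sep="\t")
    rs = pd.read_csv(run_dir / "dmr_R_vs_S.tsv", sep="\t")
    n_hypo = int(
        (rcr["significant"] & (rcr["direction"] == "hypo")).sum()
    )
    if n_hypo:
        frac = regions.cross_overlap_fraction(rcr, rs)
        summary["cross_overlap_fraction"] = frac
        lines.append(
            f"  treatment-demethylated windows also resistance-"
            f"hypermethylated: {100 * frac:.1f}%"
        )
    else:
        lines.append("  cross-overlap: no treatment-hypo windows "
                     "(section empty)")
    lines.append("")

    dist = pd.read_csv(run_dir / "chrom_distribution.tsv", sep="\t")
    summary["chrom_distribution"] = dist
    lines.append("## Demethylated-CpG distribution per chromosome "
                 "(RC vs R, % of tested CpGs)")
    for row in dist.itertuples(index=False):
        lines.append(
            f"  {row.chrom}: {row.pct:.2f}% ({row.n_dmc}/{row.n_tested}); "
            f"other chromosomes pooled: {row.pct_rest:.2f}%"
        )
    if len(dist):
        top = dist.iloc[0]
        summary["top_chromosome"] = top.chrom
        lines.append(f"  top chromosome: {top.chrom}")
    lines.append("")

    for test, ref in COMPARISONS:
        cmp_name = f"{test}_vs_{ref}"
        ann_path = run_dir / f"annotated_{cmp_name}.tsv"
        if not ann_path.exists():
            continue
        annotated = pd.read_csv(ann_path, sep="\t")
        lines.append(f"## Annotation facets ({cmp_name}, significant DMRs)")
        if len(annotated) == 0:
            lines.append("  no significant DMRs (section empty)")
            lines.append("")
            continue
        for facet in ("feature", "cgi"):
            if facet in annotated.columns:
                vc = annotated[facet].value_counts()
                lines.append(
                    f"  {facet}: "
                    + ", ".join(f"{k}={v}" for k, v in vc.items())
                )
                summary[f"{facet}_{cmp_name}"] = vc.to_dict()
        if "ccre" in annotated.columns:
            n_ccre = int(annotated["ccre"].sum())
            lines.append(f"  ccre overlap: {n_ccre}/{len(annotated)}")
            summary[f"ccre_{cmp_name}"] = n_ccre
        gc_path = run_dir / f"gene_class_{cmp_name}.tsv"
        if gc_path.exists():
            gc = pd.read_csv(gc_path, sep="\t")
            if len(gc):
                lines.append(
                    "  gene classes: "
                    + ", ".join(
                        f"{r.gene_type}={r.n_genes}"
                        for r in gc.itertuples(index=False)
                    )
                )
                summary[f"gene_class_{cmp_name}"] = gc
        lines.append("")

    (run_dir / "report.txt").write_text("\n".join(lines) + "\n")
    return summary
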