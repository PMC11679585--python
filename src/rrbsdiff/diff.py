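"""Coverage filtering, descriptive statistics and differential testing.

Differential methylation between two condition groups is tested per unit
(single CpG or fixed genome-aligned tile) on methylated/unmethylated read
counts.  Two tests are provided:

``logistic``
    Likelihood-ratio test of a binomial logistic regression of methylation
    on the group indicator.  With a single binary covariate the fitted
    group probabilities are the group-pooled proportions, so the LRT
    statistic has a closed form (a G-test on the pooled 2x2 table) and is
    computed vectorised; p-values come from chi-square with 1 df.  Complete
    separation (a group pooled at 0% or 100%) falls back to Fisher.

``fisher``
    Two-sided Fisher exact test on the pooled 2x2 table
    (methylated/unmethylated x group).

q-values are Benjamini-Hochberg over all tested units of one comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import UsageError, ValidationError
from .io import SampleTable

__all__ = [
    "UnitedMatrix",
    "MethProfile",
    "filter_by_coverage",
    "destrand_calls",
    "unite",
    "methylation_profile",
    "sample_correlation",
    "tile_counts",
    "diff_test",
    "select_significant",
]


@dataclass
class UnitedMatrix:
    """Units x samples count matrix restricted to commonly covered units.

    ``sites`` has columns chrom, start, end, n_cpgs (0-based half-open);
    ``coverage`` and ``meth`` are (n_units, n_samples) integer arrays
    aligned with ``samples``.
    """

    sites: pd.DataFrame = field(repr=False)
    coverage: np.ndarray = field(repr=False)
    meth: np.ndarray = field(repr=False)
    samples: list[str]
    design: dict[str, str]  # sample_id -> condition
    min_coverage: int
    unit: str = "cpg"  # cpg or tile

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def meth_pct(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.meth / self.coverage

    def group_columns(self, condition: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.design[s] == condition]
        if not idx:
            raise UsageError(f"no samples with condition {condition!r}")
        return np.asarray(idx)


@dataclass
class MethProfile:
    """Histogram of per-CpG methylation plus the two bimodality fractions."""

    histogram: np.ndarray  # counts per 10-percentage-point bin
    frac_demethylated: float
    frac_strongly_methylated: float
    low_threshold: float
    high_threshold: float
    n_sites: int


def filter_by_coverage(
    table: SampleTable, min_cov: int, high_pctile: float | None = None
) -> SampleTable:
    """Retain calls with coverage >= min_cov (and below a high percentile).

    ``high_pctile`` (e.g. 99.9) additionally drops calls whose coverage
    exceeds that empirical percentile — a guard against PCR duplicates.
    """
    if min_cov < 1:
        raise UsageError("min_cov must be >= 1")
    df = table.data
    keep = df["coverage"].values >= min_cov
    if high_pctile is not None:
        bound = np.percentile(df["coverage"].values, high_pctile)
        keep &= df["coverage"].values <= bound
    out = df.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn(
            f"{table.sample_id}: no calls survive coverage filtering "
            f"(min_cov={min_cov}, high_pctile={high_pctile})",
            stacklevel=2,
        )
    return SampleTable(table.sample_id, table.condition, table.replicate, out)


def destrand_calls(df: pd.DataFrame) -> pd.DataFrame:
    """Pool the two strands of each CpG (F at p with R at p+1) onto p.

    CpG methylation is symmetric, so a reverse-strand call at p+1 reports
    the same CpG as the forward call at p.
    """
    work = df.copy()
    rev = work["strand"].values == "R"
    pos = work["pos"].values.copy()
    pos[rev] -= 1
    work["pos"] = pos
    pooled = (
        work.groupby(["chrom", "pos"], sort=True, as_index=False)[
            ["coverage", "meth_count"]
        ].sum()
    )
    pooled["strand"] = "F"
    pooled["meth_pct"] = 100.0 * pooled["meth_count"] / pooled["coverage"]
    return pooled[["chrom", "pos", "strand", "coverage", "meth_count", "meth_pct"]]


def unite(
    samples: list[SampleTable], min_cov: int = 10, destrand: bool = True
) -> UnitedMatrix:
    """Join samples on CpGs covered >= min_cov in every sample.

    With ``destrand`` (default, CpG-symmetric) forward/reverse calls of one
    CpG are pooled before the coverage filter is applied.
    """
    if len(samples) < 2:
        raise UsageError("unite needs at least 2 samples")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_ids in unite input")
    frames = []
    for s in samples:
        df = destrand_calls(s.data) if destrand else s.data
        frames.append(
            df.set_index(["chrom", "pos"])[["coverage", "meth_count"]].rename(
                columns={
                    "coverage": f"cov_{s.sample_id}",
                    "meth_count": f"meth_{s.sample_id}",
                }
            )
        )
    joined = frames[0].join(frames[1:], how="inner")
    cov = joined[[f"cov_{i}" for i in ids]].to_numpy(dtype=np.int64)
    keep = (cov >= min_cov).all(axis=1)
    joined = joined.loc[keep]
    if len(joined) == 0:
        warnings.warn("unite: zero common sites after coverage filtering",
                      stacklevel=2)
    idx = joined.index.to_frame(index=False)
    sites = pd.DataFrame(
        {
            "chrom": idx["chrom"],
            "start": idx["pos"] - 1,  # 1-based cytosine -> 0-based
            "end": idx["pos"],
            "n_cpgs": 1,
        }
    )
    return UnitedMatrix(
        sites=sites.reset_index(drop=True),
        coverage=joined[[f"cov_{i}" for i in ids]].to_numpy(dtype=np.int64),
        meth=joined[[f"meth_{i}" for i in ids]].to_numpy(dtype=np.int64),
        samples=ids,
        design={s.sample_id: s.condition for s in samples},
        min_coverage=min_cov,
        unit="cpg",
    )


def methylation_profile(
    table: SampleTable, low_threshold: float = 10, high_threshold: float = 90
) -> MethProfile:
    """Histogram per-CpG methylation and the demethylated/strong fractions.

    Fractions use inclusive thresholds: meth_pct <= low counts as
    demethylated, meth_pct >= high as strongly methylated.  RRBS samples
    typically show a bimodal profile with mass near 0% and near 100%.
    """
    if len(table) == 0:
        raise UsageError("methylation_profile: empty sample table")
    pct = table.data["meth_pct"].values
    hist, _ = np.histogram(pct, bins=np.linspace(0.0, 100.0, 11))
    return MethProfile(
        histogram=hist,
        frac_demethylated=float(np.mean(pct <= low_threshold)),
        frac_strongly_methylated=float(np.mean(pct >= high_threshold)),
        low_threshold=low_threshold,
        high_threshold=high_threshold,
        n_sites=len(pct),
    )


def sample_correlation(matrix: UnitedMatrix) -> pd.DataFrame:
    """Pearson correlation of per-site methylation between all sample pairs.

    Zero-variance samples produce undefined entries; these are set to NaN
    and reported with a warning rather than silently propagated.
    """
    if len(matrix.samples) < 2 or len(matrix) < 3:
        raise UsageError("sample_correlation needs >= 2 samples and >= 3 sites")
    pct = matrix.meth_pct
    flat = [s for j, s in enumerate(matrix.samples) if np.std(pct[:, j]) == 0]
    if flat:
        warnings.warn(
            f"zero-variance sample(s) {flat}: correlation undefined (NaN)",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(pct, rowvar=False)
    out = pd.DataFrame(corr, index=matrix.samples, columns=matrix.samples)
    np.fill_diagonal(out.values, 1.0)
    for s in flat:
        out.loc[s, :] = np.nan
        out.loc[:, s] = np.nan
        out.loc[s, s] = np.nan
    return out


def tile_counts(
    samples: list[SampleTable],
    win: int = 200,
    min_cov: int = 10,
    min_cpgs: int = 1,
    destrand: bool = True,
) -> UnitedMatrix:
    """Sum CpG counts over fixed genome-aligned windows [k*win, (k+1)*win).

    A tile is retained when its summed coverage is >= min_cov in every
    sample and it contains >= min_cpgs distinct CpG positions.
    """
    if win <= 0:
        raise UsageError("win must be positive")
    ids = [s.sample_id for s in samples]
    frames = []
    pos_frames = []
    for s in samples:
        df = destrand_calls(s.data) if destrand else s.data
        start0 = df["pos"].values - 1
        tile = start0 // win
        work = pd.DataFrame(
            {
                "chrom": df["chrom"].values,
                "tile": tile,
                "coverage": df["coverage"].values,
                "meth_count": df["meth_count"].values,
            }
        )
        pos_frames.append(
            pd.DataFrame({"chrom": df["chrom"].values, "tile": tile, "pos": start0})
        )
        agg = work.groupby(["chrom", "tile"], sort=True).sum()
        frames.append(
            agg.rename(
                columns={
                    "coverage": f"cov_{s.sample_id}",
                    "meth_count": f"meth_{s.sample_id}",
                }
            )
        )
    joined = frames[0].join(frames[1:], how="inner")
    cov = joined[[f"cov_{i}" for i in ids]].to_numpy(dtype=np.int64)
    # distinct CpG positions (union over samples) per tile
    all_pos = pd.concat(pos_frames, ignore_index=True).drop_duplicates()
    counts = all_pos.groupby(["chrom", "tile"], sort=True).size()
    n_cpgs = (
        counts.reindex(joined.index, fill_value=0).to_numpy(dtype=np.int64)
        if len(joined)
        else np.array([], dtype=np.int64)
    )
    keep = (cov >= min_cov).all(axis=1) & (n_cpgs >= min_cpgs)
    joined = joined.loc[keep]
    idx = joined.index.to_frame(index=False)
    sites = pd.DataFrame(
        {
            "chrom": idx["chrom"],
            "start": idx["tile"] * win,
            "end": (idx["tile"] + 1) * win,
            "n_cpgs": n_cpgs[keep],
        }
    )
    return UnitedMatrix(
        sites=sites.reset_index(drop=True),
        coverage=joined[[f"cov_{i}" for i in ids]].to_numpy(dtype=np.int64),
        meth=joined[[f"meth_{i}" for i in ids]].to_numpy(dtype=np.int64),
        samples=ids,
        design={s.sample_id: s.condition for s in samples},
        min_coverage=min_cov,
        unit="tile",
    )


def _binom_loglik(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood kernel with the 0*log(0) = 0 convention."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log(p), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log1p(-p), 0.0)
    return t1 + t2


def fisher_exact_p(kt: int, nt: int, kr: int, nr: int) -> float:
    """Two-sided Fisher exact p for a pooled 2x2 (meth/unmeth x group)."""
    table = [[kt, nt - kt], [kr, nr - kr]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def diff_test(
    matrix: UnitedMatrix,
    test_group: str,
    ref_group: str,
    method: str = "logistic",
) -> pd.DataFrame:
    """Per-unit differential methylation test between two condition groups.

    Returns one row per tested unit with chrom/start/end, comparison,
    meth_diff (percentage points, pooled test minus pooled ref), pvalue,
    qvalue (BH over all tested units), n_cpgs and the test actually used.
    Units with zero pooled coverage in either group are excluded and
    reported in the ``n_skipped`` attribute of the frame.
    """
    if method not in ("fisher", "logistic"):
        raise UsageError(f"unknown method {method!r}")
    ti = matrix.group_columns(test_group)
    ri = matrix.group_columns(ref_group)
    cov_t, meth_t = matrix.coverage[:, ti], matrix.meth[:, ti]
    cov_r, meth_r = matrix.coverage[:, ri], matrix.meth[:, ri]
    Nt, Kt = cov_t.sum(axis=1), meth_t.sum(axis=1)
    Nr, Kr = cov_r.sum(axis=1), meth_r.sum(axis=1)
    valid = (Nt > 0) & (Nr > 0)
    n_skipped = int((~valid).sum())

    Nt_, Kt_, Nr_, Kr_ = Nt[valid], Kt[valid], Nr[valid], Kr[valid]
    pt, pr = Kt_ / Nt_, Kr_ / Nr_
    meth_diff = 100.0 * (pt - pr)
    n = valid.sum()
    pvals = np.ones(n)
    test_used = np.full(n, method, dtype=object)

    if method == "logistic":
        p0 = (Kt_ + Kr_) / (Nt_ + Nr_)
        ll_alt = _binom_loglik(Kt_, Nt_, pt) + _binom_loglik(Kr_, Nr_, pr)
        ll_null = _binom_loglik(Kt_, Nt_, p0) + _binom_loglik(Kr_, Nr_, p0)
        lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
        pvals = stats.chi2.sf(lrt, df=1)
        # complete separation: a group pooled at exactly 0% or 100%
        sep = (pt == 0) | (pt == 1) | (pr == 0) | (pr == 1)
        for i in np.flatnonzero(sep):
            pvals[i] = fisher_exact_p(Kt_[i], Nt_[i], Kr_[i], Nr_[i])
            test_used[i] = "fisher_fallback"
    else:
        for i in range(n):
            pvals[i] = fisher_exact_p(Kt_[i], Nt_[i], Kr_[i], Nr_[i])

    pvals = np.clip(pvals, 0.0, 1.0)
    qvals = (
        multipletests(pvals, method="fdr_bh")[1] if n else np.empty(0)
    )
    sites = matrix.sites.loc[valid].reset_index(drop=True)
    out = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["start"],
            "end": sites["end"],
            "comparison": f"{test_group}_vs_{ref_group}",
            "meth_diff": meth_diff,
            "pvalue": pvals,
            "qvalue": qvals,
            "n_cpgs": sites["n_cpgs"],
            "test_used": test_used,
        }
    )
    out.attrs["n_skipped"] = n_skipped
    out.attrs["unit"] = matrix.unit
    return out


def select_significant(
    records: pd.DataFrame,
    q_cutoff: float = 0.01,
    diff_cutoff: float = 25.0,
    unit: str = "cpg",
) -> pd.DataFrame:
    """Apply the significance cutoffs to tested units.

    Single CpGs keep q < q_cutoff and |meth_diff| >= diff_cutoff
    (inclusive); tiles use a strict |meth_diff| > diff_cutoff.
    """
    if unit not in ("cpg", "tile"):
        raise UsageError(f"unknown unit {unit!r}")
    if "qvalue" not in records.columns:
        raise UsageError("records lack q-values; run diff_test first")
    absd = records["meth_diff"].abs()
    if unit == "cpg":
        keep = (records["qvalue"] < q_cutoff) & (absd >= diff_cutoff)
    else:
        keep = (records["qvalue"] < q_cutoff) & (absd > diff_cutoff)
    out = records.loc[keep].reset_index(drop=True)
    out.attrs.update(records.attrs)
    return out
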