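"""Coverage filtering, uniting, profiles, correlation and the tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import exact_fisher_two_sided, make_table
from rrbsdiff.diff import (
    diff_test,
    filter_by_coverage,
    methylation_profile,
    sample_correlation,
    select_significant,
    tile_counts,
    unite,
)
from rrbsdiff.errors import UsageError


def single_strand_rows(positions, coverage, meth, chrom="chr1"):
    return [(chrom, p, "F", c, m) for p, c, m in
            zip(positions, coverage, meth)]


class TestFilterByCoverage:
    def test_threshold_is_inclusive(self):
        table = make_table(
            single_strand_rows([10, 20, 30, 40], [3, 9, 10, 25], [0, 0, 0, 0])
        )
        kept = filter_by_coverage(table, 10)
        assert list(kept.data["coverage"]) == [10, 25]

    def test_min_cov_one_is_identity(self):
        table = make_table(single_strand_rows([1, 2], [5, 7], [1, 2]))
        pd.testing.assert_frame_equal(
            filter_by_coverage(table, 1).data, table.data
        )

    def test_high_percentile_bound_matches_quantile(self):
        rng = np.random.default_rng(3)
        cov = rng.integers(1, 5_000, size=10_000)
        table = make_table(
            single_strand_rows(range(1, 10_001), cov, np.zeros(10_000, int))
        )
        kept = filter_by_coverage(table, 1, high_pctile=99.9)
        assert kept.data["coverage"].max() <= np.percentile(cov, 99.9)
        assert len(kept) >= 0.998 * len(table)

    def test_empty_result_warns_not_raises(self):
        table = make_table(single_strand_rows([5], [2], [1]))
        with pytest.warns(UserWarning, match="no calls"):
            out = filter_by_coverage(table, 100)
        assert len(out) == 0


class TestUnite:
    def make_samples(self, coverages):
        out = []
        for i, cov in enumerate(coverages):
            cond = ["S", "S", "R", "R"][i]
            out.append(
                make_table(
                    single_strand_rows([100], [cov], [cov // 2]),
                    sample_id=f"s{i}", condition=cond,
                    replicate=i % 2 + 1,
                )
            )
        return out

    def test_site_kept_when_all_pass(self):
        united = unite(self.make_samples([12, 15, 11, 20]), min_cov=10)
        assert len(united) == 1

    def test_site_dropped_when_any_fails(self):
        with pytest.warns(UserWarning, match="zero common sites"):
            united = unite(self.make_samples([12, 3, 11, 20]), min_cov=10)
        assert len(united) == 0

    def test_destrand_pools_the_two_strands(self):
        rows = [("chr1", 50, "F", 8, 5), ("chr1", 51, "R", 4, 3)]
        a = make_table(rows, sample_id="a", condition="S")
        b = make_table(rows, sample_id="b", condition="R")
        united = unite([a, b], min_cov=10, destrand=True)
        assert len(united) == 1
        assert united.sites.loc[0, "start"] == 49  # 0-based CpG position
        assert united.coverage[0].tolist() == [12, 12]
        assert united.meth[0].tolist() == [8, 8]


class TestMethylationProfile:
    def test_all_zero_sites_fully_demethylated(self):
        table = make_table(single_strand_rows([1, 2, 3], [10] * 3, [0] * 3))
        prof = methylation_profile(table)
        assert prof.frac_demethylated == 1.0
        assert prof.frac_strongly_methylated == 0.0

    def test_constructed_bimodal_fractions(self):
        """250 low + 400 mid + 350 high sites -> 25% / 35% fractions."""
        rows = []
        pos = 1
        for _ in range(250):
            rows.append(("chr1", pos, "F", 100, 5)); pos += 2
        for _ in range(400):
            rows.append(("chr1", pos, "F", 100, 50)); pos += 2
        for _ in range(350):
            rows.append(("chr1", pos, "F", 100, 95)); pos += 2
        prof = methylation_profile(make_table(rows))
        assert prof.frac_demethylated == pytest.approx(0.25)
        assert prof.frac_strongly_methylated == pytest.approx(0.35)
        assert prof.histogram.sum() == prof.n_sites == 1000

    def test_extreme_thresholds_count_exact_endpoints(self):
        rows = single_strand_rows([1, 2, 3, 4], [10] * 4, [0, 3, 10, 10])
        prof = methylation_profile(make_table(rows), low_threshold=0,
                                   high_threshold=100)
        assert prof.frac_demethylated == pytest.approx(0.25)
        assert prof.frac_strongly_methylated == pytest.approx(0.5)


class TestSampleCorrelation:
    def build_matrix(self, vectors):
        samples = []
        conds = ["S", "S", "R", "R"]
        for i, v in enumerate(vectors):
            rows = [("chr1", 10 * (j + 1), "F", 100, int(m))
                    for j, m in enumerate(v)]
            samples.append(
                make_table(rows, sample_id=f"s{i}", condition=conds[i])
            )
        return unite(samples, min_cov=1, destrand=False)

    def test_duplicated_sample_has_unit_correlation(self):
        m = self.build_matrix([[0, 50, 100], [0, 50, 100]])
        corr = sample_correlation(m)
        assert corr.loc["s0", "s1"] == pytest.approx(1.0)

    def test_reversed_vector_has_minus_one(self):
        m = self.build_matrix([[0, 50, 100], [100, 50, 0]])
        corr = sample_correlation(m)
        assert corr.loc["s0", "s1"] == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 101, size=100)
        y = rng.integers(0, 101, size=100)
        m = self.build_matrix([x, y])
        r = sample_correlation(m).loc["s0", "s1"]
        expected = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_sample_flagged(self):
        m = self.build_matrix([[50, 50, 50], [0, 50, 100]])
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = sample_correlation(m)
        assert np.isnan(corr.loc["s0", "s1"])


class TestTileCounts:
    def two_sample(self, rows):
        a = make_table(rows, sample_id="a", condition="S")
        b = make_table(rows, sample_id="b", condition="R")
        return [a, b]

    def test_cpgs_in_one_window_are_summed(self):
        rows = [("chr1", 150, "F", 10, 5), ("chr1", 180, "F", 10, 5)]
        m = tile_counts(self.two_sample(rows), win=200, min_cov=10)
        assert len(m) == 1
        assert (m.sites.loc[0, "start"], m.sites.loc[0, "end"]) == (0, 200)
        assert m.coverage[0, 0] == 20 and m.meth[0, 0] == 10
        assert m.sites.loc[0, "n_cpgs"] == 2

    def test_window_boundary_uses_zero_based_grid(self):
        rows = [("chr1", 201, "F", 15, 5)]  # 0-based 200
        m = tile_counts(self.two_sample(rows), win=200, min_cov=10)
        assert (m.sites.loc[0, "start"], m.sites.loc[0, "end"]) == (200, 400)

    def test_coverage_is_conserved_across_tiling(self):
        rng = np.random.default_rng(4)
        pos = np.sort(rng.choice(np.arange(1, 50_000, 2), size=1_000,
                                 replace=False))
        cov = rng.integers(1, 40, size=1_000)
        meth = rng.binomial(cov, 0.5)
        rows = single_strand_rows(pos, cov, meth)
        m = tile_counts(self.two_sample(rows), win=200, min_cov=1, min_cpgs=1)
        assert m.coverage[:, 0].sum() == cov.sum()
        assert m.meth[:, 0].sum() == meth.sum()


def group_matrix(test_counts, ref_counts):
    """Units x 4 samples matrix from per-sample (meth, cov) pairs."""
    samples = []
    for i, (cond, pairs) in enumerate(
        [("R", test_counts[0]), ("R", test_counts[1]),
         ("S", ref_counts[0]), ("S", ref_counts[1])]
    ):
        rows = [("chr1", 10 * (j + 1), "F", c, m)
                for j, (m, c) in enumerate(pairs)]
        samples.append(
            make_table(rows, sample_id=f"x{i}", condition=cond,
                       replicate=i % 2 + 1)
        )
    return unite(samples, min_cov=1, destrand=False)


class TestDiffTest:
    def test_identical_groups_no_association(self):
        m = group_matrix(
            [[(5, 10)], [(5, 10)]], [[(5, 10)], [(5, 10)]]
        )
        for method in ("fisher", "logistic"):
            rec = diff_test(m, "R", "S", method=method)
            assert rec.loc[0, "meth_diff"] == 0.0
            assert rec.loc[0, "pvalue"] == pytest.approx(1.0)

    def test_pooled_2x2_matches_exact_enumeration(self):
        # pooled test group 30/40 methylated vs ref 10/40
        m = group_matrix(
            [[(15, 20)], [(15, 20)]], [[(5, 20)], [(5, 20)]]
        )
        rec = diff_test(m, "R", "S", method="fisher")
        assert rec.loc[0, "meth_diff"] == pytest.approx(50.0)
        assert rec.loc[0, "pvalue"] == pytest.approx(
            exact_fisher_two_sided(30, 40, 10, 40), abs=1e-9
        )

    @pytest.mark.parametrize("method", ["fisher", "logistic"])
    def test_swapping_groups_negates_diff_keeps_p(self, method):
        rng = np.random.default_rng(9)
        pairs = lambda: [[(int(m), int(c)) for m, c in
                          zip(rng.integers(0, 15, 5), rng.integers(15, 30, 5))]
                         for _ in range(2)]
        m = group_matrix(pairs(), pairs())
        fwd = diff_test(m, "R", "S", method=method)
        rev = diff_test(m, "S", "R", method=method)
        np.testing.assert_allclose(fwd["meth_diff"], -rev["meth_diff"])
        np.testing.assert_allclose(fwd["pvalue"], rev["pvalue"], rtol=1e-12)
        assert (fwd["meth_diff"].abs() <= 100).all()

    def test_logistic_lrt_equals_statsmodels_glm(self):
        """The closed-form LRT is the binomial-GLM likelihood-ratio test."""
        rng = np.random.default_rng(12)
        grp = np.array([1, 1, 0, 0])
        for _ in range(10):
            cov = rng.integers(10, 40, size=4)
            k = rng.binomial(cov, rng.uniform(0.2, 0.8, size=4))
            if k.sum() == 0 or (cov - k).sum() == 0:
                continue
            m = group_matrix(
                [[(int(k[0]), int(cov[0]))], [(int(k[1]), int(cov[1]))]],
                [[(int(k[2]), int(cov[2]))], [(int(k[3]), int(cov[3]))]],
            )
            rec = diff_test(m, "R", "S", method="logistic")
            if rec.loc[0, "test_used"] != "logistic":
                continue
            endog = np.column_stack([k, cov - k])
            full = sm.GLM(endog, sm.add_constant(grp),
                          family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, np.ones((4, 1)),
                          family=sm.families.Binomial()).fit()
            from scipy import stats as sps

            p_sm = sps.chi2.sf(2 * (full.llf - null.llf), df=1)
            assert rec.loc[0, "pvalue"] == pytest.approx(p_sm, rel=1e-8)

    def test_logistic_and_fisher_agree_in_order_of_magnitude(self):
        """Balanced 2-replicate units, coverage >= 20, moderate effects."""
        rng = np.random.default_rng(21)
        n_checked = 0
        for _ in range(60):
            mu_t = rng.uniform(0.2, 0.8)
            mu_r = np.clip(mu_t + rng.uniform(-0.2, 0.2), 0.05, 0.95)
            cov = rng.integers(20, 41, size=4)
            k = rng.binomial(cov, [mu_t, mu_t, mu_r, mu_r])
            m = group_matrix(
                [[(int(k[0]), int(cov[0]))], [(int(k[1]), int(cov[1]))]],
                [[(int(k[2]), int(cov[2]))], [(int(k[3]), int(cov[3]))]],
            )
            p_log = diff_test(m, "R", "S", method="logistic").loc[0, "pvalue"]
            p_fis = diff_test(m, "R", "S", method="fisher").loc[0, "pvalue"]
            if min(p_log, p_fis) < 1e-12:
                continue
            assert abs(np.log10(p_log) - np.log10(p_fis)) <= 1.0
            n_checked += 1
        assert n_checked >= 40

    def test_separation_falls_back_to_fisher(self):
        m = group_matrix(
            [[(20, 20)], [(18, 18)]], [[(2, 20)], [(3, 20)]]
        )
        rec = diff_test(m, "R", "S", method="logistic")
        assert rec.loc[0, "test_used"] == "fisher_fallback"
        assert rec.loc[0, "pvalue"] == pytest.approx(
            exact_fisher_two_sided(38, 38, 5, 40), abs=1e-9
        )

    def test_bh_qvalues_monotone_in_p_rank(self):
        rng = np.random.default_rng(17)
        pairs = lambda: [
            [(int(m), int(c)) for m, c in
             zip(rng.integers(0, 20, 50), rng.integers(20, 40, 50))]
            for _ in range(2)
        ]
        m = group_matrix(pairs(), pairs())
        rec = diff_test(m, "R", "S").sort_values("pvalue")
        assert (np.diff(rec["qvalue"].values) >= -1e-15).all()
        assert (rec["qvalue"].values >= rec["pvalue"].values - 1e-15).all()


class TestSelectSignificant:
    def frame(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "meth_diff", "qvalue"]
        )

    def test_cpg_boundary_is_inclusive(self):
        rec = self.frame([("c", 0, 1, -30.0, 0.005), ("c", 2, 3, 25.0, 0.005),
                          ("c", 4, 5, 24.9, 0.005), ("c", 6, 7, 30.0, 0.02)])
        kept = select_significant(rec, unit="cpg")
        assert list(kept["start"]) == [0, 2]

    def test_tile_boundary_is_strict(self):
        rec = self.frame([("c", 0, 200, 25.0, 0.005),
                          ("c", 200, 400, 25.1, 0.005)])
        kept = select_significant(rec, unit="tile")
        assert list(kept["start"]) == [200]

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_tightening_q_cutoff_never_keeps_more(self, seed):
        rng = np.random.default_rng(seed)
        rec = self.frame(
            [("c", i, i + 1, d, q) for i, (d, q) in
             enumerate(zip(rng.uniform(-100, 100, 30),
                           rng.uniform(0, 0.05, 30)))]
        )
        loose = len(select_significant(rec, q_cutoff=0.01))
        tight = len(select_significant(rec, q_cutoff=0.001))
        assert tight <= loose
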