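import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from clearscore import (
    ClinicalTable,
    ExpressionMatrix,
    RSSProfiles,
    RunConfig,
    build_rss,
    filter_genes,
    raw_score,
    scale_scores,
    score_cohort,
    score_new_samples,
    generate_cohort,
)
from clearscore.iocore import ClearScoreError
from conftest import brute_force_score


def make_rss(low, high, genes=None, axis="grade"):
    low = np.asarray(low, float)
    genes = genes or tuple(f"g{i}" for i in range(len(low)))
    return RSSProfiles(
        gene_ids=tuple(genes),
        profile_low=low,
        profile_high=np.asarray(high, float),
        n_low=1,
        n_high=1,
        clinical_axis=axis,
    )


class TestFilterGenes:
    def test_all_retained_when_all_high(self):
        df = pd.DataFrame(np.full((4, 6), 10.0),
                          index=[f"g{i}" for i in range(4)],
                          columns=[f"s{j}" for j in range(6)])
        assert filter_genes(ExpressionMatrix(df), 8, 0.10) == [f"g{i}" for i in range(4)]

    def test_all_zero_errors(self):
        df = pd.DataFrame(np.zeros((3, 5)),
                          index=list("abc"), columns=[f"s{j}" for j in range(5)])
        with pytest.raises(ClearScoreError, match="removed every gene"):
            filter_genes(ExpressionMatrix(df), 8, 0.10)

    def test_threshold_count_rule(self):
        # ceil(0.10 * 10) = 1: gene A passes in exactly 1 sample, B in none
        vals = np.full((5, 10), 5.0)
        vals[0, 3] = 9.0          # gene A: one sample above 8
        vals[2, :] = 8.0          # exactly 8 is NOT above threshold
        vals[3, :2] = 12.0        # two samples above
        df = pd.DataFrame(vals, index=list("ABCDE"),
                          columns=[f"s{j}" for j in range(10)])
        kept = filter_genes(ExpressionMatrix(df), 8, 0.10)
        # brute-force oracle
        expected = [g for g, row in df.iterrows() if (row > 8).sum() >= 1]
        assert kept == expected
        assert "A" in kept and "B" not in kept and "C" not in kept

    def test_order_preserved(self, small_cohort):
        kept = filter_genes(small_cohort.expr)
        order = {g: i for i, g in enumerate(small_cohort.expr.gene_ids)}
        assert kept == sorted(kept, key=order.get)


class TestBuildRSS:
    def test_single_member_extremes_equal_columns(self, tiny_expr, tiny_clin):
        rss = build_rss(tiny_expr, tiny_clin, axis="grade")
        np.testing.assert_array_equal(rss.profile_low, tiny_expr.sample_vector("s1"))
        np.testing.assert_array_equal(rss.profile_high, tiny_expr.sample_vector("s4"))
        assert rss.n_low == 1 and rss.n_high == 1

    def test_median_vs_mean_centroid(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 9.0, 5.0], [2.0, 3.0, 10.0, 6.0]],
            index=["gA", "gB"], columns=["a", "b", "c", "d"],
        )
        clin = ClinicalTable(pd.DataFrame(
            {"grade": [1, 1, 1, 4]}, index=pd.Index(list("abcd"), name="sample_id")))
        med = build_rss(ExpressionMatrix(df), clin, axis="grade")
        assert med.profile_low[0] == 2.0       # median of {1, 2, 9}
        mean = build_rss(ExpressionMatrix(df), clin, axis="grade", statistic="mean")
        assert mean.profile_low[0] == 4.0      # mean of {1, 2, 9}

    def test_size_quartile_membership(self):
        sizes = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        ids = [f"s{i}" for i in range(8)]
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(9, 1, (5, 8)),
                          index=[f"g{i}" for i in range(5)], columns=ids)
        clin = ClinicalTable(pd.DataFrame(
            {"size": sizes}, index=pd.Index(ids, name="sample_id")))
        rss = build_rss(ExpressionMatrix(df), clin, axis="size")
        # sort-based oracle for the quartile split
        s = pd.Series(sizes, index=ids)
        low_expected = list(s.index[s <= s.quantile(0.25)])
        high_expected = list(s.index[s >= s.quantile(0.75)])
        np.testing.assert_allclose(
            rss.profile_low, np.median(df[low_expected].to_numpy(), axis=1))
        np.testing.assert_allclose(
            rss.profile_high, np.median(df[high_expected].to_numpy(), axis=1))
        assert rss.n_low == len(low_expected)
        assert rss.n_high == len(high_expected)

    def test_missing_extreme_errors(self, tiny_expr):
        clin = ClinicalTable(pd.DataFrame(
            {"grade": [2, 2, 3, 3]},
            index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id")))
        with pytest.raises(ClearScoreError, match="empty extreme"):
            build_rss(tiny_expr, clin, axis="grade")

    def test_constant_centroid_errors(self, tiny_clin):
        df = pd.DataFrame(np.full((3, 4), 9.0), index=list("abc"),
                          columns=["s1", "s2", "s3", "s4"])
        with pytest.raises(ClearScoreError, match="constant"):
            build_rss(ExpressionMatrix(df), tiny_clin, axis="grade")


class TestRawScore:
    def test_sample_equal_to_low_profile_scores_near_zero(self, oracle_cfg):
        low = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        high = low[::-1].copy()
        rss = make_rss(low, high)
        cs = raw_score(low, rss, oracle_cfg)
        assert cs <= oracle_cfg.epsilon / 1e-3  # d1 floored at epsilon

    def test_hand_computed_six_gene_example(self, oracle_cfg):
        low = np.array([1.0, 2, 3, 4, 5, 6])
        high = np.array([6.0, 5, 4, 3, 2, 1])
        s = np.array([1.0, 2, 3, 4, 5, 7])
        rss = make_rss(low, high)
        cs = raw_score(s, rss, oracle_cfg)
        # independent oracle via np.corrcoef
        expected = brute_force_score(s, low, high)
        assert cs == pytest.approx(expected, abs=1e-12)
        # and the raw Pearson values this encodes
        r1 = np.corrcoef(s, low)[0, 1]
        assert r1 == pytest.approx(20 / np.sqrt(17.5 * (70 / 3)), abs=1e-12)

    def test_reciprocal_on_swap(self, oracle_cfg):
        rng = np.random.default_rng(5)
        low = rng.normal(9, 1, 12)
        high = rng.normal(9, 1, 12)
        s = rng.normal(9, 1, 12)
        rss = make_rss(low, high)
        cs = raw_score(s, rss, oracle_cfg)
        cs_swapped = raw_score(s, rss.swap(), oracle_cfg)
        assert cs_swapped == pytest.approx(1.0 / cs, rel=1e-12)

    def test_oracle_equivalence_many_fixtures(self, oracle_cfg):
        rng = np.random.default_rng(123)
        for _ in range(20):
            n = rng.integers(5, 40)
            low = rng.normal(9, 1, n)
            high = rng.normal(9, 1, n)
            s = rng.normal(9, 1, n)
            rss = make_rss(low, high)
            assert raw_score(s, rss, oracle_cfg) == pytest.approx(
                brute_force_score(s, low, high), abs=1e-12)

    def test_subset_too_small_errors(self):
        rng = np.random.default_rng(0)
        rss = make_rss(rng.normal(size=4), rng.normal(size=4))
        cfg = RunConfig(subset_fraction=0.5, n_boot=2)  # round(0.5*4) = 2 < 3
        with pytest.raises(ClearScoreError, match="too small"):
            raw_score(rng.normal(size=4), rss, cfg)

    def test_spearman_option(self, oracle_cfg):
        rng = np.random.default_rng(2)
        low, high, s = rng.normal(9, 1, (3, 15))
        rss = make_rss(low, high)
        cfg = oracle_cfg.replace(correlation_method="spearman")
        got = raw_score(s, rss, cfg)
        r1 = spearmanr(s, low).statistic
        r2 = spearmanr(s, high).statistic
        assert got == pytest.approx((1 - r1) / (1 - r2), abs=1e-12)


class TestScaleScores:
    def test_direct_formula(self):
        scaled, lo, hi = scale_scores(np.array([0.2, 0.5, 1.0]))
        np.testing.assert_allclose(scaled, [1.0, 38.125, 100.0])
        assert (lo, hi) == (0.2, 1.0)

    def test_bounds_attained(self):
        rng = np.random.default_rng(0)
        scaled, _, _ = scale_scores(rng.exponential(size=50))
        assert scaled.min() == pytest.approx(1.0)
        assert scaled.max() == pytest.approx(100.0)
        assert ((scaled >= 1) & (scaled <= 100)).all()

    def test_degenerate_cohort_midpoint(self, caplog):
        scaled, lo, hi = scale_scores(np.array([3.3, 3.3]))
        np.testing.assert_allclose(scaled, [50.5, 50.5])
        assert any("degenerate" in r.message for r in caplog.records)

    def test_too_few_scores(self):
        with pytest.raises(ClearScoreError):
            scale_scores(np.array([1.0]))


class TestScoreCohort:
    def test_profile_copies_attain_extremes(self, oracle_cfg):
        rng = np.random.default_rng(8)
        low = rng.normal(9, 1, 20)
        high = rng.normal(9, 1, 20)
        mids = [0.5 * low + 0.5 * high + rng.normal(0, 0.3, 20) for _ in range(3)]
        df = pd.DataFrame(
            np.column_stack([low] + mids + [high]),
            index=[f"g{i}" for i in range(20)],
            columns=["lowcopy", "m1", "m2", "m3", "highcopy"],
        )
        rss = make_rss(low, high, genes=[f"g{i}" for i in range(20)])
        res = score_cohort(ExpressionMatrix(df), rss, oracle_cfg)
        assert res.sample_ids[np.argmin(res.raw_scores)] == "lowcopy"
        assert res.scaled_scores[list(res.sample_ids).index("lowcopy")] == 1.0

    def test_determinism_under_seed(self, small_cohort_scored):
        sub, cfg, res = small_cohort_scored
        res2 = score_cohort(sub, res.rss, cfg)
        np.testing.assert_array_equal(res.raw_scores, res2.raw_scores)

    def test_order_invariance(self, small_cohort_scored):
        # per-sample seeding: shuffling the cohort must not change any score
        sub, cfg, res = small_cohort_scored
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(sub.sample_ids))
        res2 = score_cohort(sub.subset_samples(perm), res.rss, cfg)
        lookup = dict(zip(res2.sample_ids, res2.raw_scores))
        for sid, raw in zip(res.sample_ids, res.raw_scores):
            assert lookup[sid] == raw

    def test_recovers_latent_ordering(self, small_cohort_scored, small_cohort):
        _, _, res = small_cohort_scored
        rho = spearmanr(res.raw_scores,
                        small_cohort.latent.loc[list(res.sample_ids)]).statistic
        assert rho > 0.8

    def test_ranking_reverses_on_swap(self, oracle_cfg, small_cohort_scored):
        sub, _, res = small_cohort_scored
        a = score_cohort(sub, res.rss, oracle_cfg)
        b = score_cohort(sub, res.rss.swap(), oracle_cfg)
        np.testing.assert_allclose(b.raw_scores, 1.0 / a.raw_scores, rtol=1e-10)
        assert list(np.argsort(a.raw_scores)) == list(np.argsort(-b.raw_scores))


class TestScoreNewSamples:
    def test_refit_member_identical(self, small_cohort_scored):
        sub, cfg, res = small_cohort_scored
        two = sub.subset_samples(list(res.sample_ids[:2]))
        projected = score_new_samples(two, res)
        for sid in two.sample_ids:
            i = list(res.sample_ids).index(sid)
            assert projected[sid] == pytest.approx(res.scaled_scores[i], abs=1e-12)

    def test_clamping(self, oracle_cfg):
        rng = np.random.default_rng(3)
        low = rng.normal(9, 1, 15)
        high = rng.normal(9, 1, 15)
        genes = [f"g{i}" for i in range(15)]
        rss = make_rss(low, high, genes=genes)
        cohort = pd.DataFrame(
            np.column_stack([0.8 * low + 0.2 * high, 0.5 * low + 0.5 * high]),
            index=genes, columns=["a", "b"])
        res = score_cohort(ExpressionMatrix(cohort), rss, oracle_cfg)
        # the high centroid itself scores beyond the fitted max -> clamped to 100
        extreme = pd.DataFrame(np.column_stack([high, low]),
                               index=genes, columns=["hi", "lo"])
        projected = score_new_samples(ExpressionMatrix(extreme), res)
        assert projected["hi"] == 100.0
        assert projected["lo"] == 1.0

    def test_low_overlap_errors(self, small_cohort_scored):
        sub, _, res = small_cohort_scored
        few = sub.subset_genes(sub.gene_ids[: sub.n_genes // 4])
        with pytest.raises(ClearScoreError, match="50%"):
            score_new_samples(few, res)

    def test_holdout_rank_correlation(self):
        cohort = generate_cohort(n_samples=70, n_genes=150, n_informative=15,
                                 noise_sd=0.8, seed=21)
        kept = filter_genes(cohort.expr)
        sub = cohort.expr.subset_genes(kept)
        train_ids = sub.sample_ids[:50]
        test_ids = sub.sample_ids[50:]
        cfg = RunConfig(n_boot=20, seed=9)
        train = sub.subset_samples(train_ids)
        rss = build_rss(train, cohort.clin.subset(train_ids))
        res = score_cohort(train, rss, cfg)
        projected = score_new_samples(sub.subset_samples(test_ids), res)
        rho = spearmanr(projected.to_numpy(),
                        cohort.latent.loc[list(projected.index)]).statistic
        assert rho > 0.7


class TestNoiseMonotonicity:
    def test_correlation_degrades_with_noise(self):
        # averaged over replicates: recovery at noise 0.5 >= recovery at 2.0
        cfg = RunConfig(n_boot=10, seed=0)
        rhos = {0.5: [], 2.0: []}
        for rep in range(4):
            for sd in rhos:
                c = generate_cohort(n_samples=50, n_genes=120, n_informative=12,
                                    noise_sd=sd, seed=100 + rep)
                kept = filter_genes(c.expr)
                sub = c.expr.subset_genes(kept)
                res = score_cohort(sub, build_rss(sub, c.clin), cfg)
                rhos[sd].append(
                    spearmanr(res.raw_scores,
                              c.latent.loc[list(res.sample_ids)]).statistic)
        assert np.mean(rhos[0.5]) >= np.mean(rhos[2.0])
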