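"""Statistical core against independent oracles.

The JZS Bayes factor is cross-checked against Rouder's g-prior integral (an
algebraically different formulation) and pingouin's implementation; the
Wilcoxon exact p against sign-pattern enumeration; BH-FDR against the step-up
rule applied by hand; d' against the high-precision normal quantile.
"""

import itertools

import numpy as np
import pytest
from scipy import integrate
from scipy import stats as sps

from stereoattn import (bf10_jzs_paired, bf10_rank, dprime, morey_ci,
                        paired_t, running_fdr_ttest, wilcoxon_signed_rank)


class TestPairedT:
    def test_identical_samples(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_hand_computed_case(self):
        # differences (1, 2, 3): mean 2, sd 1 -> t = 2*sqrt(3), df 2
        res = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(2 * np.sqrt(3))
        assert res.df == 2
        assert res.effect_size == pytest.approx(2.0)
        assert res.p == pytest.approx(2 * sps.t.sf(2 * np.sqrt(3), 2))

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert paired_t(x, y).statistic == pytest.approx(
            -paired_t(y, x).statistic)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_type_i_error_calibrated(self):
        # 10,000 null simulations at n = 23: rejection rate within
        # binomial bounds of alpha = 0.05
        rng = np.random.default_rng(99)
        x = rng.normal(size=(10_000, 23))
        t = x.mean(1) / (x.std(1, ddof=1) / np.sqrt(23))
        p = 2 * sps.t.sf(np.abs(t), 22)
        rate = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 10_000)
        assert abs(rate - 0.05) < 3.5 * se


def _bf10_cauchy_nct(t, n, r=np.sqrt(2) / 2):
    """Effect-scale formulation (independent oracle).

    Integrates the noncentral-t likelihood against the Cauchy prior on the
    standardized effect directly — an algebraically different route from the
    implementation's variance-mixture integral.
    """
    nu = n - 1
    sqrt_n = np.sqrt(n)

    def alt(delta):
        return sps.nct.pdf(t, nu, delta * sqrt_n) * sps.cauchy.pdf(delta,
                                                                   scale=r)

    center = t / sqrt_n
    m1, _ = integrate.quad(alt, -np.inf, center, limit=300)
    m2, _ = integrate.quad(alt, center, np.inf, limit=300)
    return (m1 + m2) / sps.t.pdf(t, nu)


class TestJzsBayesFactor:
    def test_null_favored_at_t_zero(self):
        assert bf10_jzs_paired(0.0, 23) < 1.0

    def test_monotone_in_t(self):
        vals = [bf10_jzs_paired(t, 23) for t in (0.0, 1.0, 2.0, 4.0, 8.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("t,n", [(0.0, 23), (1.5, 23), (3.0, 23),
                                     (-2.0, 10), (5.0, 8), (0.114, 23)])
    def test_matches_cauchy_nct_integral(self, t, n):
        assert bf10_jzs_paired(t, n) == pytest.approx(
            _bf10_cauchy_nct(t, n), rel=1e-4)

    @pytest.mark.parametrize("t,n", [(2.0, 23), (4.0, 15)])
    def test_matches_pingouin(self, t, n):
        pg = pytest.importorskip("pingouin")
        assert bf10_jzs_paired(t, n) == pytest.approx(
            float(pg.bayesfactor_ttest(t, n, paired=True)), rel=1e-3)

    def test_consistency_under_large_effect(self):
        # d = 1.3 at n = 23 should give overwhelming evidence
        rng = np.random.default_rng(3)
        bfs = []
        for _ in range(50):
            d = rng.normal(1.3, 1.0, size=23)
            t = d.mean() / (d.std(ddof=1) / np.sqrt(23))
            bfs.append(bf10_jzs_paired(t, 23))
        assert np.median(bfs) > 100


class TestRunningFdr:
    def test_identical_series_empty_mask(self):
        x = np.random.default_rng(1).normal(size=(5, 20))
        mask, p = running_fdr_ttest(x, x.copy())
        assert not mask.any()

    def test_bh_step_up_matches_hand_rule(self):
        # p = (.001, .01, .02, .04, .05), m = 5, q = .05: p_(i) <= i*q/m holds
        # at i = 5 (.05 <= .05), so the step-up rejects all five.
        from statsmodels.stats.multitest import multipletests

        pvals = np.array([0.001, 0.01, 0.02, 0.04, 0.05])

        def bh_by_hand(p, q):
            order = np.argsort(p)
            m = len(p)
            below = p[order] <= (np.arange(1, m + 1) * q / m)
            k = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
            mask = np.zeros(m, dtype=bool)
            mask[order[:k]] = True
            return mask

        hand = bh_by_hand(pvals, 0.05)
        assert hand.all()
        assert np.array_equal(
            multipletests(pvals, alpha=0.05, method="fdr_bh")[0], hand)

    def test_running_mask_consistent_with_bh_on_pointwise_p(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        x = rng.normal(0.4, 1.0, size=(12, 40))
        y = rng.normal(size=(12, 40))
        mask, p = running_fdr_ttest(x, y, q=0.05)
        assert np.array_equal(mask,
                              multipletests(p, 0.05, method="fdr_bh")[0])

    def test_never_rejects_more_than_uncorrected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(23, 100))
        y = rng.normal(size=(23, 100))
        mask, p = running_fdr_ttest(x, y, q=0.05)
        assert mask.sum() <= (p < 0.05).sum()


class TestMoreyCi:
    def test_identical_condition_difference_gives_zero(self):
        subj = np.arange(8, dtype=float)[:, None]
        data = np.hstack([subj, subj + 3.0])    # same diff for all subjects
        assert morey_ci(data) == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_two_condition_correction_factor(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(10, 2))
        norm = data - data.mean(1, keepdims=True) + data.mean()
        se = norm.std(0, ddof=1) / np.sqrt(10)
        expected = sps.t.ppf(0.975, 9) * se * np.sqrt(2.0)
        assert morey_ci(data) == pytest.approx(expected)

    def test_toy_numeric_case(self):
        # n = 5, C = 2, hand-computable normalized values
        data = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 3.0],
                         [4.0, 6.0], [5.0, 5.0]])
        grand = data.mean()
        norm = data - data.mean(1, keepdims=True) + grand
        half = sps.t.ppf(0.975, 4) * norm.std(0, ddof=1) / np.sqrt(5) * np.sqrt(2)
        assert morey_ci(data) == pytest.approx(half)


class TestWilcoxon:
    def test_all_positive_small_n_exact(self):
        # n = 5, all positive differences: one-sided 1/32, two-sided 1/16
        res = wilcoxon_signed_rank([2.0, 3.0, 4.0, 5.0, 6.0],
                                   [1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.p == pytest.approx(2 / 32)
        assert res.effect_size == pytest.approx(1.0)

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(11)
        d = rng.normal(0.3, 1.0, size=10)
        d = d[d != 0]
        res = wilcoxon_signed_rank(d, np.zeros_like(d))
        # enumerate all sign patterns
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        ws = [sum(r for r, s in zip(ranks, signs) if s)
              for signs in itertools.product([0, 1], repeat=len(d))]
        ws = np.array(ws)
        center = total / 2
        p_exact = np.mean(np.abs(ws - center) >= abs(w_obs - center) - 1e-9)
        assert res.p == pytest.approx(p_exact, abs=1e-9)

    def test_symmetric_differences_central(self):
        res = wilcoxon_signed_rank([1.0, -1.0, 2.0, -2.0],
                                   [0.0, 0.0, 0.0, 0.0])
        assert res.p == pytest.approx(1.0)

    def test_approx_close_to_exact_at_n20(self):
        rng = np.random.default_rng(13)
        d = rng.normal(0.2, 1.0, 20)
        exact = sps.wilcoxon(d, method="exact").pvalue
        approx = sps.wilcoxon(d, method="approx", correction=True).pvalue
        assert abs(exact - approx) < 0.01

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


class TestRankBayesFactor:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(17)
        x = rng.normal(0.5, 1.0, 23)
        y = np.zeros(23)
        b1 = bf10_rank(x, y)
        # cubing preserves sign and order of the differences
        b2 = bf10_rank(np.sign(x) * np.abs(x) ** 3, y)
        assert b1 == pytest.approx(b2)

    def test_null_data_typically_below_one(self):
        rng = np.random.default_rng(19)
        bfs = [bf10_rank(rng.normal(size=23), np.zeros(23)) for _ in range(60)]
        assert np.median(bfs) < 1.0

    def test_large_shift_gives_strong_evidence(self):
        rng = np.random.default_rng(23)
        x = rng.normal(2.0, 1.0, 23)
        assert bf10_rank(x, np.zeros(23)) > 10


class TestDprime:
    def test_equal_rates_zero(self):
        assert dprime(50, 50, 50, 50) == pytest.approx(0.0)

    def test_perfect_performance_finite(self):
        assert np.isfinite(dprime(100, 0, 0, 100))

    def test_matches_quantile_oracle(self):
        h = (93 + 0.5) / (100 + 1)
        f = (4 + 0.5) / (100 + 1)
        expected = sps.norm.ppf(h) - sps.norm.ppf(f)
        assert dprime(93, 7, 4, 96) == pytest.approx(expected, abs=1e-6)

    def test_clip_correction_variant(self):
        d = dprime(100, 0, 0, 100, correction="clip")
        expected = sps.norm.ppf(1 - 1 / 200) - sps.norm.ppf(1 / 200)
        assert d == pytest.approx(expected, abs=1e-9)

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            dprime(0, 0, 5, 5)
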