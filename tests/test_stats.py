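import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from betareach import stats as st


class TestPairedPermMap:
    def test_identical_maps_give_zero_t_and_no_hits(self):
        a = np.random.default_rng(0).normal(size=(10, 8))
        res = st.perm_ttest_paired(a, a.copy(), n_perm=500, alpha=0.05, seed=1)
        assert np.allclose(res.t, 0.0)
        assert not res.significant.any()

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(14, 16))
        b = a + 0.0
        b[:, :5] += 1.2  # strong planted effect on five channels
        res = st.perm_ttest_paired(b, a, n_perm=2000, alpha=0.05, seed=2)
        assert res.significant[:5].all()
        assert res.significant[5:].sum() <= 1

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(12, 8)), rng.normal(size=(12, 8))
        r1 = st.perm_ttest_paired(a, b, n_perm=1000, seed=7)
        r2 = st.perm_ttest_paired(a, b, n_perm=1000, seed=7)
        assert np.array_equal(r1.p_corrected, r2.p_corrected)

    def test_p_floor_respects_add_one_convention(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(10, 4))
        res = st.perm_ttest_paired(a + 10.0, a, n_perm=200, seed=5, correction="none")
        assert res.p_corrected.min() >= 1.0 / 201.0

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            st.perm_ttest_paired(np.ones((1, 4)), np.zeros((1, 4)))


class TestIndependentPermMap:
    def test_label_swap_negates_t(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(1, 1, size=(9, 8)), rng.normal(0, 1, size=(12, 8))
        r1 = st.perm_ttest_independent(a, b, n_perm=1500, seed=6)
        r2 = st.perm_ttest_independent(b, a, n_perm=1500, seed=6)
        assert np.allclose(r1.t, -r2.t)
        assert np.max(np.abs(r1.p_corrected - r2.p_corrected)) < 0.1

    def test_null_rarely_significant(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(30):
            a, b = rng.normal(size=(8, 6)), rng.normal(size=(8, 6))
            res = st.perm_ttest_independent(
                a, b, n_perm=400, alpha=0.05, seed=int(rng.integers(2**31))
            )
            hits += int(res.significant.any())
        assert hits / 30 <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / 30)

    def test_unequal_group_sizes_with_planted_difference(self):
        rng = np.random.default_rng(8)
        a = rng.normal(1.0, 1, size=(25, 8))
        b = rng.normal(0.0, 1, size=(13, 8))
        res = st.perm_ttest_independent(a, b, n_perm=2000, alpha=0.05, seed=9)
        # a 1-SD group difference at these sizes is detected on most channels
        assert res.significant.sum() >= 4
        assert res.t.min() > 1.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            st.perm_ttest_independent(np.empty((0, 4)), np.ones((5, 4)))


class TestWilcoxon:
    def test_symmetric_differences_z_zero_p_one(self):
        res = st.wilcoxon_signed_rank(np.array([-2.0, -1.0, 1.0, 2.0]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_six_positive_differences_exact_p(self):
        res = st.wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]))
        assert res.p == pytest.approx(2 / 64)
        assert res.detail["method"] == "exact"

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            n = int(rng.integers(5, 11))
            d = rng.normal(0.4, 1.0, n).round(2)
            d = d[d != 0]
            if d.size < 2:
                continue
            res = st.wilcoxon_signed_rank(d)
            ranks = sps.rankdata(np.abs(d))
            mu = d.size * (d.size + 1) / 4
            obs = abs(float(ranks[d > 0].sum()) - mu)
            cnt = sum(
                abs(float(np.dot(sgn, ranks)) - mu) >= obs - 1e-12
                for sgn in itertools.product((0, 1), repeat=d.size)
            )
            assert res.p == pytest.approx(cnt / 2.0**d.size)

    def test_normal_approximation_matches_scipy(self):
        d = np.random.default_rng(11).normal(0.3, 1, 40)
        res = st.wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, method="approx", correction=False)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_all_zero_differences_degenerate(self):
        res = st.wilcoxon_signed_rank(np.zeros(8))
        assert res.detail["degenerate"]


class TestKruskalWallis:
    def test_identical_groups(self):
        res = st.kruskal_wallis(np.ones(5), np.ones(5))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_textbook_value_without_ties(self):
        res = st.kruskal_wallis([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == pytest.approx(27 / 7)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(12)
        a = rng.integers(0, 5, 15).astype(float)
        b = rng.integers(1, 6, 11).astype(float)
        res = st.kruskal_wallis(a, b)
        ref = sps.kruskal(a, b)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(size=10), rng.normal(1, 1, size=8)
        r1 = st.kruskal_wallis(a, b)
        r2 = st.kruskal_wallis(np.exp(a), np.exp(b))
        assert r1.statistic == pytest.approx(r2.statistic)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert st.spearman(x, x**3).statistic == pytest.approx(1.0)
        assert st.spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_exact_p_matches_enumeration(self):
        x = np.array([1.0, 4.0, 2.0, 5.0, 3.0])
        y = np.array([2.0, 3.0, 1.0, 5.0, 4.0])
        res = st.spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        cnt = sum(
            abs(np.corrcoef(rx, ry[list(p)])[0, 1]) >= obs - 1e-12
            for p in itertools.permutations(range(5))
        )
        assert res.p == pytest.approx(cnt / math.factorial(5))
        assert res.detail["method"] == "exact"

    def test_large_n_matches_scipy(self):
        rng = np.random.default_rng(14)
        x, y = rng.normal(size=25), rng.normal(size=25)
        res = st.spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_zero_variance_flagged(self):
        res = st.spearman(np.ones(6), np.arange(6.0))
        assert res.detail["degenerate"]


class TestMixedAnova:
    def _frame(self, effect=0.0, seed=15):
        rng = np.random.default_rng(seed)
        rows = []
        for g, n in (("ROT", 10), ("MOT", 8)):
            for i in range(n):
                base = rng.normal(0, 1)
                for blk in ("mov0", "mov3"):
                    y = base + rng.normal(0, 1)
                    if blk == "mov3":
                        # crossed effect: practice helps one group, hurts the
                        # other, so the interaction carries the signal
                        y += effect if g == "ROT" else -effect
                    rows.append(
                        dict(subject=f"{g}{i}", group=g, block=blk, y=y)
                    )
        return pd.DataFrame(rows)

    def test_null_data_small_f(self):
        res = st.mixed_anova(
            self._frame(0.0), dv="y", within="block", between="group", subject="subject"
        )
        assert all(r.p > 0.01 for r in res.values())

    def test_planted_interaction_dominates(self):
        res = st.mixed_anova(
            self._frame(2.5), dv="y", within="block", between="group", subject="subject"
        )
        f_int = res["Interaction"].statistic
        assert f_int == max(r.statistic for r in res.values())

    def test_partial_eta_squared_identity(self):
        res = st.mixed_anova(
            self._frame(1.0), dv="y", within="block", between="group", subject="subject"
        )
        for r in res.values():
            df1, df2 = r.detail["df1"], r.detail["df2"]
            assert r.effect_size == pytest.approx(
                r.statistic * df1 / (r.statistic * df1 + df2), rel=1e-6
            )

    def test_incomplete_cases_rejected(self):
        df = self._frame(0.0).iloc[:-1]
        with pytest.raises(ValueError):
            st.mixed_anova(
                df, dv="y", within="block", between="group", subject="subject"
            )
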