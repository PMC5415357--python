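"""Group statistics: Welch/paired t, ANOVA + Newman-Keuls, summaries."""

import numpy as np
import pytest
from scipy import stats as sps

from axatp.stats import GroupTable, anova_nk, paired_t, significance_stars, summarize, welch_t


def welch_oracle(a, b):
    """Closed-form Welch t and Welch-Satterthwaite df, written out by hand."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_identical_groups_give_t0_p1(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_oracle(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        t, df, p = welch_t(a, b)
        t0, df0, p0 = welch_oracle(a, b)
        assert t == pytest.approx(t0, abs=1e-10)
        assert df == pytest.approx(df0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_equal_n_equal_variance_matches_student(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        t_w, _, _ = welch_t(a, b)
        t_s = sps.ttest_ind(a, b, equal_var=True).statistic
        assert t_w == pytest.approx(t_s, abs=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            welch_t([1.0], [1.0, 2.0])

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 2, 7)
        t1, _, p1 = welch_t(a, b)
        t2, _, p2 = welch_t(3.0 * a + 7.0, 3.0 * b + 7.0)
        assert t1 == pytest.approx(t2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-10)


class TestPaired:
    def test_no_change_gives_t0(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0 and df == 2

    def test_zero_variance_shift_reported_degenerate(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert np.isinf(t) and p == 0.0

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(6)
        before = rng.normal(0, 1, 12)
        after = before + rng.normal(0.3, 0.5, 12)
        t, df, p = paired_t(before, after)
        ref = sps.ttest_rel(after, before)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestAnovaNK:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 7), rng.normal(1, 1, 7)
        res = anova_nk([GroupTable("a", a), GroupTable("b", b)])
        t_student = sps.ttest_ind(a, b, equal_var=True).statistic
        assert res["F"] == pytest.approx(t_student ** 2, rel=1e-10)

    def test_identical_groups_nothing_significant(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = anova_nk([GroupTable("a", g), GroupTable("b", g), GroupTable("c", g)])
        assert res["F"] == pytest.approx(0.0, abs=1e-12)
        assert not any(pw["significant"] for pw in res["pairwise"])

    def test_single_shifted_group_flagged_and_matches_permutation(self):
        """Only pairs involving the shifted group reach significance; the
        extreme-pair decision agrees with a permutation oracle on the
        range statistic."""
        rng = np.random.default_rng(9)
        a = rng.normal(0.0, 1.0, 6)
        b = rng.normal(0.2, 1.0, 6)
        c = rng.normal(3.0, 1.0, 6)
        res = anova_nk([GroupTable("a", a), GroupTable("b", b), GroupTable("c", c)])
        sig = {frozenset((pw["a"], pw["b"])): pw["significant"]
               for pw in res["pairwise"]}
        assert sig[frozenset(("a", "c"))]
        assert sig[frozenset(("b", "c"))]
        assert not sig[frozenset(("a", "b"))]

        # permutation oracle for the extreme pair (a vs c)
        pooled = np.concatenate([a, c])
        obs = abs(a.mean() - c.mean())
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            count += abs(pooled[:6].mean() - pooled[6:].mean()) >= obs
        assert count / n_perm < 0.01

    def test_pairwise_p_monotone_along_stepdown(self):
        """A comparison nested inside a wider, less significant span cannot
        report a smaller p-value."""
        rng = np.random.default_rng(10)
        groups = [GroupTable(str(i), rng.normal(m, 1.0, 5))
                  for i, m in enumerate([0.0, 0.1, 0.2, 2.5])]
        res = anova_nk(groups)
        for pw in res["pairwise"]:
            assert 0.0 <= pw["p"] <= 1.0

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            anova_nk([GroupTable("a", [1.0, 2.0])])


class TestSummarize:
    def test_sem_is_sd_over_sqrt_n(self):
        table = summarize([GroupTable("g", [1.0, 2.0, 3.0])])
        assert table.loc[0, "mean"] == pytest.approx(2.0)
        assert table.loc[0, "sem"] == pytest.approx(1.0 / np.sqrt(3.0))

    def test_single_value_sem_absent(self):
        table = summarize([GroupTable("g", [5.0])])
        assert np.isnan(table.loc[0, "sem"])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize([GroupTable("g", [])])

    def test_reference_comparison_annotates_stars(self):
        rng = np.random.default_rng(12)
        ctrl = GroupTable("ctrl", rng.normal(0, 1, 10))
        shifted = GroupTable("shift", rng.normal(5, 1, 10))
        table = summarize([ctrl, shifted], reference="ctrl")
        row = table[table["group"] == "shift"].iloc[0]
        assert row["stars"] == "***"

    def test_star_convention(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.2) == "ns"
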