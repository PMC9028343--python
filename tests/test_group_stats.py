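"""Mann–Whitney, boxplot summaries, comparison table, ANOVA and post-hoc."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dermaquant import (
    boxplot_summary,
    condition_table,
    mann_whitney,
    student_t,
    two_way_anova_bonferroni,
)
from dermaquant.synthetic_data import StudyDesign, generate_tile_stat_table


def permutation_oracle(x, y):
    """Brute-force two-sided Mann–Whitney p: enumerate all group assignments
    of the pooled sample and count those with min(U1, U2) at least as extreme."""
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    ranks = sps.rankdata(pooled)

    def min_u(idx):
        r1 = ranks[list(idx)].sum()
        u1 = n1 * len(y) + n1 * (n1 + 1) / 2 - r1
        return min(u1, n1 * len(y) - u1)

    observed = min_u(range(n1))
    count = total = 0
    for combo in itertools.combinations(range(n), n1):
        total += 1
        if min_u(combo) <= observed + 1e-9:
            count += 1
    return count / total


class TestMannWhitney:
    def test_worked_example(self):
        r = mann_whitney([1, 2], [3, 4])
        assert r.statistic_value == 0
        assert r.p_value == pytest.approx(1 / 3, abs=1e-10)
        assert r.method == "exact-enumeration"

    def test_identical_constant_samples(self):
        r = mann_whitney([5.0] * 6, [5.0] * 6)
        assert r.statistic_value == pytest.approx(18.0)  # n^2 / 2
        assert r.p_value == 1.0

    def test_exact_matches_oracle_exhaustive_small_layouts(self, rng):
        """Exact-mode p equals the full-permutation oracle for every untied
        layout with combined n <= 10."""
        for n1 in range(1, 10):
            for n2 in range(1, 11 - n1):
                vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
                x, y = vals[:n1], vals[n1:]
                r = mann_whitney(x, y)
                assert r.method == "exact-enumeration"
                assert r.p_value == pytest.approx(
                    permutation_oracle(x, y), abs=1e-10
                )

    def test_exact_mode_with_ties_matches_oracle(self, rng):
        for _ in range(5):
            x = rng.integers(0, 4, size=6).astype(float)
            y = rng.integers(0, 4, size=6).astype(float)
            r = mann_whitney(x, y, method="exact")
            assert r.p_value == pytest.approx(permutation_oracle(x, y), abs=1e-10)

    def test_normal_approximation_close_to_scipy(self, rng):
        x = rng.poisson(40, size=60).astype(float)
        y = rng.poisson(100, size=60).astype(float)
        ours = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.method == "normal-approximation-tie-corrected"
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    @settings(max_examples=40, deadline=None)
    @given(
        n1=st.integers(2, 8), n2=st.integers(2, 8), seed=st.integers(0, 2**16)
    )
    def test_symmetry(self, n1, n2, seed):
        """Swapping the samples leaves the two-sided p and U unchanged."""
        r = np.random.default_rng(seed)
        x, y = r.normal(size=n1), r.normal(size=n2)
        a, b = mann_whitney(x, y), mann_whitney(y, x)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        assert a.statistic_value == pytest.approx(b.statistic_value)

    def test_u_within_bounds(self, rng):
        x, y = rng.normal(size=7), rng.normal(size=9)
        r = mann_whitney(x, y)
        assert 0 <= r.statistic_value <= 63

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestBoxplotSummary:
    def test_known_five_numbers(self):
        s = boxplot_summary([1, 2, 3, 4, 5])
        assert (s.min, s.median, s.max, s.mean) == (1, 3, 5, 3)
        assert s.q1 == 2 and s.q3 == 4

    def test_constant_sample(self):
        s = boxplot_summary([7.0] * 10)
        assert s.min == s.q1 == s.median == s.q3 == s.max == 7.0
        assert s.sd == 0.0

    def test_quartiles_match_order_statistics_oracle(self, rng):
        v = rng.normal(size=60)
        s = boxplot_summary(v)
        srt = np.sort(v)
        # linear interpolation convention at the quartile positions
        for q, frac in ((s.q1, 0.25), (s.median, 0.5), (s.q3, 0.75)):
            pos = frac * (len(v) - 1)
            lo, hi = int(math.floor(pos)), int(math.ceil(pos))
            expect = srt[lo] + (pos - lo) * (srt[hi] - srt[lo])
            assert q == pytest.approx(expect, abs=1e-12)
        assert s.min <= s.q1 <= s.median <= s.q3 <= s.max

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            boxplot_summary([])


class TestConditionTable:
    def test_identical_arms_give_p_one(self):
        rows = []
        for treatment in ("VAS", "IMQ"):
            for i in range(60):
                rows.append(
                    {"strain": "WT", "treatment": treatment, "timepoint": 24,
                     "n_g": 10 + (i % 5), "n_pc": 60000 - i}
                )
        tab = condition_table(pd.DataFrame(rows))
        assert tab.loc[0, "p_n_g"] == 1.0

    def test_missing_arm_named_in_error(self):
        df = pd.DataFrame(
            [{"strain": "WT", "treatment": "VAS", "timepoint": 24,
              "n_g": 1, "n_pc": 2}]
        )
        with pytest.raises(ValueError, match="IMQ"):
            condition_table(df)

    def test_planted_effect_detected(self):
        design = StudyDesign(gap_density_effect=2.5, master_seed=42)
        tab = condition_table(generate_tile_stat_table(design))
        assert len(tab) == 6
        assert (tab["p_n_g"] < 0.01).all()
        assert (tab["p_n_pc"] < 0.01).all()

    def test_null_rejection_rate_near_alpha(self):
        """Type-I error of the VAS-vs-IMQ table under zero effect stays near
        the nominal 5% level (moderate replicate count; the acceptance suite
        runs the full calibration)."""
        rej = total = 0
        for rep in range(120):
            design = StudyDesign(gap_density_effect=1.0, master_seed=5_000 + rep)
            tab = condition_table(generate_tile_stat_table(design))
            rej += int(tab["significant_n_g"].sum() + tab["significant_n_pc"].sum())
            total += 2 * len(tab)
        assert 0.02 <= rej / total <= 0.09


def anova_balanced_oracle(df, response, fa, fb):
    """Textbook mean-decomposition sums of squares for a balanced layout."""
    y = df[response].to_numpy(float)
    grand = y.mean()
    ss_a = sum(
        len(g) * (g[response].mean() - grand) ** 2 for _, g in df.groupby(fa)
    )
    ss_b = sum(
        len(g) * (g[response].mean() - grand) ** 2 for _, g in df.groupby(fb)
    )
    ss_cells = sum(
        len(g) * (g[response].mean() - grand) ** 2 for _, g in df.groupby([fa, fb])
    )
    ss_ab = ss_cells - ss_a - ss_b
    sse = sum(
        ((g[response] - g[response].mean()) ** 2).sum()
        for _, g in df.groupby([fa, fb])
    )
    return ss_a, ss_b, ss_ab, sse


class TestTwoWayAnova:
    @staticmethod
    def balanced(rng, na=2, nb=3, reps=4):
        rows = []
        for a in range(na):
            for b in range(nb):
                for _ in range(reps):
                    rows.append(
                        {"A": f"a{a}", "B": f"b{b}",
                         "y": a * 0.5 + b * 0.2 + rng.normal()}
                    )
        return pd.DataFrame(rows)

    def test_all_equal_gives_f_zero_p_one(self):
        df = pd.DataFrame(
            {"A": ["a", "a", "b", "b"] * 2, "B": ["x", "y"] * 4, "y": 3.0}
        )
        anova, _ = two_way_anova_bonferroni(df, "y", "A", "B")
        for res in anova.values():
            assert res.statistic_value == 0.0
            assert res.p_value == 1.0

    def test_pure_interaction_zero_variance_limit(self):
        rows = []
        for a in ("a1", "a2"):
            for b in ("b1", "b2"):
                val = 1.0 if (a, b) == ("a2", "b2") else 0.0
                rows += [{"A": a, "B": b, "y": val}] * 3
        anova, _ = two_way_anova_bonferroni(pd.DataFrame(rows), "y", "A", "B")
        assert math.isinf(anova["interaction"].statistic_value)
        assert 0 < anova["interaction"].p_value < 1e-100

    def test_sums_of_squares_match_decomposition_oracle(self, rng):
        df = self.balanced(rng)
        anova, _ = two_way_anova_bonferroni(df, "y", "A", "B")
        ss_a, ss_b, ss_ab, sse = anova_balanced_oracle(df, "y", "A", "B")
        df_e = anova["A"].n2
        mse = sse / df_e
        assert anova["A"].statistic_value == pytest.approx(ss_a / 1 / mse, rel=1e-9)
        assert anova["B"].statistic_value == pytest.approx(ss_b / 2 / mse, rel=1e-9)
        assert anova["interaction"].statistic_value == pytest.approx(
            ss_ab / 2 / mse, rel=1e-9
        )

    def test_matches_statsmodels_cross_check(self, rng):
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        df = self.balanced(rng)
        anova, _ = two_way_anova_bonferroni(df, "y", "A", "B")
        fit = smf.ols("y ~ C(A) * C(B)", data=df).fit()
        table = anova_lm(fit, typ=1)
        assert anova["A"].p_value == pytest.approx(
            table.loc["C(A)", "PR(>F)"], rel=1e-8
        )
        assert anova["interaction"].p_value == pytest.approx(
            table.loc["C(A):C(B)", "PR(>F)"], rel=1e-8
        )

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"A": ["a"] * 4, "B": ["x", "y"] * 2, "y": 1.0})
        with pytest.raises(ValueError):
            two_way_anova_bonferroni(df, "y", "A", "B")

    def test_bonferroni_bounds(self, rng):
        _, posthoc = two_way_anova_bonferroni(
            self.balanced(rng, na=3), "y", "A", "B"
        )
        assert (posthoc["p_bonferroni"] >= posthoc["p_raw"] - 1e-15).all()
        assert (posthoc["p_bonferroni"] <= 1.0).all()


class TestStudentT:
    def test_identical_groups(self):
        assert student_t([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]).p_value == 1.0

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=8), rng.normal(0.8, size=8)
        ours = student_t(x, y)
        ref = sps.ttest_ind(x, y)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)
        assert ours.statistic_value == pytest.approx(ref.statistic, rel=1e-9)
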