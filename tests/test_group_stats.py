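"""Summaries, ANOVA + Tukey HSD, and relative qPCR expression (2^-ddCt)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vasoquant import (
    InputError,
    ci_from_summary,
    compare_groups,
    relative_expression,
    summarize_group,
)
from vasoquant.group_stats import round_half_up


def make_ct_table(rows):
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])


class TestConfidenceIntervals:
    def test_zero_sem_degenerate_interval(self):
        assert ci_from_summary(10.0, 0.0, 5) == (10.0, 10.0)

    def test_zero_variance_group(self):
        s = summarize_group([3.0, 3.0, 3.0])
        assert s.ci_low == s.mean == s.ci_high == 3.0

    def test_n2_interval_uses_t_quantile_12p706(self):
        lo, hi = ci_from_summary(0.0, 1.0, 2)
        assert hi == pytest.approx(stats.t.ppf(0.975, 1), abs=1e-3)
        assert hi == pytest.approx(12.706, abs=1e-3)
        assert lo == -hi

    @pytest.mark.parametrize(
        "mean,sem,lo,hi",
        [
            (1.44, 0.012, 1.41, 1.47),   # control arm
            (1.21, 0.022, 1.16, 1.26),   # high-dose arm
        ],
    )
    def test_reported_df_interval_bounds(self, mean, sem, lo, hi):
        a, b = ci_from_summary(mean, sem, 10, 0.95)
        assert round_half_up(a) == lo
        assert round_half_up(b) == hi

    def test_reported_low_dose_upper_bound(self):
        _, b = ci_from_summary(1.32, 0.020, 10, 0.95)
        assert round_half_up(b) == 1.37

    def test_summary_agrees_with_ci_from_summary(self):
        rng = np.random.default_rng(0)
        v = rng.normal(5, 2, size=17)
        s = summarize_group(v)
        lo, hi = ci_from_summary(s.mean, s.sem, s.n)
        assert s.ci_low == pytest.approx(lo, rel=1e-12)
        assert s.ci_high == pytest.approx(hi, rel=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(InputError):
            ci_from_summary(1.0, 0.1, 1)
        with pytest.raises(InputError):
            summarize_group([1.0])


class TestCompareGroups:
    def test_identical_groups_give_zero_f(self):
        res = compare_groups({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_group_f_matches_hand_calculation(self):
        # groups {1,2}, {3,4}: SSB = 4, SSW = 1, F = (4/1)/(1/2) = 8
        res = compare_groups({"a": [1, 2], "b": [3, 4]})
        assert res.f_statistic == pytest.approx(8.0, rel=1e-12)

    def test_degenerate_constant_data_convention(self):
        res = compare_groups({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        assert res.f_statistic == 0.0 and res.anova_p == 1.0
        assert all(t.p_adjusted == 1.0 for t in res.pairwise)

    def test_f_invariant_under_shift_and_scale(self):
        rng = np.random.default_rng(1)
        g = {k: rng.normal(k_i, 1, 6) for k_i, k in enumerate("abc")}
        f0 = compare_groups(g).f_statistic
        shifted = {k: np.asarray(v) + 100.0 for k, v in g.items()}
        scaled = {k: np.asarray(v) * 3.0 for k, v in g.items()}
        assert compare_groups(shifted).f_statistic == pytest.approx(f0, rel=1e-9)
        assert compare_groups(scaled).f_statistic == pytest.approx(f0, rel=1e-9)

    def test_tukey_never_below_unadjusted_pooled_t(self):
        """Adjusted pairwise p >= the unadjusted pooled-variance t-test p,
        over 100 random datasets."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            groups = {
                f"g{j}": rng.normal(rng.normal(0, 1), 1, rng.integers(3, 8))
                for j in range(3)
            }
            res = compare_groups(groups)
            arrays = {k: np.asarray(v, float) for k, v in groups.items()}
            n_total = sum(a.size for a in arrays.values())
            df_w = n_total - len(arrays)
            msw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_w
            for pair in res.pairwise:
                a, b = arrays[pair.group_a], arrays[pair.group_b]
                t = abs(a.mean() - b.mean()) / np.sqrt(msw * (1 / a.size + 1 / b.size))
                p_unadj = 2 * stats.t.sf(t, df_w)
                assert pair.p_adjusted >= p_unadj - 1e-12

    def test_tukey_cross_checked_against_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(3)
        groups = {k: rng.normal(mu, 1, 8) for k, mu in [("a", 0), ("b", 1), ("c", 3)]}
        res = compare_groups(groups)
        values = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [len(v) for v in groups.values()])
        sm = pairwise_tukeyhsd(values, labels)
        ours = {(t.group_a, t.group_b): t.p_adjusted for t in res.pairwise}
        for row, p in zip(sm.summary().data[1:], sm.pvalues):
            key = (str(row[0]), str(row[1]))
            assert ours[key] == pytest.approx(p, abs=1e-6)

    def test_single_group_rejected(self):
        with pytest.raises(InputError):
            compare_groups({"a": [1, 2, 3]})


class TestRelativeExpression:
    def test_null_table_all_fold_changes_one(self):
        rows = []
        for grp in ("control", "low", "high"):
            for s in range(2):
                sample = f"{grp}{s}"
                for gene in ("VEGF-A", "VEGF-R2", "B2M", "GAPDH"):
                    rows.append((sample, grp, gene, 20.0))
        res = relative_expression(make_ct_table(rows))
        assert (res["fold_change"] == 1.0).all()

    def test_one_cycle_shift_halves_expression(self):
        rows = []
        for grp, shift in (("control", 0.0), ("treated", 1.0)):
            sample = f"{grp}1"
            rows += [
                (sample, grp, "VEGF-A", 22.0 + shift),
                (sample, grp, "B2M", 18.0),
                (sample, grp, "GAPDH", 18.0),
            ]
        res = relative_expression(make_ct_table(rows), target_genes=("VEGF-A",))
        fold = res.set_index("group")["fold_change"]
        assert fold["control"] == 1.0
        assert fold["treated"] == pytest.approx(0.5, rel=1e-12)

    def test_two_reference_genes_average_to_combined_ct(self):
        rows = [
            ("s1", "control", "VEGF-A", 25.0),
            ("s1", "control", "B2M", 20.0),
            ("s1", "control", "GAPDH", 22.0),
        ]
        res = relative_expression(make_ct_table(rows), target_genes=("VEGF-A",))
        # combined reference Ct = mean(20, 22) = 21 -> delta Ct = 4
        assert res.loc[0, "mean_delta_ct"] == pytest.approx(4.0)

    def test_translation_invariance_of_fold_changes(self):
        rng = np.random.default_rng(4)
        rows = []
        for grp in ("control", "treated"):
            for s in range(3):
                sample = f"{grp}{s}"
                for gene in ("VEGF-A", "B2M", "GAPDH"):
                    rows.append((sample, grp, gene, float(rng.uniform(15, 30))))
        table = make_ct_table(rows)
        res0 = relative_expression(table, target_genes=("VEGF-A",))
        shifted = table.copy()
        shifted["ct"] = shifted["ct"] + 3.7
        res1 = relative_expression(shifted, target_genes=("VEGF-A",))
        np.testing.assert_allclose(
            res0["fold_change"], res1["fold_change"], rtol=1e-12
        )

    def test_control_fold_change_is_exactly_one(self):
        rng = np.random.default_rng(5)
        rows = []
        for grp in ("control", "x"):
            for s in range(4):
                sample = f"{grp}{s}"
                for gene in ("VEGF-A", "B2M"):
                    rows.append((sample, grp, gene, float(rng.uniform(15, 30))))
        res = relative_expression(
            make_ct_table(rows), target_genes=("VEGF-A",), reference_genes=("B2M",)
        )
        assert res.set_index("group").loc["control", "fold_change"] == 1.0

    def test_missing_reference_lists_offending_samples(self):
        rows = [
            ("s1", "control", "VEGF-A", 25.0),
            ("s1", "control", "B2M", 20.0),
            ("s2", "treated", "VEGF-A", 26.0),   # no reference gene
        ]
        with pytest.raises(InputError, match="s2"):
            relative_expression(make_ct_table(rows))

    def test_missing_control_group_rejected(self):
        rows = [
            ("s1", "treated", "VEGF-A", 25.0),
            ("s1", "treated", "B2M", 20.0),
        ]
        with pytest.raises(InputError, match="control"):
            relative_expression(make_ct_table(rows))


class TestRounding:
    @pytest.mark.parametrize("x,expected", [(1.275, 1.28), (1.265, 1.27), (2.0, 2.0)])
    def test_round_half_up(self, x, expected):
        assert round_half_up(x) == expected
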