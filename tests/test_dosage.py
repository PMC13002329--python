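"""Dosage-balance statistics: regressions, group splits, correlations,
ploidy contrasts, expression comparison, and their distributional behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dosagebal import (
    CopySimSpec,
    expression_compare,
    ploidy_comparison,
    receptor_correlation,
    simulate_copy_number_table,
    simulate_expression_matrix,
    split_high_low,
    subfamily_regression,
)


def _table(asmt, comt, receptor=None):
    asmt, comt = np.asarray(asmt), np.asarray(comt)
    df = pd.DataFrame({"species": [f"s{i}" for i in range(len(asmt))],
                       "asmt": asmt, "comt": comt, "total": asmt + comt})
    if receptor is not None:
        df["receptor"] = receptor
    return df


class TestSubfamilyRegression:
    def test_noiseless_fixed_share(self):
        totals = np.array([10, 20, 30, 40, 50])
        asmt = (totals * 6) // 10  # exact 60% share at these totals
        table = _table(asmt, totals - asmt)
        reg = subfamily_regression(table)
        assert reg.slope_asmt == pytest.approx(0.6)
        assert reg.slope_comt == pytest.approx(0.4)
        assert reg.slope_ratio == pytest.approx(1.5)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.tuples(st.integers(0, 200), st.integers(0, 200)),
                    min_size=3, max_size=40))
    def test_slopes_sum_to_one_identity(self, counts):
        asmt = [a for a, _ in counts]
        comt = [c for _, c in counts]
        totals = np.array(asmt) + np.array(comt)
        if np.ptp(totals) == 0:
            return
        reg = subfamily_regression(_table(asmt, comt))
        assert reg.slope_asmt + reg.slope_comt == pytest.approx(1.0, abs=1e-9)

    def test_brassicaceae_like_low_share(self):
        table = simulate_copy_number_table(
            CopySimSpec(n_species=800, asmt_share=0.11, total_range=(2, 30), seed=0)
        )
        reg = subfamily_regression(table)
        assert reg.slope_ratio == pytest.approx(0.11 / 0.89, abs=0.03)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            subfamily_regression(_table([1, 2], [1, 2]))
        with pytest.raises(ValueError):
            subfamily_regression(_table([5, 5, 5], [5, 5, 5]))

    def test_invariant_to_row_order(self):
        table = simulate_copy_number_table(CopySimSpec(n_species=50, seed=3))
        shuffled = table.sample(frac=1, random_state=1)
        a = subfamily_regression(table)
        b = subfamily_regression(shuffled)
        assert a.slope_asmt == pytest.approx(b.slope_asmt)
        assert a.spearman_rho == pytest.approx(b.spearman_rho)


class TestSplitHighLow:
    def test_separated_clusters(self):
        split = split_high_low(np.array([10, 12, 14, 80, 85, 90]))
        assert list(split.labels) == ["low"] * 3 + ["high"] * 3
        assert split.boundary_low == 14 and split.boundary_high == 80

    def test_split_is_threshold_rule(self):
        rng = np.random.default_rng(0)
        totals = rng.integers(2, 150, size=200)
        split = split_high_low(totals)
        assert totals[split.labels == "low"].max() < totals[split.labels == "high"].min()

    def test_identical_groups_not_significant(self):
        totals = np.array([1.0] * 20 + [100.0] * 20)
        stat = np.array([0.5] * 40)
        split = split_high_low(totals, stat)
        assert split.t_p > 0.9 or np.isnan(split.t_p)

    def test_power_matches_monte_carlo_oracle(self):
        """Rejection rate under a planted share shift matches an independent
        Welch-t Monte-Carlo estimate within the binomial CI."""
        rng = np.random.default_rng(1)
        n_low, n_high, delta, sd = 200, 100, 0.06, 0.2
        totals = np.concatenate([rng.integers(2, 20, n_low), rng.integers(80, 120, n_high)])

        n_rep = 300
        rejections = 0
        for _ in range(n_rep):
            stat = np.concatenate(
                [rng.normal(0.5, sd, n_low), rng.normal(0.5 + delta, sd, n_high)]
            )
            split = split_high_low(totals, stat)
            rejections += split.t_p < 0.05
        observed_power = rejections / n_rep

        # independent oracle: direct Welch t simulation without the split
        oracle = 0
        for _ in range(2000):
            a = rng.normal(0.5, sd, n_low)
            b = rng.normal(0.5 + delta, sd, n_high)
            oracle += stats.ttest_ind(b, a, equal_var=False).pvalue < 0.05
        oracle_power = oracle / 2000
        ci = 3 * np.sqrt(oracle_power * (1 - oracle_power) / n_rep)
        assert abs(observed_power - oracle_power) < ci + 0.02

    def test_type_one_error_near_alpha_under_null(self):
        rng = np.random.default_rng(2)
        totals = np.array([5.0] * 30 + [100.0] * 30)
        n_rep = 2000
        rej_t = rej_u = 0
        for _ in range(n_rep):
            stat = rng.normal(0.5, 0.1, 60)
            split = split_high_low(totals, stat)
            rej_t += split.t_p < 0.05
            rej_u += split.u_p < 0.05
        ci = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rej_t / n_rep - 0.05) < ci
        assert abs(rej_u / n_rep - 0.05) < ci

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            split_high_low(np.array([3, 3, 3, 3]))
        with pytest.raises(ValueError):
            split_high_low(np.array([1, 2]))


class TestReceptorCorrelation:
    def test_receptor_equal_total_gives_rho_one(self):
        totals = np.arange(10, 30)
        table = _table(totals // 2, totals - totals // 2, receptor=totals)
        result = receptor_correlation(table)
        assert result.rho == pytest.approx(1.0)

    def test_estimates_true_rho_within_fisher_ci(self):
        """Simulated rank correlation ~0.3 at n=1052 lands in the analytic CI
        in nearly all seeds."""
        hits = 0
        n_seeds = 12
        rho_true = 0.3
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 1052
            z = rng.normal(size=n)
            total = z
            receptor = rho_true * z + np.sqrt(1 - rho_true**2) * rng.normal(size=n)
            table = _table(np.ones(n, int), np.ones(n, int), receptor=receptor)
            table["total"] = total
            result = receptor_correlation(table)
            # Fisher z 99.7% CI around the Pearson-equivalent rank correlation
            half = 3 / np.sqrt(n - 3)
            lo = np.tanh(np.arctanh(6 / np.pi * np.arcsin(rho_true / 2)) - half)
            hi = np.tanh(np.arctanh(6 / np.pi * np.arcsin(rho_true / 2)) + half)
            hits += lo <= result.rho <= hi
        assert hits >= n_seeds - 1

    def test_constant_receptor_flagged(self):
        totals = np.arange(10, 30)
        table = _table(totals // 2, totals - totals // 2, receptor=np.full(20, 2))
        result = receptor_correlation(table)
        assert result.rho is None
        assert result.undefined_reason == "constant_receptor_counts"

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            receptor_correlation(_table(np.arange(12), np.arange(12)))


class TestPloidyComparison:
    def test_printed_means_give_printed_fold_change(self):
        # deterministic tables with the published mean totals (144.06 vs 54.00)
        wheat = _table(np.full(36, 100), np.array([44] * 34 + [45, 45]))
        tauschii = _table(np.full(7, 40), np.full(7, 14))
        assert wheat["total"].mean() == pytest.approx(144.0555, abs=1e-3)
        comp = ploidy_comparison(wheat, tauschii)
        assert comp.fold_change_2dp == 2.67

    def test_identical_tables(self):
        table = simulate_copy_number_table(CopySimSpec(n_species=30, seed=1))
        comp = ploidy_comparison(table, table)
        assert comp.fold_change == pytest.approx(1.0)
        assert comp.t_total_p > 0.99

    def test_share_contrast_detected(self):
        a = simulate_copy_number_table(
            CopySimSpec(n_species=36, asmt_share=0.782, total_range=(120, 170), seed=2)
        )
        b = simulate_copy_number_table(
            CopySimSpec(n_species=7, asmt_share=0.721, total_range=(40, 70), seed=3)
        )
        comp = ploidy_comparison(a, b, share="comt")
        assert comp.mean_share_a < comp.mean_share_b

    def test_empty_table_rejected(self):
        table = simulate_copy_number_table(CopySimSpec(n_species=5, seed=0))
        with pytest.raises(ValueError):
            ploidy_comparison(table.iloc[:0], table)


class TestExpressionCompare:
    def test_all_below_threshold_rejected(self):
        fpkm = pd.DataFrame({"s1": [0.1, 0.2]}, index=["ASMT000", "COMT000"])
        labels = pd.Series(["ASMT", "COMT"], index=["ASMT000", "COMT000"])
        with pytest.raises(ValueError):
            expression_compare(fpkm, labels)

    def test_comt_shift_flags_direction_every_seed(self):
        for seed in range(20):
            fpkm, labels = simulate_expression_matrix(25, 25, 30, comt_shift=1.0, seed=seed)
            result = expression_compare(fpkm, labels)
            assert result.comt_higher

    def test_no_shift_direction_at_chance_rate(self):
        flags = [
            expression_compare(
                *simulate_expression_matrix(25, 25, 30, comt_shift=0.0, seed=seed)
            ).comt_higher
            for seed in range(40)
        ]
        assert 0.2 < np.mean(flags) < 0.8

    def test_mannwhitney_invariant_to_monotone_transform(self):
        fpkm, labels = simulate_expression_matrix(10, 10, 20, comt_shift=0.5, seed=1)
        base = expression_compare(fpkm, labels, outlier_rule="none")
        squared = expression_compare(fpkm**2, labels, fpkm_min=1.0, outlier_rule="none")
        assert squared.u_stat == pytest.approx(base.u_stat)
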