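import math

import numpy as np
import pytest
from scipy import stats as sps

from flarediary import (
    build_table1,
    compare_cluster_baselines,
    compare_cluster_features,
    paired_t_test,
    welch_t_test,
)
from flarediary.data import BaselineRecord
from flarediary.features import FeatureRow


class TestPairedT:
    def test_all_zero_diffs(self):
        res = paired_t_test([0.0] * 5)
        assert res.estimate == 0.0
        assert res.p_value == 1.0
        assert (res.ci_low, res.ci_high) == (0.0, 0.0)
        assert res.degenerate

    def test_frozen_example(self):
        res = paired_t_test([-1.0, -0.5, -1.5, -1.0])
        assert res.estimate == pytest.approx(-1.0)
        assert res.t_stat == pytest.approx(-4.89898, abs=1e-4)
        assert res.p_value == pytest.approx(0.01630, abs=1e-4)
        assert res.ci_low == pytest.approx(-1.6497, abs=1e-3)
        assert res.ci_high == pytest.approx(-0.3503, abs=1e-3)
        assert res.df == 3

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(5)
        diffs = list(rng.normal(-0.5, 1.0, size=12))
        a = paired_t_test(diffs)
        b = paired_t_test([-d for d in diffs])
        assert b.estimate == pytest.approx(-a.estimate)
        assert b.t_stat == pytest.approx(-a.t_stat)
        assert (b.ci_low, b.ci_high) == pytest.approx((-a.ci_high, -a.ci_low))
        assert b.p_value == pytest.approx(a.p_value)

    def test_degenerate_small_n(self):
        assert paired_t_test([]).degenerate
        one = paired_t_test([0.7])
        assert one.degenerate and one.estimate == pytest.approx(0.7)
        assert one.p_value is None

    def test_zero_spread_nonzero_mean(self):
        res = paired_t_test([0.5, 0.5, 0.5])
        assert res.p_value == 0.0 and res.degenerate
        assert res.ci_low == res.ci_high == pytest.approx(0.5)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            diffs = rng.normal(rng.normal(), rng.uniform(0.2, 2.0), size=rng.integers(2, 30))
            res = paired_t_test(list(diffs))
            t, p = sps.ttest_rel(diffs, np.zeros_like(diffs))
            assert res.t_stat == pytest.approx(t, rel=1e-10)
            assert res.p_value == pytest.approx(p, rel=1e-10)
            lo, hi = sps.t.interval(0.95, len(diffs) - 1, loc=diffs.mean(),
                                    scale=sps.sem(diffs))
            assert res.ci_low == pytest.approx(lo, rel=1e-9)
            assert res.ci_high == pytest.approx(hi, rel=1e-9)


class TestWelch:
    def test_identical_groups_null(self):
        res = welch_t_test([1, 2, 3], [1, 2, 3])
        assert res.t_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_frozen_example(self):
        # A mean 2, var 1 (n=3); B mean 3.5, var 5/3 (n=4):
        # t = -1.5/sqrt(1/3 + 5/12) = -1.7321, Satterthwaite df = 4.9592
        res = welch_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0, 5.0])
        assert res.t_stat == pytest.approx(-1.73205, abs=1e-4)
        assert res.df == pytest.approx(4.9592, abs=1e-3)
        assert res.p_value == pytest.approx(0.14429, abs=1e-4)

    def test_antisymmetry(self):
        a, b = [1.0, 2.5, 2.0], [4.0, 3.5, 5.0, 4.5]
        ab, ba = welch_t_test(a, b), welch_t_test(b, a)
        assert ba.t_stat == pytest.approx(-ab.t_stat)
        assert ba.df == pytest.approx(ab.df)
        assert ba.p_value == pytest.approx(ab.p_value)

    def test_small_group_degenerate(self):
        res = welch_t_test([1.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p_value is None
        assert res.reason

    def test_missing_values_dropped(self):
        res = welch_t_test([1.0, None, 2.0, np.nan, 3.0], [2.0, 3.0, 4.0, 5.0])
        assert res.n_a == 3

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            a = rng.normal(0, rng.uniform(0.5, 2), size=rng.integers(2, 25))
            b = rng.normal(rng.normal(), rng.uniform(0.5, 2), size=rng.integers(2, 25))
            res = welch_t_test(list(a), list(b))
            t, p = sps.ttest_ind(a, b, equal_var=False)
            assert res.t_stat == pytest.approx(t, rel=1e-10)
            assert res.p_value == pytest.approx(p, rel=1e-10)


class TestTable1:
    def _row(self, pid, diff):
        return FeatureRow(
            pid, {"pain": 3.0 + diff}, {"pain": 3.0}, {"pain": 5}, {"pain": 5}, 30
        )

    def test_varying_n_and_na_rows(self):
        rows = [self._row(f"P{i}", d) for i, d in enumerate([-1.0, -0.5, -1.5, -1.0])]
        table = build_table1(rows, ["pain", "stress"])
        assert table.loc["pain", "n"] == 4
        assert table.loc["pain", "estimated_difference"] == pytest.approx(-1.0)
        assert bool(table.loc["pain", "significant"]) is False  # p = 0.016 > 0.01
        assert table.loc["stress", "n"] == 0
        assert np.isnan(table.loc["stress", "estimated_difference"])

    def test_single_participant_all_degenerate(self):
        table = build_table1([self._row("P1", -1.0)], ["pain"])
        assert np.isnan(table.loc["pain", "p_value"])
        assert not table["significant"].any()


class TestClusterComparisons:
    def _cohort(self, shift):
        rows, labels = [], {}
        rng = np.random.default_rng(2)
        for i in range(20):
            cluster = int(i >= 12)
            diff = -0.4 - shift * cluster + rng.normal(0, 0.05)
            rows.append(
                FeatureRow(
                    f"P{i}", {"pain": 3.5 + diff}, {"pain": 3.5},
                    {"pain": 8}, {"pain": 20}, 30,
                )
            )
            labels[f"P{i}"] = cluster
        return rows, labels

    def test_identical_clusters_null(self):
        rows, labels = self._cohort(shift=0.0)
        table2, table3 = compare_cluster_features(rows, labels, ["pain"])
        assert table2.loc["pain", "p_value"] > 0.05
        assert table2.loc["pain", "n_group1"] == 12
        assert table3.loc[("flare_off", "pain"), "p_value"] == pytest.approx(1.0)

    def test_planted_shift_detected(self):
        rows, labels = self._cohort(shift=0.7)
        table2, _ = compare_cluster_features(rows, labels, ["pain"])
        assert table2.loc["pain", "p_value"] < 0.01

    def test_unobserved_variable_gets_na(self):
        rows, labels = self._cohort(shift=0.0)
        table2, table3 = compare_cluster_features(rows, labels, ["stress"])
        assert table2.loc["stress", "n_group1"] == 0
        assert np.isnan(table2.loc["stress", "p_value"])

    def test_baseline_binary_as_indicator(self):
        records, labels = [], {}
        rng = np.random.default_rng(4)
        for i in range(40):
            cluster = int(i >= 25)
            records.append(
                BaselineRecord(
                    f"P{i}",
                    {"basdai": float(rng.normal(4, 1))},
                    {"current_smoker": int(rng.random() < (0.6 if cluster == 0 else 0.05))},
                )
            )
            labels[f"P{i}"] = cluster
        table4 = compare_cluster_baselines(records, labels)
        assert table4.loc["current_smoker", "p_value"] < 0.05
        assert table4.loc["basdai", "p_value"] > 0.05
        # covariate never observed: NA row, not an exception
        assert np.isnan(table4.loc["basmi", "p_value"])
        assert table4.loc["basmi", "n_group1"] == 0
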