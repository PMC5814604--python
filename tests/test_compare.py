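import numpy as np
import pandas as pd
import pytest
from scipy import stats

from acticlust import ComparisonSpec, cluster_summary_table, compare_groups
from conftest import make_cohort, make_trace


def cohort_with_covariates(values: dict, n_per_group=None):
    """Build a cohort whose covariate table holds ``values`` (column -> array)."""
    n = len(next(iter(values.values())))
    ids = [f"P{i:04d}" for i in range(n)]
    cov = pd.DataFrame(values, index=pd.Index(ids, name="participant_id"))
    return make_cohort([make_trace(pid) for pid in ids], cov), ids


class TestContinuous:
    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(0)
        y = np.concatenate([rng.normal(0, 1, 30), rng.normal(1, 1, 30)])
        cohort, ids = cohort_with_covariates({"y": y})
        labels = {pid: int(i >= 30) for i, pid in enumerate(ids)}
        res = compare_groups(cohort, labels, [ComparisonSpec("y", "continuous")])[0]
        t, _ = stats.ttest_ind(y[:30], y[30:], equal_var=True)  # pooled t
        assert res.statistic == pytest.approx(t**2, abs=1e-9)
        assert res.df == (1, 58)

    def test_strong_separation_triggers_pairwise(self):
        rng = np.random.default_rng(1)
        y = np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50), rng.normal(0.1, 1, 50)])
        cohort, ids = cohort_with_covariates({"y": y})
        labels = {pid: i // 50 for i, pid in enumerate(ids)}
        res = compare_groups(cohort, labels, [ComparisonSpec("y", "continuous")])[0]
        assert res.p_value < 0.001
        assert len(res.pairwise) == 3
        sig = {(a, b): p for a, b, p in res.pairwise}
        assert sig[(0, 1)] < 0.001 and sig[(1, 2)] < 0.001

    def test_no_pairwise_when_overall_not_significant(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, 90)
        cohort, ids = cohort_with_covariates({"y": y})
        labels = {pid: i // 30 for i, pid in enumerate(ids)}
        res = compare_groups(cohort, labels, [ComparisonSpec("y", "continuous")])[0]
        if res.p_value >= 0.05:  # overwhelmingly likely under this seed's null draw
            assert res.pairwise == []

    def test_zero_variance_flagged_na(self):
        y = np.concatenate([np.full(10, 1.0), np.full(10, 2.0)])
        cohort, ids = cohort_with_covariates({"y": y})
        labels = {pid: int(i >= 10) for i, pid in enumerate(ids)}
        res = compare_groups(cohort, labels, [ComparisonSpec("y", "continuous")])[0]
        assert np.isnan(res.p_value)
        assert any("variance" in f for f in res.flags)
        assert res.pairwise == []

    def test_welch_default_differs_from_pooled_option(self):
        rng = np.random.default_rng(3)
        y = np.concatenate([rng.normal(0, 0.5, 20), rng.normal(1.1, 3.0, 60)])
        cohort, ids = cohort_with_covariates({"y": y})
        labels = {pid: int(i >= 20) for i, pid in enumerate(ids)}
        spec = [ComparisonSpec("y", "continuous")]
        welch = compare_groups(cohort, labels, spec, t_variant="welch")[0]
        pooled = compare_groups(cohort, labels, spec, t_variant="pooled")[0]
        if welch.pairwise and pooled.pairwise:
            assert welch.pairwise[0][2] != pooled.pairwise[0][2]


class TestCategorical:
    def test_identical_distributions_statistic_zero(self):
        levels = np.array(["a"] * 10 + ["b"] * 10)
        x = np.concatenate([levels, levels, levels])
        cohort, ids = cohort_with_covariates({"x": x})
        labels = {pid: i // 20 for i, pid in enumerate(ids)}
        res = compare_groups(cohort, labels, [ComparisonSpec("x", "categorical")])[0]
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.choice(["a", "b", "c"], 120)
        cohort, ids = cohort_with_covariates({"x": x})
        labels1 = {pid: i % 3 for i, pid in enumerate(ids)}
        labels2 = {pid: (i % 3 + 1) % 3 for i, pid in enumerate(ids)}  # relabeled
        r1 = compare_groups(cohort, labels1, [ComparisonSpec("x", "categorical")])[0]
        r2 = compare_groups(cohort, labels2, [ComparisonSpec("x", "categorical")])[0]
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_all_zero_level_dropped_with_warning(self):
        x = pd.Categorical(["a"] * 30 + ["b"] * 30, categories=["a", "b", "c"])
        cohort, ids = cohort_with_covariates({"x": x})
        labels = {pid: i // 30 for i, pid in enumerate(ids)}
        with pytest.warns(UserWarning, match="all-zero"):
            res = compare_groups(cohort, labels, [ComparisonSpec("x", "categorical")])[0]
        assert np.isfinite(res.statistic)

    def test_strong_association_pairwise(self):
        x = np.array(["a"] * 45 + ["b"] * 5 + ["a"] * 5 + ["b"] * 45 + ["a"] * 25 + ["b"] * 25)
        cohort, ids = cohort_with_covariates({"x": x})
        labels = {pid: i // 50 for i, pid in enumerate(ids)}
        res = compare_groups(cohort, labels, [ComparisonSpec("x", "categorical")])[0]
        assert res.p_value < 0.001
        assert len(res.pairwise) == 3


class TestValidationAndTable:
    def test_single_cluster_rejected(self):
        cohort, ids = cohort_with_covariates({"y": np.zeros(10)})
        with pytest.raises(ValueError, match="two clusters"):
            compare_groups(cohort, {pid: 0 for pid in ids}, [])

    def test_unknown_variable_rejected(self):
        cohort, ids = cohort_with_covariates({"y": np.zeros(10)})
        labels = {pid: i % 2 for i, pid in enumerate(ids)}
        with pytest.raises(KeyError):
            compare_groups(cohort, labels, [ComparisonSpec("nope", "continuous")])

    def test_bad_spec_type(self):
        with pytest.raises(ValueError):
            ComparisonSpec("y", "ordinal")

    def test_table_layout(self):
        rng = np.random.default_rng(5)
        y = rng.normal(50, 5, 60)
        x = rng.choice(["hs", "college"], 60)
        cohort, ids = cohort_with_covariates({"age": y, "education": x})
        labels = {pid: i // 20 for i, pid in enumerate(ids)}
        table = cluster_summary_table(
            cohort, labels, None,
            [ComparisonSpec("age", "continuous"), ComparisonSpec("education", "categorical")],
        )
        assert "cluster 0 (n=20)" in table.columns
        assert table.loc[0, "variable"] == "n"
        age_row = table[table["variable"] == "age"].iloc[0]
        # mean (SD) cell format
        assert "(" in age_row["cluster 0 (n=20)"] and ")" in age_row["cluster 0 (n=20)"]
        assert (table["variable"] == "education: hs").any()

    def test_empty_spec_list_gives_n_row_only(self):
        cohort, ids = cohort_with_covariates({"y": np.zeros(10)})
        labels = {pid: i % 2 for i, pid in enumerate(ids)}
        table = cluster_summary_table(cohort, labels, None, [])
        assert len(table) == 1 and table.loc[0, "variable"] == "n"

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(6)
        y = np.concatenate([rng.normal(0, 1, 40), rng.normal(1.5, 1, 40), rng.normal(3, 1, 40)])
        cohort, ids = cohort_with_covariates({"y": y})
        labels = {pid: i // 40 for i, pid in enumerate(ids)}
        spec = [ComparisonSpec("y", "continuous")]
        raw = compare_groups(cohort, labels, spec)[0]
        adj = compare_groups(cohort, labels, spec, adjust="holm")[0]
        for (_, _, p_raw), (_, _, p_adj) in zip(raw.pairwise, adj.pairwise):
            assert p_adj >= p_raw - 1e-12
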