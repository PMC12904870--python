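import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from snorelab.stats import (
    GroupSample,
    StatsConfig,
    cohens_d,
    cohens_d_from_samples,
    compare_groups,
    descriptive_table,
    mann_whitney_u,
    rank_biserial,
    select_test,
    student_t,
    welch_t,
)


def brute_force_mwu(a, b):
    """Exact U and two-sided p by enumerating all rank assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    u_obs = sum(
        1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
    )
    pooled = np.concatenate([a, b])
    n_a = len(a)
    mean_u = n_a * len(b) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        ua = sum(
            1.0 if x > y else (0.5 if x == y else 0.0)
            for x in pooled[mask] for y in pooled[~mask]
        )
        total += 1
        if abs(ua - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return u_obs, count / total


class TestDescriptives:
    def test_basic_cells(self):
        table = descriptive_table([GroupSample("f1_hz", "apnea", [1.0, 2.0, 3.0])])
        row = table.iloc[0]
        assert row["mean"] == 2.0 and row["sd"] == 1.0
        assert row["min"] == 1.0 and row["max"] == 3.0

    def test_single_value_sd_undefined(self):
        table = descriptive_table([GroupSample("f1_hz", "apnea", [5.0])])
        assert table.iloc[0]["mean"] == 5.0
        assert np.isnan(table.iloc[0]["sd"])

    def test_missing_values_dropped(self):
        s = GroupSample("hnr_db", "continuous", [1.0, np.nan, 3.0])
        assert s.n == 2


class TestSelectTest:
    def test_gaussian_equal_variance_student(self):
        rng = np.random.default_rng(42)
        a = GroupSample("x", "apnea", rng.normal(0, 1, 50))
        b = GroupSample("x", "continuous", rng.normal(0.3, 1, 50))
        assert select_test(a, b) == "student_t"

    def test_variance_ratio_four_welch(self):
        rng = np.random.default_rng(3)
        a = GroupSample("x", "apnea", rng.normal(0, 1, 80))
        b = GroupSample("x", "continuous", rng.normal(0, 2, 80))
        assert select_test(a, b) == "welch_t"

    def test_lognormal_skew_mann_whitney(self):
        rng = np.random.default_rng(1)
        a = GroupSample("x", "apnea", rng.lognormal(0, 1, 80))
        b = GroupSample("x", "continuous", rng.normal(0, 1, 80))
        assert select_test(a, b) == "mann_whitney"

    def test_too_few_values_demands_explicit_choice(self):
        a = GroupSample("x", "apnea", [1.0, 2.0])
        b = GroupSample("x", "continuous", [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="test_override"):
            select_test(a, b)


class TestTwoSampleTests:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        stat, p = student_t(a, a.copy())
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_pair_counting_u(self):
        u, _ = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0

    def test_exact_p_shifted_groups(self):
        """a = {1..4}, b = a + 10: the most extreme of C(8,4) = 70 rank splits
        in both tails, p = 2/70."""
        a = np.array([1.0, 2.0, 3.0, 4.0])
        _, p = mann_whitney_u(a, a + 10.0)
        assert p == pytest.approx(2.0 / 70.0)

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            a = rng.permutation(np.arange(1.0, 11.0))[:4]
            b = np.setdiff1d(np.arange(1.0, 11.0), a) + rng.uniform(0, 0.3)
            u_ref, p_ref = brute_force_mwu(a, b)
            u, p = mann_whitney_u(a, b)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref, rel=1e-12)

    def test_zero_variance_equal_means_convention(self):
        a = np.array([2.0, 2.0, 2.0])
        assert student_t(a, a)[1] == 1.0
        assert welch_t(a, a)[1] == 1.0
        assert mann_whitney_u(a, a)[1] == 1.0

    def test_welch_equals_student_under_equal_variance_and_n(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        b = (b - b.mean()) / b.std(ddof=1) * a.std(ddof=1) + b.mean()
        assert welch_t(a, b)[0] == pytest.approx(student_t(a, b)[0])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        a=st_h.lists(st_h.integers(0, 20), min_size=2, max_size=12),
        b=st_h.lists(st_h.integers(0, 20), min_size=2, max_size=12),
    )
    def test_u_antisymmetry_with_ties(self, a, b):
        u_ab, _ = mann_whitney_u(np.array(a, float), np.array(b, float))
        u_ba, _ = mann_whitney_u(np.array(b, float), np.array(a, float))
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))


class TestEffectSizes:
    def test_equal_weight_pooling_from_summaries(self):
        d = cohens_d(846.73, 218.27, None, 929.28, 234.76, None)
        assert d == pytest.approx(-0.3642, abs=5e-4)

    def test_equal_means_zero(self):
        assert cohens_d(5.0, 1.0, 10, 5.0, 2.0, 10) == 0.0

    def test_zero_spread_undefined(self):
        assert np.isnan(cohens_d(1.0, 0.0, None, 2.0, 0.0, None))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        a=st_h.lists(st_h.floats(-50, 50), min_size=3, max_size=20),
        b=st_h.lists(st_h.floats(-50, 50), min_size=3, max_size=20),
    )
    def test_cohens_d_antisymmetry(self, a, b):
        a, b = np.array(a), np.array(b)
        if np.std(a, ddof=1) + np.std(b, ddof=1) == 0:
            return
        d_ab = cohens_d_from_samples(a, b)
        d_ba = cohens_d_from_samples(b, a)
        assert d_ab == pytest.approx(-d_ba, rel=1e-9, abs=1e-12)

    def test_rank_biserial_endpoints(self):
        assert rank_biserial(12.0, 3, 4) == 1.0
        assert rank_biserial(6.0, 3, 4) == 0.0
        u, _ = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert rank_biserial(u, 2, 2) == -1.0

    def test_rank_biserial_bounds(self):
        with pytest.raises(ValueError):
            rank_biserial(13.0, 3, 4)


class TestCompareGroups:
    @staticmethod
    def _frame(rng, delta=0.0):
        n = 40
        return pd.DataFrame({
            "label": ["preapneic"] * n + ["continuous"] * n,
            "f1_hz": np.r_[rng.normal(850 + delta, 200, n), rng.normal(850, 200, n)],
            "ser": np.r_[10 ** rng.normal(-0.8, 0.6, n), 10 ** rng.normal(-0.8, 0.6, n)],
        })

    def test_identical_groups_nothing_flagged(self, rng):
        df = self._frame(rng)
        results = compare_groups(df, variables=["f1_hz", "log_ser"])
        assert not any(r.significant for r in results)

    def test_log_transform_applied_to_ser(self, rng):
        df = self._frame(rng)
        results = compare_groups(df, variables=["f1_hz", "log_ser"])
        names = [r.variable for r in results]
        assert "log_ser" in names and "ser" not in names

    def test_constant_variable_convention_row(self, rng):
        df = self._frame(rng)
        df["f1_hz"] = 100.0
        row = compare_groups(df, variables=["f1_hz"])[0]
        assert row.p_value == 1.0
        assert not row.significant

    def test_effect_kind_matches_test(self, rng):
        df = self._frame(rng, delta=150.0)
        df["skewed"] = 10 ** np.r_[rng.normal(0, 1, 40), rng.normal(0, 1, 40)]
        for r in compare_groups(df, variables=["f1_hz", "skewed"]):
            if r.test == "mann_whitney":
                assert r.effect_kind == "rank_biserial"
                assert -1.0 <= r.effect_size <= 1.0
            else:
                assert r.effect_kind == "cohens_d"

    def test_reported_assignment_override(self, rng):
        from snorelab.stats import REPORTED_TEST_ASSIGNMENT

        df = self._frame(rng)
        cfg = StatsConfig(test_override=REPORTED_TEST_ASSIGNMENT)
        results = compare_groups(df, cfg, variables=["f1_hz", "log_ser"])
        by_var = {r.variable: r.test for r in results}
        assert by_var == {"f1_hz": "student_t", "log_ser": "welch_t"}
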