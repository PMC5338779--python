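import itertools

import numpy as np
import pandas as pd
import pytest

from oracles import (
    km_oracle,
    logrank_permutation_p,
    mann_whitney_exact_oracle,
    quantile_oracle,
)
from channelscreen import survival_assoc as sv
from channelscreen.types import SurvivalTable, ValidationError


def _table(times, events, expression=None, index=None):
    idx = index or [f"p{i}" for i in range(len(times))]
    df = pd.DataFrame({"time": times, "event": events}, index=idx)
    if expression is not None:
        df["expression"] = expression
    return SurvivalTable(df)


class TestQuantileStratification:
    def test_extreme_deciles_of_1_to_100(self):
        values = pd.Series(np.arange(1.0, 101.0), index=[f"p{i}" for i in range(100)])
        labels = sv.stratify_quantile(values)
        assert (labels == "low").sum() == 10  # values 1..10 <= Q(0.10) = 10.9
        assert (labels == "high").sum() == 10
        assert (labels == "excluded").sum() == 80

    def test_full_range_cutoffs_select_extremes(self):
        values = pd.Series(np.arange(10.0), index=[f"p{i}" for i in range(10)])
        labels = sv.stratify_quantile(values, lo=0.0, hi=1.0)
        assert list(values[labels == "low"]) == [0.0]
        assert list(values[labels == "high"]) == [9.0]

    def test_matches_sort_and_interpolate_oracle(self):
        rng = np.random.default_rng(31)
        values = pd.Series(rng.uniform(0, 50, 20), index=[f"p{i}" for i in range(20)])
        labels = sv.stratify_quantile(values)
        q_lo = quantile_oracle(list(values), 0.10)
        q_hi = quantile_oracle(list(values), 0.90)
        for s, v in values.items():
            expected = "low" if v <= q_lo else "high" if v >= q_hi else "excluded"
            assert labels[s] == expected

    def test_constant_values_rejected(self):
        values = pd.Series(3.0, index=[f"p{i}" for i in range(12)])
        with pytest.raises(ValidationError, match="identical"):
            sv.stratify_quantile(values)


class TestMedianStratification:
    def test_even_split(self):
        values = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        labels = sv.stratify_median(values)
        assert set(values[labels == "low"]) == {1.0, 2.0}
        assert set(values[labels == "high"]) == {3.0, 4.0}

    def test_supplied_median_overrides(self):
        values = pd.Series({"a": 3.9, "b": 3.91})
        labels = sv.stratify_median(values, median_value=3.908)
        assert labels["a"] == "low"
        assert labels["b"] == "high"

    def test_tie_with_median_goes_low(self):
        values = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        labels = sv.stratify_median(values)  # median = 2.0
        assert labels["b"] == "low"


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        curve = sv.km_estimate(_table([1.0, 2.0, 3.0], [1, 1, 1]))
        assert np.allclose(curve.times, [1.0, 2.0, 3.0])
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        assert curve.median == 2.0

    def test_all_censored_flat_curve_no_median(self):
        curve = sv.km_estimate(_table([5.0, 8.0, 2.0], [0, 0, 0]))
        assert curve.times.size == 0
        assert curve.median is None

    def test_matches_product_limit_oracle_on_mixed_table(self):
        times = [3.0, 5.0, 5.0, 8.0, 10.0, 12.0, 12.0, 15.0]
        events = [1, 0, 1, 1, 0, 1, 1, 0]
        curve = sv.km_estimate(_table(times, events))
        expected = km_oracle(times, events)
        assert np.allclose(curve.times, [t for t, _ in expected])
        assert np.allclose(curve.survival, [s for _, s in expected])

    def test_curve_non_increasing_on_random_tables(self):
        rng = np.random.default_rng(44)
        for _ in range(10):
            n = int(rng.integers(5, 40))
            times = rng.exponential(100, n).round(1)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            curve = sv.km_estimate(_table(times, events))
            assert np.all(np.diff(curve.survival) <= 1e-12)
            assert curve.survival.max() <= 1.0 + 1e-12


class TestLogRank:
    def _strata(self, labels, index):
        return pd.Series(labels, index=index, name="stratum")

    def test_identical_groups_statistic_zero(self):
        times = [2.0, 4.0, 6.0, 2.0, 4.0, 6.0]
        events = [1, 1, 0, 1, 1, 0]
        table = _table(times, events)
        strata = self._strata(["a"] * 3 + ["b"] * 3, table.data.index)
        res = sv.logrank_test(table, strata)
        assert np.isclose(res.chi2, 0.0, atol=1e-12)
        assert np.isclose(res.p_value, 1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(13)
        times = rng.exponential(50, 20).round(1)
        events = rng.integers(0, 2, 20)
        events[:2] = 1
        table = _table(times, events)
        labels = ["a"] * 10 + ["b"] * 10
        res1 = sv.logrank_test(table, self._strata(labels, table.data.index))
        flipped = ["b" if l == "a" else "a" for l in labels]
        res2 = sv.logrank_test(table, self._strata(flipped, table.data.index))
        assert np.isclose(res1.chi2, res2.chi2, atol=1e-10)

    def test_time_shift_invariance(self):
        rng = np.random.default_rng(19)
        times = rng.exponential(50, 16).round(1)
        events = rng.integers(0, 2, 16)
        events[:2] = 1
        labels = ["a"] * 8 + ["b"] * 8
        t1 = _table(times, events)
        t2 = _table(times + 100.0, events)
        res1 = sv.logrank_test(t1, self._strata(labels, t1.data.index))
        res2 = sv.logrank_test(t2, self._strata(labels, t2.data.index))
        assert np.isclose(res1.chi2, res2.chi2, atol=1e-10)

    def test_p_close_to_permutation_oracle_on_toy(self):
        times = [5.0, 8.0, 12.0, 20.0, 25.0, 30.0, 3.0, 6.0, 9.0, 11.0, 14.0, 40.0]
        events = [1, 1, 0, 1, 1, 0, 1, 1, 1, 1, 0, 1]
        labels = ["hi"] * 6 + ["lo"] * 6
        table = _table(times, events)
        res = sv.logrank_test(table, self._strata(labels, table.data.index))
        p_perm = logrank_permutation_p(times, events, labels, n_perm=20_000, seed=0)
        # chi-square approximation vs exact permutation; MC sd ~ 0.004 here
        assert abs(res.p_value - p_perm) < 0.05

    def test_empty_stratum_is_error(self):
        table = _table([1.0, 2.0], [1, 1])
        strata = self._strata(["a", "a"], table.data.index)
        with pytest.raises(ValidationError, match="2 non-empty strata"):
            sv.logrank_test(table, strata)


class TestMannWhitney:
    def test_complete_separation_forced_p(self):
        u, p = sv.mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert u == 0.0
        assert np.isclose(p, 0.1)  # 2/20 orderings as extreme

    def test_identical_multisets_u_half(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, _ = sv.mann_whitney(x, list(x))
        assert u == len(x) * len(x) / 2

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(23)
        for n1, n2 in [(2, 3), (3, 3), (4, 5), (5, 6), (6, 6)]:
            x = list(rng.normal(0, 1, n1))
            y = list(rng.normal(0.5, 1, n2))
            u, p = sv.mann_whitney(x, y)
            u_exp, p_exp = mann_whitney_exact_oracle(x, y)
            assert np.isclose(u, u_exp)
            assert np.isclose(p, p_exp, atol=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            sv.mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_two_group_agreement_with_mann_whitney(self):
        rng = np.random.default_rng(27)
        x = list(rng.normal(0, 1, 15))
        y = list(rng.normal(0.8, 1, 12))
        _, p_kw = sv.kruskal_wallis([x, y])
        # force the asymptotic route by exceeding the exact-size cutoff
        _, p_mw = sv.mann_whitney(x, y)
        assert np.isclose(p_kw, p_mw, atol=1e-6)

    def test_strong_shift_is_significant(self):
        rng = np.random.default_rng(29)
        groups = [list(rng.normal(0, 1, 20)), list(rng.normal(0, 1, 20)),
                  list(rng.normal(5, 1, 20))]
        _, p = sv.kruskal_wallis(groups)
        assert p <= 1e-4

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(30)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            groups = [list(rng.normal(0, 1, 10)) for _ in range(3)]
            _, p = sv.kruskal_wallis(groups)
            rejections += p < 0.05
        assert abs(rejections / n_rep - 0.05) < 0.03

    def test_identical_observations_rejected(self):
        with pytest.raises(ValidationError, match="identical"):
            sv.kruskal_wallis([[1.0, 1.0], [1.0, 1.0]])


class TestMutationAssociation:
    def _expression(self, rng, isolates, shifted=None, gene="gX"):
        vals = rng.lognormal(1, 0.5, len(isolates))
        if shifted:
            for i, iso in enumerate(isolates):
                if iso in shifted:
                    vals[i] *= 4.0
        return pd.DataFrame([vals], index=[gene], columns=isolates)

    def test_rare_mutation_skipped(self):
        rng = np.random.default_rng(40)
        isolates = [f"i{k}" for k in range(10)]
        expr = self._expression(rng, isolates)
        flags = pd.DataFrame(
            {"EGFR": ["mutant"] * 2 + ["wildtype"] * 8}, index=isolates
        )
        out = sv.mutation_association(expr, flags, min_mutant=3)
        assert len(out) == 0

    def test_common_mutation_tested(self):
        rng = np.random.default_rng(41)
        isolates = [f"i{k}" for k in range(12)]
        flags = pd.DataFrame(
            {"TP53": ["mutant"] * 5 + ["wildtype"] * 7}, index=isolates
        )
        expr = self._expression(rng, isolates, shifted=set(isolates[:5]))
        out = sv.mutation_association(expr, flags)
        assert len(out) == 1
        assert out.iloc[0]["mutation"] == "TP53"
        assert out.iloc[0]["p_value"] < 0.05

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(42)
        isolates = [f"i{k}" for k in range(20)]
        flags = pd.DataFrame(
            {"NF1": ["mutant"] * 8 + ["wildtype"] * 12}, index=isolates
        )
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            expr = self._expression(rng, isolates)
            out = sv.mutation_association(expr, flags)
            rejections += bool(out.iloc[0]["p_value"] < 0.05)
        assert abs(rejections / n_rep - 0.05) < 0.035

    def test_planted_shift_power(self):
        rng = np.random.default_rng(43)
        isolates = [f"i{k}" for k in range(20)]
        flags = pd.DataFrame(
            {"MET": ["mutant"] * 8 + ["wildtype"] * 12}, index=isolates
        )
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            expr = self._expression(rng, isolates, shifted=set(isolates[:8]))
            out = sv.mutation_association(expr, flags)
            hits += bool(out.iloc[0]["p_value"] < 0.05)
        assert hits / n_rep >= 0.80
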