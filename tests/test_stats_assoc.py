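import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from pneumabio.stats_assoc import (
    association_table,
    bh_fdr,
    firth_logistic,
    logistic_or_per_sd,
    penalised_loglik,
    rank_compare,
    table_one,
)


class TestBhFdr:
    def test_worked_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_bruteforce_stepup(self, ps):
        q = bh_fdr(ps)
        m = len(ps)
        order = sorted(range(m), key=lambda i: ps[i])
        expected = [0.0] * m
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, ps[i] * m / rank)
            expected[i] = min(running, 1.0)
        assert np.allclose(q, expected, atol=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        assert np.all(bh_fdr(p) >= p - 1e-15)


class TestLogisticOrPerSd:
    def test_null_feature(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        y = rng.random(2000) < 0.3
        row = logistic_or_per_sd(x, y)
        assert 0.9 <= row.odds_ratio <= 1.1
        assert row.scaling == "per_sd"

    def test_binary_cross_product(self):
        # exposed: 10 deaths / 40 survivors; unexposed: 5 / 45 -> OR 2.25
        x = np.concatenate([np.ones(50), np.zeros(50)])
        y = np.concatenate([np.ones(10), np.zeros(40), np.ones(5), np.zeros(45)])
        row = logistic_or_per_sd(x, y, binary=True)
        assert row.odds_ratio == pytest.approx((10 * 45) / (40 * 5), rel=1e-6)
        assert row.scaling == "binary"

    def test_planted_per_sd_or(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        p = expit(-1.0 + np.log(2.0) * x)
        y = rng.random(2000) < p
        row = logistic_or_per_sd(x, y)
        assert 1.8 <= row.odds_ratio <= 2.2

    def test_ci_brackets_or(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        y = rng.random(500) < expit(0.5 * x)
        row = logistic_or_per_sd(x, y)
        assert row.ci_low < row.odds_ratio < row.ci_high
        assert row.odds_ratio == pytest.approx(np.exp(row.beta))

    def test_separation_status(self):
        x = np.concatenate([np.ones(20), np.zeros(20)])
        y = x.copy()
        row = logistic_or_per_sd(x, y, binary=True)
        assert row.status == "separation"
        assert np.isnan(row.odds_ratio)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            logistic_or_per_sd(np.arange(10.0), np.zeros(10))

    def test_association_table_fdr(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(5):
            x = rng.standard_normal(300)
            y = rng.random(300) < 0.3
            rows.append(logistic_or_per_sd(x, y, feature=f"f{i}"))
        df = association_table(rows, apply_fdr=True)
        assert np.all(df["q_value"] >= df["p_value"] - 1e-15)


def make_2x2(a, b, c, d):
    """exposure=1: a events / b non-events; exposure=0: c events / d non-events."""
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    return x, y


class TestFirth:
    def test_haldane_equivalence_2x2(self):
        x, y = make_2x2(0, 10, 5, 5)
        res = firth_logistic(x[:, None], y)
        expected_or = (0.5 * 5.5) / (10.5 * 5.5)
        assert res.converged
        assert np.exp(res.beta[1]) == pytest.approx(expected_or, rel=1e-4)

    def test_grid_search_oracle_2x2(self):
        # brute-force maximisation of the written penalised likelihood
        from scipy.optimize import minimize_scalar

        x, y = make_2x2(2, 8, 6, 4)
        X = np.column_stack([np.ones_like(x), x])
        res = firth_logistic(x[:, None], y)
        grid = np.linspace(res.beta[1] - 0.02, res.beta[1] + 0.02, 401)
        best = None
        for b1 in grid:
            # profile out the intercept at each slope value
            prof = minimize_scalar(
                lambda b0: -penalised_loglik(X, y, np.array([b0, b1])),
                bounds=(-5, 5), method="bounded",
                options={"xatol": 1e-10},
            )
            ll = -prof.fun
            if best is None or ll > best[1]:
                best = (b1, ll)
        assert res.beta[1] == pytest.approx(best[0], abs=1e-4)

    def test_null_data_beta_near_zero(self):
        x, y = make_2x2(10, 10, 10, 10)
        res = firth_logistic(x[:, None], y)
        assert abs(res.beta[1]) < 1e-6

    def test_finite_under_separation(self):
        x = np.concatenate([np.ones(15), np.zeros(15)])
        y = x.copy()
        res = firth_logistic(x[:, None], y)
        assert np.all(np.isfinite(res.beta))
        assert np.all(np.isfinite(res.se))

    def test_rank_deficient_rejected(self):
        X = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(ValueError):
            firth_logistic(X, np.random.default_rng(0).integers(0, 2, 20), add_intercept=False)

    def test_multi_predictor_runs(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((121, 3))
        p = expit(-1.7 + X @ np.array([0.8, 0.4, 0.1]))
        y = (rng.random(121) < p).astype(float)
        res = firth_logistic(X, y)
        assert res.converged
        assert res.beta.shape == (4,)
        assert np.all(res.ci_low < res.beta) and np.all(res.beta < res.ci_high)


class TestRankCompare:
    def test_complete_separation(self):
        res = rank_compare([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.rank_biserial == pytest.approx(1.0)

    def test_identical_groups_r_zero(self):
        res = rank_compare([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.rank_biserial == pytest.approx(0.0)

    def test_reverse_separation(self):
        res = rank_compare([4, 5, 6], [1, 2, 3])
        assert res.rank_biserial == pytest.approx(-1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_compare([], [1.0])

    def test_exact_vs_asymptotic_switch(self):
        small = rank_compare(np.arange(5) + 0.1, np.arange(5) + 0.35)
        assert small.method == "exact"
        rng = np.random.default_rng(0)
        big = rank_compare(rng.random(30), rng.random(30))
        assert big.method == "asymptotic"


class TestTableOne:
    def _cohort(self):
        rng = np.random.default_rng(0)
        n = 121
        death = np.zeros(n, dtype=int)
        death[:19] = 1
        return pd.DataFrame({
            "death": death,
            "age": rng.normal(66, 12, n),
            "los": rng.exponential(11, n),
            "sex": rng.choice(["F", "M"], n),
        })

    def test_death_row_counts(self):
        df = self._cohort()
        t = table_one(df, "sex", variables=["death"])
        row = t[(t["variable"] == "death") & (t["level"] == "1")].iloc[0]
        assert row["overall"] == "19 (15.7)"

    def test_constant_variable_p_one(self):
        df = self._cohort()
        df["const"] = 5.0
        t = table_one(df, "death", variables=["const"])
        assert t.iloc[0]["p_value"] == 1.0

    def test_zero_cell_takes_fisher(self):
        df = pd.DataFrame({
            "grp": [0] * 10 + [1] * 10,
            "flag": [0] * 10 + [1] * 3 + [0] * 7,
        })
        t = table_one(df, "grp", variables=["flag"])
        assert t.iloc[0]["test"] == "fisher"

    def test_continuous_gets_rank_test(self):
        df = self._cohort()
        t = table_one(df, "death", variables=["los"])
        assert t.iloc[0]["test"] in ("mannwhitney", "t")
        assert 0.0 <= t.iloc[0]["p_value"] <= 1.0

    def test_nonbinary_group_rejected(self):
        df = self._cohort()
        df["g3"] = np.arange(len(df)) % 3
        with pytest.raises(ValueError):
            table_one(df, "g3")
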