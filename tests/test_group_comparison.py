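"""Rank-based tests against hand-built enumeration and arithmetic oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hemri import (
    comparison_table,
    kruskal_wallis,
    ks_normality,
    mann_whitney_u,
)


def mwu_enumeration_oracle(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration (tie-free data)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx = len(x)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = np.array([
        ranks[list(combo)].sum() - nx * (nx + 1) / 2
        for combo in itertools.combinations(range(len(pooled)), nx)
    ])
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


def ks_ecdf_sweep_oracle(values):
    """Max ECDF deviation from the fitted normal, by direct sweep."""
    s = np.sort(values)
    n = s.size
    f = stats.norm.cdf(s, np.mean(values), np.std(values, ddof=1))
    upper = np.abs(np.arange(1, n + 1) / n - f)
    lower = np.abs(np.arange(0, n) / n - f)
    return max(upper.max(), lower.max())


class TestKSNormality:
    def test_statistic_equals_ecdf_sweep_on_fixed_sample(self):
        vals = np.array([2.1, 3.4, 1.9, 5.6, 4.4, 2.8, 3.1, 6.0, 2.2, 3.9])
        res = ks_normality(vals)
        assert res.statistic == pytest.approx(ks_ecdf_sweep_oracle(vals), abs=1e-12)
        assert 0.0 <= res.statistic <= 1.0

    def test_normal_data_rarely_flagged(self, rng):
        """Fitted-parameter KS is conservative: high p on normal draws."""
        hits = sum(
            ks_normality(rng.normal(size=1000)).p_value > 0.05
            for _ in range(50)
        )
        assert hits >= 45

    def test_zero_variance_degenerate_convention(self):
        res = ks_normality(np.full(20, 3.3))
        assert res.statistic == 1.0 and res.p_value == 0.0

    def test_corrected_variant_is_less_conservative(self, rng):
        vals = rng.normal(size=200)
        plain = ks_normality(vals)
        lillie = ks_normality(vals, corrected=True)
        assert lillie.p_value <= plain.p_value + 1e-9


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.100, abs=1e-12)

    def test_identical_samples_centered_u(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 4.5  # n^2/2
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_all_values_identical_degenerate(self):
        res = mann_whitney_u([2.0] * 5, [2.0] * 4)
        assert res.statistic == 10.0 and res.p_value == 1.0

    @pytest.mark.parametrize("nx,ny", [(n, m) for n in range(2, 7)
                                       for m in range(n, 7)])
    def test_exact_p_matches_full_enumeration(self, nx, ny, rng):
        """All group sizes <= (6,6): exact p equals the enumeration oracle."""
        for _ in range(3):
            pooled = rng.permutation(np.arange(1.0, nx + ny + 1))
            x, y = pooled[:nx], pooled[nx:]
            res = mann_whitney_u(x, y, method="exact")
            assert res.p_value == pytest.approx(
                mwu_enumeration_oracle(x, y), abs=1e-12
            )

    def test_exact_and_asymptotic_agree_at_moderate_n(self, rng):
        """Tie-free n=(7,7): exact and asymptotic p agree to < 0.01 on
        average (worst case ~0.012, near the p=0.5 doubling boundary)."""
        diffs = []
        for _ in range(50):
            pooled = rng.permutation(np.arange(1.0, 15.0))
            x, y = pooled[:7], pooled[7:]
            pe = mann_whitney_u(x, y, method="exact").p_value
            pa = mann_whitney_u(x, y, method="asymptotic").p_value
            diffs.append(abs(pe - pa))
        assert np.mean(diffs) < 0.01
        assert max(diffs) < 0.02

    def test_invariance_under_monotone_transform(self, rng):
        x, y = rng.normal(size=30) + 2.1, rng.normal(size=40)
        r1 = mann_whitney_u(x, y)
        r2 = mann_whitney_u(np.exp(x), np.exp(y))
        assert r1.statistic == r2.statistic
        assert r1.p_value == r2.p_value


class TestKruskalWallis:
    def test_hand_rank_sum_arithmetic(self):
        """{1,2},{3,4},{5,6}: H = 12/(6*7) * sum R_i^2/n_i - 3*7 = 32/7."""
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        h_hand = 12 / (6 * 7) * (3**2 / 2 + 7**2 / 2 + 11**2 / 2) - 3 * 7
        assert res.statistic == pytest.approx(h_hand, abs=1e-12)

    def test_identical_groups_no_separation(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_two_group_h_equals_squared_mwu_z(self, rng):
        """For k=2 the H-test is the squared MWU z (no continuity corr.)."""
        x, y = rng.normal(size=40), rng.normal(0.3, 1, size=35)
        kw = kruskal_wallis([x, y])
        mw = mann_whitney_u(x, y, method="asymptotic", use_continuity=False)
        assert kw.p_value == pytest.approx(mw.p_value, abs=1e-9)
        z = stats.norm.isf(mw.p_value / 2)
        assert kw.statistic == pytest.approx(z**2, rel=1e-6)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


class TestComparisonTable:
    @staticmethod
    def _frame(rng, shift_t3=0.0, np_empty=False):
        rows = []
        for part in ("T1", "T2", "T3", "NP"):
            if np_empty and part == "NP":
                continue
            n = 130
            vals = rng.normal(10.0, 2.0, n)
            if part == "T3":
                vals = vals + shift_t3
            rows.append(pd.DataFrame({"partition": part, "X": vals}))
        return pd.concat(rows, ignore_index=True)

    def test_large_shift_detected(self, rng):
        table = comparison_table(self._frame(rng, shift_t3=2.0), ["X"])
        row = table.iloc[0]
        assert row["T1_vs_T3_p"] < 0.05
        assert row["trimesters_p"] < 0.05

    def test_empty_partition_marked_unavailable(self, rng):
        table = comparison_table(
            self._frame(rng, np_empty=True), ["X"],
            partitions=("T1", "T2", "T3"),
        )
        row = table.iloc[0]
        assert np.isnan(row["pregnant_vs_np_p"])
        assert not np.isnan(row["trimesters_p"])

    def test_null_type_i_error_controlled(self, rng):
        """Identical partition distributions: ~5% of tests significant."""
        hits = 0
        trials = 500
        for _ in range(trials):
            x = rng.normal(size=130)
            y = rng.normal(size=130)
            hits += mann_whitney_u(x, y).p_value < 0.05
        assert 0.03 <= hits / trials <= 0.07

    def test_bonferroni_scales_pairwise_p(self, rng):
        frame = self._frame(rng)
        plain = comparison_table(frame, ["X"])
        adj = comparison_table(frame, ["X"], bonferroni=True)
        expected = min(1.0, 3 * plain.iloc[0]["T1_vs_T2_p"])
        assert adj.iloc[0]["T1_vs_T2_p"] == pytest.approx(expected)
        assert adj.iloc[0]["pregnant_vs_np_p"] == \
            pytest.approx(plain.iloc[0]["pregnant_vs_np_p"])
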