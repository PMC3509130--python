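"""Differential-abundance decision procedure: prefilter, Wilcoxon, Storey q."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from mproteo.errors import ConfigurationError
from mproteo.quant import AbundanceMatrix
from mproteo.stats import (
    call_differential,
    prefilter_features,
    storey_q,
    wilcoxon_p,
)


def matrix(data, runs):
    df = pd.DataFrame(data, columns=runs)
    df.index = [f"f{i}" for i in range(len(df))]
    return AbundanceMatrix(df.astype(float), "cluster", True)


RUNS_A = [f"a{i}" for i in range(4)]
RUNS_B = [f"b{i}" for i in range(4)]


class TestPrefilter:
    @pytest.mark.parametrize(
        "row, eligible",
        [
            ([6, 6, 6, 0, 0, 0, 0, 0], False),  # >5 in only 3 runs
            ([6, 6, 6, 6, 0, 0, 0, 0], True),   # >5 in exactly 4 runs
            ([5, 5, 5, 5, 5, 5, 5, 5], False),  # exactly 5 is not "more than 5"
        ],
    )
    def test_pooled_rule(self, row, eligible):
        m = matrix([row], RUNS_A + RUNS_B)
        got = prefilter_features(m, RUNS_A, RUNS_B)
        assert (got == ["f0"]) is eligible

    def test_small_group_rejected(self):
        m = matrix([[6] * 5], ["a0", "a1", "a2", "a3", "b0"])
        with pytest.raises(ConfigurationError):
            prefilter_features(m, RUNS_A, ["b0"])


def brute_force_ranksum_p(x, y):
    """Two-sided permutation p-value of the rank-sum statistic."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n = len(x)
    observed = ranks[:n].sum()
    expected = ranks.mean() * n
    stats = [
        ranks[list(idx)].sum()
        for idx in itertools.combinations(range(len(pooled)), n)
    ]
    stats = np.asarray(stats)
    return float(
        np.mean(np.abs(stats - expected) >= np.abs(observed - expected) - 1e-12)
    )


class TestWilcoxon:
    def test_complete_separation_small_sample(self):
        # 2/20 labelings are as extreme as [1,2,3] vs [4,5,6]
        assert wilcoxon_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups(self):
        assert wilcoxon_p([2, 2, 2], [2, 2, 2]) == 1.0

    def test_symmetry(self):
        x, y = [1.0, 5.0, 3.0], [2.0, 8.0, 9.0, 4.0]
        assert wilcoxon_p(x, y) == pytest.approx(wilcoxon_p(y, x))

    def test_exact_agrees_with_brute_force_4v4(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            vals = rng.permutation(rng.uniform(0, 10, 8))
            x, y = vals[:4], vals[4:]
            assert wilcoxon_p(x, y) == pytest.approx(
                brute_force_ranksum_p(x, y), abs=1e-12
            )

    def test_needs_two_per_group(self):
        with pytest.raises(ConfigurationError):
            wilcoxon_p([1.0], [2.0, 3.0])


class TestStoreyQ:
    def test_hand_example(self):
        q = storey_q([0.125, 0.375, 0.625, 0.875], lam=0.5)
        # pi0 = 2/(0.5*4) = 1.0; step-down minimum of m*p/i
        assert q == pytest.approx([0.5, 0.75, 5 / 6, 0.875])

    def test_equals_bh_when_pi0_is_one(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=100)
        q = storey_q(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.max(np.abs(q - bh)) < 1e-12

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_sorted_order_and_bounded(self, p):
        q = storey_q(p)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_empty(self):
        assert storey_q([]).size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ConfigurationError):
            storey_q([0.5, 1.5])


class TestCallDifferential:
    RUNS_A6 = [f"a{i}" for i in range(6)]
    RUNS_B6 = [f"b{i}" for i in range(6)]

    def _matrix_with_signal(self, diff_scale):
        rng = np.random.default_rng(2)
        rows = [rng.normal(20, 1, 12) for _ in range(20)]
        # feature 0: clean separation with controllable median gap
        rows[0] = np.array([20.0] * 6 + [20.0 - diff_scale] * 6)
        return matrix(np.vstack(rows), self.RUNS_A6 + self.RUNS_B6)

    def test_both_criteria_met_is_significant(self):
        res = call_differential(
            self._matrix_with_signal(8.0), self.RUNS_A6, self.RUNS_B6
        ).set_index("feature_id")
        assert bool(res.loc["f0", "significant"])
        assert res.loc["f0", "direction"] == "higher-in-A"

    def test_small_median_gap_not_significant_despite_q(self):
        res = call_differential(
            self._matrix_with_signal(3.0), self.RUNS_A6, self.RUNS_B6
        ).set_index("feature_id")
        assert res.loc["f0", "q"] < 0.05
        assert not bool(res.loc["f0", "significant"])

    def test_prefiltered_feature_absent(self):
        m = self._matrix_with_signal(8.0)
        m.values.iloc[1] = 0.0  # never above 5 counts
        res = call_differential(m, self.RUNS_A6, self.RUNS_B6)
        assert "f1" not in set(res["feature_id"])

    def test_low_power_flag(self):
        m = matrix([[20, 20, 20, 20, 9, 9, 9, 9]], RUNS_A + RUNS_B)
        res = call_differential(m, RUNS_A, RUNS_B)
        assert res.attrs["low_power"]
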