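"""Exact rank tests, permutation tests, correlation networks, moment screens."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from rhizoface.stats import (
    array_permutation_test,
    correlation_network,
    pairwise_slope,
    skew_kurtosis,
    wilcoxon_rank_sum,
)


class TestWilcoxonRankSum:
    def test_separated_triples_exact(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.statistic == 6.0  # minimal rank sum
        assert res.p_value == pytest.approx(0.10, abs=1e-12)  # 2/20 arrangements

    def test_identical_samples_p_one(self):
        res = wilcoxon_rank_sum([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0

    def test_one_sided_smaller(self):
        two = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]).p_value
        one = wilcoxon_rank_sum([4, 5, 6], [1, 2, 3], two_sided=False).p_value
        assert one == pytest.approx(two / 2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_matches_scipy_exact_on_tie_free_draws(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            nx, ny = rng.integers(2, 7, size=2)
            pooled = rng.permutation(np.arange(1.0, nx + ny + 1))
            x, y = pooled[:nx], pooled[nx:]
            ours = wilcoxon_rank_sum(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.method == "exact"
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_close_to_normal_approximation(self):
        # the approximation should track enumeration within 0.02 at n = 8 vs 8
        rng = np.random.default_rng(5)
        worst = 0.0
        for _ in range(200):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            exact = wilcoxon_rank_sum(x, y).p_value
            worst = max(worst, abs(exact - _normal_approx_p(x, y)))
        assert worst < 0.02

    def test_tie_aware_enumeration_uses_midranks(self):
        # with ties the exact path must still produce a valid symmetric p
        res = wilcoxon_rank_sum([1, 1, 2], [2, 3, 3])
        swapped = wilcoxon_rank_sum([2, 3, 3], [1, 1, 2])
        assert 0 < res.p_value <= 1
        assert res.p_value == pytest.approx(swapped.p_value)


def _normal_approx_p(x, y):
    """Continuity- and tie-corrected normal approximation (reference copy)."""
    nx, ny = len(x), len(y)
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = ranks[:nx].sum()
    mean_w = nx * (n + 1) / 2
    _, t = np.unique(pooled, return_counts=True)
    var_w = nx * ny / 12 * ((n + 1) - np.sum(t**3 - t) / (n * (n - 1)))
    d = w - mean_w
    z = (d - 0.5 * np.sign(d)) / np.sqrt(var_w)
    return 2 * sps.norm.sf(abs(z))


class TestArrayPermutation:
    def test_maximal_separation_hits_floor(self):
        res = array_permutation_test([10.0, 11.0, 12.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 labelings
        assert "0.1" in res.note

    def test_identical_means_p_one(self):
        assert array_permutation_test([5.0, 5.0], [5.0, 5.0]).p_value == 1.0

    def test_label_swap_symmetry(self):
        e, a = [3.1, 4.0, 2.2], [1.0, 1.4, 0.9]
        assert array_permutation_test(e, a).p_value == array_permutation_test(a, e).p_value

    def test_rejects_single_array(self):
        with pytest.raises(ValueError):
            array_permutation_test([1.0], [2.0, 3.0])


def _table_with_correlation(r, n=6, seed=0):
    """Two columns whose sample Pearson correlation is exactly r."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= x * (x @ z) / (x @ x)  # orthogonalize
    z /= z.std()
    y = r * x + np.sqrt(1 - r**2) * z
    return pd.DataFrame({"u": x, "w": y})


class TestCorrelationNetwork:
    def test_perfect_linear_pair_kept(self):
        x = np.arange(5.0)
        net = correlation_network(pd.DataFrame({"a": x, "b": 2 * x}), threshold=0.5)
        assert len(net.edges) == 1
        assert net.edges.iloc[0]["r"] == pytest.approx(1.0)

    def test_just_below_threshold_dropped(self):
        net = correlation_network(_table_with_correlation(0.49), threshold=0.5)
        assert len(net.edges) == 0

    def test_at_threshold_kept_with_absolute_value(self):
        net = correlation_network(_table_with_correlation(-0.6), threshold=0.5)
        assert len(net.edges) == 1
        assert net.edges.iloc[0]["r"] == pytest.approx(-0.6)

    def test_threshold_monotone(self):
        rng = np.random.default_rng(3)
        tab = pd.DataFrame(rng.normal(size=(8, 5)), columns=list("abcde"))
        lo = correlation_network(tab, threshold=0.3)
        hi = correlation_network(tab, threshold=0.6)
        lo_pairs = set(map(tuple, lo.edges[["var_a", "var_b"]].to_numpy()))
        hi_pairs = set(map(tuple, hi.edges[["var_a", "var_b"]].to_numpy()))
        assert hi_pairs <= lo_pairs

    def test_constant_variable_excluded(self):
        tab = pd.DataFrame({"a": [1.0, 2, 3, 4], "c": [5.0, 5, 5, 5]})
        net = correlation_network(tab)
        assert net.excluded == ["c"]
        assert "c" not in net.nodes

    def test_dot_export_lists_edges(self, tmp_path):
        x = np.arange(5.0)
        net = correlation_network(pd.DataFrame({"a": x, "b": -2 * x}), threshold=0.5)
        net.to_dot(tmp_path / "net.dot")
        text = (tmp_path / "net.dot").read_text()
        assert '"a" -- "b"' in text and "dashed" in text  # negative edge styled

    def test_slope_sign_recovered(self):
        tab = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [8.0, 6, 4.2, 1.9]})
        fit = pairwise_slope(tab, "x", "y")
        assert fit["slope"] < 0 and fit["r"] < -0.99


class TestSkewKurtosis:
    def test_symmetric_triple_zero_skew(self):
        skew, _ = skew_kurtosis([-1.0, 0.0, 1.0])
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_normal_sample_near_zero_excess_kurtosis(self):
        x = np.random.default_rng(0).normal(size=10_000)
        skew, kurt = skew_kurtosis(x)
        assert abs(skew) < 0.1 and abs(kurt) < 0.15

    def test_exponential_sample_skewness_two(self):
        x = np.random.default_rng(1).exponential(size=200_000)
        skew, _ = skew_kurtosis(x)
        assert skew == pytest.approx(2.0, abs=0.1)

    def test_degenerate_sample_undefined(self):
        skew, kurt = skew_kurtosis([3.0, 3.0, 3.0])
        assert np.isnan(skew) and np.isnan(kurt)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.lists(st.floats(-50, 50), min_size=2, max_size=6),
       st.lists(st.floats(-50, 50), min_size=2, max_size=6))
def test_wilcoxon_p_valid_and_symmetric(x, y):
    res = wilcoxon_rank_sum(x, y)
    assert 0.0 <= res.p_value <= 1.0
    assert res.p_value == pytest.approx(wilcoxon_rank_sum(y, x).p_value, abs=1e-9)
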