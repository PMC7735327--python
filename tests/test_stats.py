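"""Statistical tests against hand arithmetic, permutation enumeration and
independent reference implementations."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from faceatlas import (
    friedman_test,
    icc,
    kruskal_wallis,
    pairwise_posthoc,
    slope_ttest,
    standardized_effect,
)


def oracle_friedman_stat(table: np.ndarray) -> float:
    """Independent statistic: tie-corrected Friedman chi-square (Conover form)."""
    n, k = table.shape
    ranks = np.array([sps.rankdata(row) for row in table])
    a = np.sum(ranks**2)
    cf = n * k * (k + 1) ** 2 / 4.0
    if a == cf:
        return 0.0
    col = ranks.sum(axis=0)
    return float((k - 1) * np.sum((col - n * (k + 1) / 2.0) ** 2) / (a - cf))


def exact_friedman_p(table: np.ndarray) -> float:
    """Oracle: enumerate all within-case permutations of the observed values."""
    n, k = table.shape
    observed = oracle_friedman_stat(table)
    perms = list(itertools.permutations(range(k)))
    count = total = 0
    for combo in itertools.product(perms, repeat=n):
        permuted = np.array([table[i, list(combo[i])] for i in range(n)])
        count += oracle_friedman_stat(permuted) >= observed - 1e-12
        total += 1
    return count / total


def oracle_kruskal_stat(groups) -> float:
    """Independent statistic: textbook tie-corrected H."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return float(h / tie)


def exact_kruskal_p(groups) -> float:
    """Oracle: enumerate all assignments of the pooled values to the groups."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    observed = oracle_kruskal_stat(groups)
    idx = np.arange(len(pooled))
    count = total = 0
    for perm in itertools.permutations(idx):
        start, gs = 0, []
        for s in sizes:
            gs.append(pooled[list(perm[start : start + s])])
            start += s
        stat = oracle_kruskal_stat(gs)
        count += stat >= observed - 1e-12
        total += 1
    return count / total


class TestFriedman:
    def test_identical_conditions(self):
        table = np.tile([[3.0, 3.0, 3.0]], (4, 1))
        res = friedman_test(table)
        assert res.statistic == 0.0 and res.p_value == 1.0 and not res.significant

    def test_hand_ranked_statistic(self):
        # every case ranks the three conditions (1, 2, 3)
        table = np.array([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0], [0.1, 0.2, 0.3]])
        assert friedman_test(table).statistic == pytest.approx(6.0)

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(0)
        table = rng.standard_normal((8, 4))
        stat, p = sps.friedmanchisquare(*table.T)
        res = friedman_test(table)
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)

    def test_chi2_p_close_to_exact_permutation(self):
        rng = np.random.default_rng(2)
        for _ in range(3):
            table = rng.standard_normal((4, 3))
            assert abs(friedman_test(table).p_value - exact_friedman_p(table)) < 0.1

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            friedman_test(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            friedman_test(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestKruskalWallis:
    def test_identical_values(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_two_group_hand_value(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(3.857, abs=1e-3)

    def test_monotone_transform_invariance(self):
        groups = [[1.0, 5.0, 2.0], [9.0, 3.0], [4.0, 8.0, 7.0]]
        trans = [list(np.exp(g)) for g in [np.array(g) for g in groups]]
        assert kruskal_wallis(groups).statistic == pytest.approx(
            kruskal_wallis(trans).statistic
        )

    def test_p_close_to_exact_permutation(self):
        rng = np.random.default_rng(3)
        groups = [list(rng.standard_normal(3)), list(rng.standard_normal(3))]
        assert abs(kruskal_wallis(groups).p_value - exact_kruskal_p(groups)) < 0.1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestPosthoc:
    def test_bonferroni_levels(self):
        assert 0.05 / 3 == pytest.approx(0.0167, abs=5e-4)
        assert 0.05 / 6 == pytest.approx(0.0083, abs=5e-4)

    def test_identical_paired_samples_not_significant(self):
        data = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        (res,) = pairwise_posthoc(data, [("a", "b")], 0.05 / 3)
        assert res.p_value == 1.0 and not res.significant

    def test_paired_difference_detected(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(20)
        data = {"a": x, "b": x + 1.0}
        (res,) = pairwise_posthoc(data, [("a", "b")], 0.05 / 3)
        assert res.significant

    def test_unpaired_mode_and_unknown_condition(self):
        data = {"a": [1.0, 2.0], "b": [5.0, 6.0, 7.0]}
        (res,) = pairwise_posthoc(data, [("a", "b")], 0.05, paired=False)
        assert 0 <= res.p_value <= 1
        with pytest.raises(KeyError):
            pairwise_posthoc(data, [("a", "zzz")], 0.05)


class TestICC:
    def test_identical_columns_is_one(self):
        table = np.tile(np.array([[1.0], [5.0], [9.0], [2.0]]), (1, 3))
        assert icc(table).statistic == pytest.approx(1.0)

    def test_small_noise_high_agreement(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            cases = rng.normal(0, 10, size=50)
            table = cases[:, None] + rng.normal(0, 0.5, size=(50, 3))
            assert icc(table).statistic > 0.95

    def test_no_case_effect_near_zero(self):
        rng = np.random.default_rng(11)
        table = rng.standard_normal((50, 3))
        assert abs(icc(table).statistic) < 0.2

    def test_variance_component_recovery(self):
        # enough raters that the realised rater variance cannot dominate
        rng = np.random.default_rng(12)
        s_case, s_rater, s_err = 4.0, 0.5, 1.0
        n, k = 200, 8
        table = (
            rng.normal(0, s_case, n)[:, None]
            + rng.normal(0, s_rater, k)[None, :]
            + rng.normal(0, s_err, (n, k))
        )
        expected = s_case**2 / (s_case**2 + s_rater**2 + s_err**2)
        assert icc(table).statistic == pytest.approx(expected, abs=0.05)

    def test_matches_pingouin_absolute_agreement(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(13)
        table = rng.normal(0, 5, size=(12, 1)) + rng.normal(0, 1, size=(12, 3))
        long = pd.DataFrame(
            {
                "case": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "y": table.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="case", raters="rater", ratings="y")
        icc2 = float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0])
        assert icc(table).statistic == pytest.approx(icc2, abs=1e-9)

    def test_zero_between_case_variance_rejected(self):
        with pytest.raises(ValueError):
            icc(np.zeros((4, 3)))


class TestSlopeTTest:
    def test_constant_response(self):
        res = slope_ttest([1, 2, 3, 4], [5.0, 5.0, 5.0, 5.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_exact_linear_fit(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = slope_ttest(x, 2 * x)
        assert res.statistic == pytest.approx(2.0)
        assert res.p_value < 1e-12

    def test_matches_closed_form_and_scipy(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(25)
        y = 0.7 * x + rng.standard_normal(25)
        res = slope_ttest(x, y)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        ref = sps.linregress(x, y)
        assert res.statistic == pytest.approx(slope)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            slope_ttest([2, 2, 2], [1.0, 2.0, 3.0])


def test_standardized_effect_direction():
    inter = [1.0, 1.2, 0.9, 1.1, 1.0, 0.8]
    intra = [0.5, 0.4, 0.6]
    assert standardized_effect(inter, intra) > 0
    assert standardized_effect([1.0, 1.0], [1.0, 1.0]) == 0.0
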