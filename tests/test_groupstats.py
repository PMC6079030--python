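"""Group-level statistics: closed-form examples, oracles, degenerate inputs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vsprl.groupstats import (
    ancova_interaction,
    bootstrap_regression,
    one_sample_t,
    regress_on_age,
    shapiro_wilk,
    spearman_correlation,
    wilcoxon_signed_rank,
)


def test_regress_on_age_perfect_fit():
    ages = np.arange(10, 26, dtype=float)
    values = 2.0 - 0.1 * ages
    res = regress_on_age(values, ages)
    assert res.estimate == pytest.approx(-0.1, abs=1e-12)
    assert res.extras["r_squared"] == pytest.approx(1.0, abs=1e-12)
    assert res.p_value < 1e-12


def test_regress_on_age_matches_f_of_t_squared():
    rng = np.random.default_rng(0)
    ages = rng.uniform(10, 25, 40)
    values = 0.3 * ages + rng.normal(0, 1, 40)
    res = regress_on_age(values, ages)
    lr = stats.linregress(ages, values)
    assert res.statistic == pytest.approx((lr.slope / lr.stderr) ** 2, rel=1e-9)
    assert res.df == (1, 38)


def test_regress_on_age_degenerate_errors():
    with pytest.raises(ValueError):
        regress_on_age([1.0, 1.0, 1.0], [10.0, 11.0, 12.0])
    with pytest.raises(ValueError):
        regress_on_age([1.0, 2.0, 3.0], [10.0, 10.0, 10.0])


def test_one_sample_t_hand_example():
    """values {1,2,3} vs 0: t = 2 / (1/sqrt(3)) = 2*sqrt(3)."""
    res = one_sample_t([1.0, 2.0, 3.0], 0.0)
    assert res.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-10)
    assert res.df == 2


def test_one_sample_t_symmetric_values():
    res = one_sample_t([-2.0, -1.0, 1.0, 2.0], 0.0)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)


def test_one_sample_t_zero_variance_errors():
    with pytest.raises(ValueError):
        one_sample_t([1.0, 1.0, 1.0])


def _exact_wilcoxon_p(diffs):
    """Exhaustive enumeration over all 2^n sign patterns (oracle)."""
    ranks = stats.rankdata(np.abs(diffs))
    n = len(diffs)
    w_obs = np.sum(ranks[np.array(diffs) > 0])
    w_all = [
        np.sum(ranks[np.array(signs, dtype=bool)])
        for signs in itertools.product([0, 1], repeat=n)
    ]
    w_all = np.array(w_all)
    mean_w = n * (n + 1) / 4
    return np.mean(np.abs(w_all - mean_w) >= np.abs(w_obs - mean_w) - 1e-12)


def test_wilcoxon_exact_small_sample_matches_enumeration():
    vals = np.array([0.8, -0.3, 1.2, 0.5, -0.9, 0.4, 1.5, 0.7])
    res = wilcoxon_signed_rank(vals, 0.0)
    assert res.extras["method"] == "exact"
    assert res.p_value == pytest.approx(_exact_wilcoxon_p(vals), abs=1e-12)


def test_wilcoxon_large_sample_uses_normal_approximation():
    rng = np.random.default_rng(1)
    vals = rng.normal(0.4, 1.0, 53)
    res = wilcoxon_signed_rank(vals, 0.0)
    assert res.extras["method"] == "approx"
    ref = stats.wilcoxon(vals, alternative="two-sided", method="approx", correction=True)
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)
    assert "iqr" in res.extras and "median" in res.extras


def test_wilcoxon_drops_ties_and_errors_when_all_tie():
    with pytest.raises(ValueError):
        wilcoxon_signed_rank([0.5] * 10, 0.5)
    with pytest.raises(ValueError):
        wilcoxon_signed_rank([0.5, 0.5, 0.5, 0.6], 0.5)  # too few non-ties


def test_spearman_monotone_and_tied_cases():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    assert spearman_correlation(x, np.exp(x)).estimate == pytest.approx(1.0)
    assert spearman_correlation(x, -x).estimate == pytest.approx(-1.0)

    # with ties: equals Pearson on mid-ranks
    xt = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0])
    yt = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 5.0])
    expected = stats.pearsonr(stats.rankdata(xt), stats.rankdata(yt)).statistic
    assert spearman_correlation(xt, yt).estimate == pytest.approx(expected, abs=1e-12)


def test_spearman_constant_vector_errors():
    with pytest.raises(ValueError):
        spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_bootstrap_regression_zero_noise_degenerate_ci():
    ages = np.arange(10.0, 30.0)
    values = 1.0 + 0.5 * ages
    res = bootstrap_regression(values, ages, n_boot=500, seed=0)
    assert res.estimate == pytest.approx(0.5, abs=1e-10)
    assert res.ci[0] == pytest.approx(0.5, abs=1e-10)
    assert res.ci[1] == pytest.approx(0.5, abs=1e-10)
    assert res.significant


def test_bootstrap_regression_constant_values():
    ages = np.arange(10.0, 20.0)
    res = bootstrap_regression(np.ones(10), ages, n_boot=200, seed=1)
    assert res.estimate == 0.0
    assert res.ci == (0.0, 0.0)


def test_bootstrap_regression_deterministic_per_seed():
    rng = np.random.default_rng(2)
    ages = rng.uniform(10, 25, 30)
    vals = -0.03 * ages + rng.normal(0, 0.1, 30)
    r1 = bootstrap_regression(vals, ages, n_boot=1000, seed=7)
    r2 = bootstrap_regression(vals, ages, n_boot=1000, seed=7)
    assert r1.ci == r2.ci


def test_bootstrap_regression_covers_generative_slope():
    rng = np.random.default_rng(3)
    cover = 0
    for i in range(200):
        ages = rng.uniform(10, 25, 56)
        vals = -0.029 * ages + rng.normal(0, 0.15, 56)
        res = bootstrap_regression(vals, ages, n_boot=600, seed=1000 + i)
        cover += res.ci[0] <= -0.029 <= res.ci[1]
    assert 0.90 <= cover / 200 <= 0.99


def _ancova_table(ages, est_a, est_b):
    n = len(ages)
    return pd.DataFrame(
        {
            "participant": list(range(n)) * 2,
            "feedback_type": ["cFB"] * n + ["accFB"] * n,
            "estimate": np.concatenate([est_a, est_b]),
            "age": np.concatenate([ages, ages]),
        }
    )


def test_ancova_interaction_equals_slope_difference_in_saturated_case():
    ages = np.array([10.0, 20.0])
    est_a = 1.0 + 0.5 * ages  # slope 0.5
    est_b = 2.0 - 0.3 * ages  # slope -0.3
    res = ancova_interaction(_ancova_table(ages, est_a, est_b))
    # coding puts cFB as the second level alphabetically -> interaction is
    # slope(cFB) - slope(accFB)
    assert res.estimate == pytest.approx(0.5 - (-0.3), abs=1e-10)


def test_ancova_detects_opposite_slopes():
    rng = np.random.default_rng(4)
    ages = rng.uniform(10, 25, 30)
    est_a = 0.2 * ages + rng.normal(0, 0.3, 30)
    est_b = -0.2 * ages + rng.normal(0, 0.3, 30)
    res = ancova_interaction(_ancova_table(ages, est_a, est_b))
    assert res.p_value < 1e-6
    assert res.df == (1, 56)


def test_ancova_unbalanced_rows_error():
    tab = _ancova_table(np.array([10.0, 20.0, 15.0]), np.zeros(3), np.zeros(3))
    tab = tab.drop(index=4)  # one participant loses its accFB row
    with pytest.raises(ValueError, match="missing a feedback-type"):
        ancova_interaction(tab)


def test_shapiro_routes_and_bounds():
    rng = np.random.default_rng(5)
    skewed = shapiro_wilk(rng.exponential(1.0, 58))
    assert skewed.p_value < 0.05 and not skewed.extras["normal_at_05"]
    with pytest.raises(ValueError):
        shapiro_wilk([1.0, 2.0])
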