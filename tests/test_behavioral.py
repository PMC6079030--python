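"""Feedback-influence logistic model: MLE correctness, exclusions, symmetry."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_trials
from vsprl._logit import fit_logit, log_likelihood
from vsprl.behavioral import FeedbackInfluenceModel, check_response_variability, fit_cohort


def brute_force_logit(X, y, box=6.0, n_grid=13):
    """Likelihood maximization over a dense coefficient grid (oracle)."""
    grids = [np.linspace(-box, box, n_grid)] * X.shape[1]
    best, best_ll = None, -np.inf
    for beta in itertools.product(*grids):
        ll = log_likelihood(X, y, np.array(beta))
        if ll > best_ll:
            best, best_ll = np.array(beta), ll
    return best, best_ll


@pytest.mark.parametrize(
    "decisions,expected_pass",
    [
        ([1] * 75, False),  # uniform
        ([1] * 74 + [0], False),  # near-uniform
        ([1] * 73 + [0, 0], False),  # minority 2 < 3
        ([1] * 40 + [0] * 35, True),
        ([1] * 3 + [0] * 72, True),  # minority exactly at threshold
    ],
)
def test_response_variability_rule(decisions, expected_pass):
    assert check_response_variability(decisions).passed is expected_pass


def test_response_variability_empty_errors():
    with pytest.raises(ValueError):
        check_response_variability([])


def test_logit_matches_statsmodels():
    """Newton core agrees with the statsmodels MLE on well-behaved data."""
    import statsmodels.api as sm

    rng = np.random.default_rng(0)
    X = np.column_stack([rng.normal(size=(200, 2)), np.ones(200)])
    beta_true = np.array([1.0, -0.5, 0.2])
    y = (rng.random(200) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
    ours = fit_logit(X, y, compute_bse=True)
    ref = sm.Logit(y, X).fit(disp=0)
    np.testing.assert_allclose(ours.params, ref.params, atol=1e-6)
    np.testing.assert_allclose(ours.llf, ref.llf, atol=1e-8)
    np.testing.assert_allclose(ours.bse, ref.bse, rtol=1e-4)


@pytest.mark.parametrize("seed", range(4))
def test_logit_matches_brute_force_grid_on_small_instances(seed):
    """On <=12-trial instances the Newton fit attains at least the likelihood
    of a dense grid search over a coefficient box (within 1e-6)."""
    rng = np.random.default_rng(seed)
    n = 12
    X = np.column_stack([rng.choice([-1.0, 0.0, 1.0], n), np.ones(n)])
    y = rng.integers(0, 2, n).astype(float)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        y[:2] = [0, 1]
    ours = fit_logit(X, y)
    _, grid_ll = brute_force_logit(X, y, box=6.0, n_grid=25)
    assert ours.llf >= grid_ll - 1e-6


def test_fitted_likelihood_dominates_truth(self_protective_trials):
    """MLE property: likelihood at the fit >= likelihood at the generating betas."""
    model = FeedbackInfluenceModel(self_protective_trials)
    res = model.fit()
    ll_true = log_likelihood(
        model.exog, model.endog, np.array([3.0, 0.0, 1.0, 0.0])
    )
    assert res.llf >= ll_true


def test_decision_flip_negates_coefficients(self_protective_trials):
    res = FeedbackInfluenceModel(self_protective_trials).fit()
    flipped = self_protective_trials.copy()
    flipped["decision"] = 1 - flipped["decision"]
    res_f = FeedbackInfluenceModel(flipped).fit()
    np.testing.assert_allclose(res.params, -res_f.params, atol=1e-6)


def test_intercept_only_truth_recovers_logit_of_proportion():
    rng = np.random.default_rng(5)
    decisions = (rng.random(75) < 0.5).astype(int)
    trials = make_trials(["neutral"] * 75, decisions)
    res = FeedbackInfluenceModel(trials).fit()
    p = decisions.mean()
    assert res.beta_0 == pytest.approx(np.log(p / (1 - p)), abs=1e-6)


def test_all_neutral_design_reports_rank_deficiency():
    rng = np.random.default_rng(6)
    trials = make_trials(["neutral"] * 75, rng.integers(0, 2, 75))
    res = FeedbackInfluenceModel(trials).fit()
    assert res.rank_deficient


def test_separation_triggers_penalized_fallback(default_design):
    """An agent that deterministically mirrors feedback separates the data."""
    decisions = [0 if v == "negative" else 1 for v in default_design.valences]
    trials = make_trials(default_design.valences, decisions, default_design.oc_levels)
    res = FeedbackInfluenceModel(trials).fit()
    assert res.separated and res.penalized
    assert np.all(np.isfinite(res.params))
    assert res.beta_cfb > 0  # direction preserved under the penalty


def test_parameter_recovery_pooled(default_design):
    """Pooled estimates across many simulated agents recover generating betas."""
    from vsprl.predictors import build_design_matrix

    rng = np.random.default_rng(7)
    base = build_design_matrix(
        pd.DataFrame(
            {
                "trial": [t.trial for t in default_design.trials],
                "valence": default_design.valences,
                "oc_level": default_design.oc_levels,
                "decision": 0,
            }
        )
    )
    X = np.column_stack(
        [base["cfb"], base["accfb"], base["oc"], np.ones(len(base))]
    )
    beta_true = np.array([1.5, 0.0, 1.0, 0.0])
    p = 1 / (1 + np.exp(-X @ beta_true))
    estimates = []
    for _ in range(120):
        df = base.copy()
        df["decision"] = (rng.random(len(base)) < p).astype(int)
        res = FeedbackInfluenceModel(df).fit()
        if not res.excluded:
            estimates.append(res.params.to_numpy())
    mean_est = np.mean(estimates, axis=0)
    se = np.std(estimates, axis=0, ddof=1) / np.sqrt(len(estimates))
    # within ~4 Monte-Carlo standard errors of truth
    assert np.all(np.abs(mean_est - beta_true) < 4 * se + 0.05)


def test_fit_cohort_exclusions(small_cohort):
    pred, _ = small_cohort
    uniform = make_trials(["neutral"] * 75, [1] * 75)
    uniform["participant"] = "uniform01"
    from vsprl.predictors import cohort_design_matrix

    table = pd.concat([pred, cohort_design_matrix(uniform)], ignore_index=True)
    summary = fit_cohort(table)
    assert summary.n_excluded == 1
    assert summary.n_fitted == 12
    df = summary.to_frame()
    assert df.loc[df["participant"] == "uniform01", "excluded"].item()
    assert "uniform" in df.loc[df["participant"] == "uniform01", "reason"].item()


def test_fit_cohort_empty_table_errors():
    with pytest.raises(ValueError):
        fit_cohort(pd.DataFrame(columns=["participant", "decision"]))
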