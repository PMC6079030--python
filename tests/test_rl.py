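"""Self-protection RL model: value updates, grid MLE, bias analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_trials
from vsprl.rl import (
    SelfProtectionModel,
    closed_form_vsp,
    fit_rl_cohort,
    flag_violator,
    reverse_code_fb,
    update_vsp,
    vsp_bias_analysis,
)
from vsprl.simulate import AgentParams, simulate_agent


@pytest.mark.parametrize(
    "valence,code", [("negative", 1), ("neutral", 0), ("positive", -1)]
)
def test_reverse_coding(valence, code):
    assert reverse_code_fb(valence) == code


def test_reverse_coding_unknown():
    with pytest.raises(ValueError):
        reverse_code_fb("mixed")


def test_update_vsp_basic_limits():
    traj = update_vsp([1.0], 0.5)
    assert traj.vsp[0] == 0.0 and traj.vsp[1] == 0.5 and traj.pe[0] == 1.0

    fb = np.array([1, -1, 0, 1, 1, -1], dtype=float)
    np.testing.assert_allclose(update_vsp(fb, 1.0).vsp[1:], fb)  # full replacement
    np.testing.assert_allclose(update_vsp(fb, 0.0).vsp, 0.0)  # frozen at the prior


def test_update_vsp_alpha_out_of_range():
    with pytest.raises(ValueError):
        update_vsp([1.0], 1.5)


def test_neutral_feedback_decays_vsp_toward_zero():
    traj = update_vsp([1.0, 0.0, 0.0], 0.5)
    np.testing.assert_allclose(traj.vsp, [0.0, 0.5, 0.25, 0.125])


def test_closed_form_matches_recursion_randomized():
    """Exponentially weighted closed form equals the recursion to 1e-12."""
    rng = np.random.default_rng(0)
    for _ in range(1000):
        T = int(rng.integers(1, 40))
        fb = rng.choice([-1.0, 0.0, 1.0], T)
        alpha = float(rng.random())
        t = int(rng.integers(0, T + 1))
        traj = update_vsp(fb, alpha)
        assert abs(closed_form_vsp(fb, alpha, t) - traj.vsp[t]) < 1e-12


def test_closed_form_edges():
    fb = [1.0, -1.0, 1.0]
    assert closed_form_vsp(fb, 0.7, 0) == 0.0
    assert closed_form_vsp(fb, 1.0, 3) == fb[2]  # only the last feedback survives


@given(
    st.lists(st.sampled_from([-1.0, 0.0, 1.0]), min_size=1, max_size=75),
    st.floats(min_value=0.0, max_value=1.0),
)
@settings(max_examples=150, deadline=None, derandomize=True)
def test_vsp_bounded_by_one(fb, alpha):
    """With VSP_0=0 and feedback in {-1,0,1}, |VSP_t| <= 1 for all t."""
    traj = update_vsp(np.array(fb), alpha)
    assert np.max(np.abs(traj.vsp)) <= 1.0 + 1e-12


def test_flat_profile_flags_nonidentifiable():
    """All-neutral feedback makes VSP identically zero at every alpha, so
    the profile likelihood is exactly flat: the tie-break reports alpha=0
    and the fit is flagged non-identifiable."""
    rng = np.random.default_rng(3)
    trials = make_trials(["neutral"] * 75, rng.integers(0, 2, 75))
    res = SelfProtectionModel(trials).fit(grid_step=0.01)
    assert not res.identifiable
    assert res.alpha_hat == 0.0


def test_two_stage_matches_exhaustive_argmax(self_protective_trials):
    """Refined two-stage search lands within one coarse cell of the
    exhaustive coarse-grid argmax and never at a lower likelihood."""
    model = SelfProtectionModel(self_protective_trials)
    fine = model.fit(grid_step=0.0001, method="two_stage")
    coarse = model.fit(grid_step=0.01, method="exhaustive")
    assert abs(fine.alpha_hat - coarse.alpha_hat) <= 0.01 + 1e-9
    assert fine.llf >= coarse.llf - 1e-9


def test_exhaustive_and_two_stage_agree_on_fine_grid(self_protective_trials):
    model = SelfProtectionModel(self_protective_trials)
    a = model.fit(grid_step=0.001, method="exhaustive")
    b = model.fit(grid_step=0.001, method="two_stage")
    assert a.alpha_hat == pytest.approx(b.alpha_hat, abs=1e-9)
    assert a.llf == pytest.approx(b.llf, abs=1e-9)


def test_alpha_hat_on_grid(self_protective_trials):
    res = SelfProtectionModel(self_protective_trials).fit(grid_step=0.0001)
    assert round(res.alpha_hat / 0.0001) == pytest.approx(res.alpha_hat / 0.0001)


def test_profile_likelihood_dominates_true_parameters(self_protective_trials):
    model = SelfProtectionModel(self_protective_trials)
    res = model.fit(grid_step=0.001)
    assert res.llf >= model.loglike(0.4, -3.0, 1.0, 0.0) - 1e-9


@pytest.mark.parametrize("beta_vsp,expected", [(-2.1, False), (0.8, True), (0.0, False)])
def test_violator_sign_rule(beta_vsp, expected):
    assert flag_violator(beta_vsp) is expected


def test_no_violators_in_self_protective_cohort(small_cohort):
    pred, participants = small_cohort
    fits = fit_rl_cohort(pred, grid_step=0.01)
    assert all(not f.violator for f in fits if not f.excluded)
    # sanity: estimated alphas correlate with truth even on a coarse grid
    est = {f.participant: f.alpha_hat for f in fits}
    merged = participants.assign(alpha_hat=participants["participant"].map(est))
    from scipy import stats

    assert stats.spearmanr(merged["true_alpha"], merged["alpha_hat"]).statistic > 0.5


def test_vsp_timing_switch_changes_design(self_protective_trials):
    cur = SelfProtectionModel(self_protective_trials, vsp_timing="current")
    prev = SelfProtectionModel(self_protective_trials, vsp_timing="previous")
    fb = cur.fb
    Vc = cur._decision_vsp(update_vsp(fb, 0.5).vsp[None, :])
    Vp = prev._decision_vsp(update_vsp(fb, 0.5).vsp[None, :])
    np.testing.assert_allclose(Vc[0, :-1], Vp[0, 1:])  # shifted by one trial
    assert Vp[0, 0] == 0.0


def test_excluded_participant_reported_not_fitted():
    trials = make_trials(["neutral"] * 75, [1] * 75)
    res = SelfProtectionModel(trials).fit(grid_step=0.01)
    assert res.excluded and np.isnan(res.alpha_hat)


def test_vsp_bias_derogation_pattern(default_design):
    """Strongly negative beta_vsp pushes high-VSP decision probability below
    chance while low-VSP trials sit near/above chance."""
    rng = np.random.default_rng(12)
    frames = []
    for i in range(12):
        params = AgentParams(
            alpha=0.4, beta_vsp=-4.0, beta_oc=1.0, beta_0=0.0
        )
        df = simulate_agent(params, default_design, seed=int(rng.integers(2**31)))
        df.insert(0, "participant", f"a{i:02d}")
        frames.append(df[["participant", "trial", "valence", "oc_level", "decision"]])
    trials = pd.concat(frames, ignore_index=True)
    from vsprl.predictors import cohort_design_matrix

    pred = cohort_design_matrix(trials)
    fits = fit_rl_cohort(pred, grid_step=0.01)
    bias = vsp_bias_analysis(fits, pred)
    assert bias.median_high < 0.5
    assert bias.median_high < bias.median_low
    assert bias.high_vs_chance.p_value < 0.05


def test_vsp_bias_empty_low_set_marked_unavailable():
    """All-negative feedback keeps VSP positive; the low-VSP cell is empty."""
    import warnings

    from vsprl.design import TaskDesign, Trial
    from vsprl.predictors import AccfbBoundWarning, cohort_design_matrix

    design = TaskDesign(
        trials=[Trial(i + 1, "negative", (i % 5) + 1) for i in range(75)]
    )
    params = AgentParams(alpha=0.3, beta_vsp=-2.0, beta_oc=1.0, beta_0=1.0)
    df = simulate_agent(params, design, seed=8)
    df.insert(0, "participant", "solo")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", AccfbBoundWarning)
        pred = cohort_design_matrix(
            df[["participant", "trial", "valence", "oc_level", "decision"]]
        )
    fits = fit_rl_cohort(pred, grid_step=0.01)
    assert not fits[0].violator
    bias = vsp_bias_analysis(fits, pred)
    assert np.isnan(bias.per_participant["mean_p_low"]).all()
    assert np.isfinite(bias.per_participant["mean_p_high"]).all()
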