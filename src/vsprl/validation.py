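"""Validation experiments: parameter recovery, calibration, coverage.

These routines run the package's own methods under the study conditions the
analyses assume — the fixed 75-trial design, self-protective agents with
age-declining learning rates, n = 56 mediation triads — and measure how well
the estimators behave: recovery of the generative learning rate, sign-level
reproduction of the developmental dissociation, type-I calibration of the
group tests, bootstrap-CI coverage for the indirect effect, and the Grubbs
screen's hit/false-alarm rates.  They are what the acceptance checks and
the reproduction script execute.
"""

from __future__ import annotations

import collections

import numpy as np
import pandas as pd
from scipy import stats

from ._logit import fit_logit, log_likelihood
from .behavioral import fit_cohort
from .design import VALENCE_CODE, DesignSpec, generate_design
from .groupstats import ancova_interaction, bootstrap_regression, regress_on_age, spearman_correlation, wilcoxon_signed_rank
from .mediation import MediationModel, grubbs_screen
from .predictors import cohort_design_matrix
from .rl import SelfProtectionModel, closed_form_vsp, fit_rl_cohort, rl_fits_frame, update_vsp
from .simulate import AgentParams, CohortSpec, MediationCohortSpec, simulate_agent, simulate_cohort, simulate_mediation_cohort


def design_constants(seed: int = 0) -> dict:
    """Counts and bounds of a default generated design."""
    design = generate_design(DesignSpec(seed=seed))
    valences = collections.Counter(design.valences)
    cells = collections.Counter(zip(design.valences, design.oc_levels))
    subtypes = collections.Counter(t.neutral_subtype for t in design.trials)
    partial = np.cumsum([VALENCE_CODE[v] for v in design.valences])
    return {
        "n_trials": len(design),
        "n_negative": valences["negative"],
        "n_neutral": valences["neutral"],
        "n_positive": valences["positive"],
        "per_cell_min": min(cells.values()),
        "per_cell_max": max(cells.values()),
        "n_not_yet_evaluated": subtypes["not_yet_evaluated"],
        "n_no_response": subtypes["no_response"],
        "max_abs_running_sum": int(np.max(np.abs(partial))),
    }


def update_rule_equivalence(n_cases: int = 1000, seed: int = 0) -> float:
    """Max |recursive - closed-form| VSP over randomized (fb, alpha, t)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        T = int(rng.integers(1, 76))
        fb = rng.choice([-1.0, 0.0, 1.0], T)
        alpha = float(rng.random())
        t = int(rng.integers(0, T + 1))
        traj = update_vsp(fb, alpha)
        worst = max(worst, abs(closed_form_vsp(fb, alpha, t) - traj.vsp[t]))
    return worst


def _fit_simulated_agent(params: AgentParams, design, seed: int, grid_step: float):
    df = simulate_agent(params, design, seed=seed)
    return SelfProtectionModel(df).fit(grid_step=grid_step)


def alpha_recovery(
    seed: int = 0,
    n_agents: int = 200,
    alpha: float = 0.3,
    beta_vsp: float = -3.0,
    grid_step: float = 0.0001,
) -> dict:
    """Grid-MLE recovery of a fixed generative learning rate."""
    design = generate_design(DesignSpec(seed=seed))
    rng = np.random.default_rng(seed + 1)
    params = AgentParams(alpha=alpha, beta_vsp=beta_vsp, beta_oc=1.0, beta_0=0.0)
    ahats = []
    for _ in range(n_agents):
        res = _fit_simulated_agent(params, design, int(rng.integers(2**31 - 1)), grid_step)
        if not res.excluded:
            ahats.append(res.alpha_hat)
    ahats = np.array(ahats)
    return {
        "true_alpha": alpha,
        "mean_alpha_hat": float(ahats.mean()),
        "sd_alpha_hat": float(ahats.std(ddof=1)),
        "abs_bias": float(abs(ahats.mean() - alpha)),
        "n_agents": int(ahats.size),
    }


def alpha_recovery_spearman(
    seed: int = 0,
    alphas: np.ndarray | None = None,
    n_per_alpha: int = 8,
    beta_vsp: float = -3.0,
    grid_step: float = 0.0001,
) -> dict:
    """Rank correlation between generative and recovered alphas."""
    if alphas is None:
        alphas = np.linspace(0.05, 0.95, 19)
    design = generate_design(DesignSpec(seed=seed))
    rng = np.random.default_rng(seed + 2)
    true, est = [], []
    for a in alphas:
        params = AgentParams(alpha=float(a), beta_vsp=beta_vsp, beta_oc=1.0, beta_0=0.0)
        for _ in range(n_per_alpha):
            res = _fit_simulated_agent(params, design, int(rng.integers(2**31 - 1)), grid_step)
            # standard pipeline exclusions: violators and non-identifiable
            # fits do not enter group analyses
            if not res.excluded and not res.violator and res.identifiable:
                true.append(float(a))
                est.append(res.alpha_hat)
    true_arr, est_arr = np.array(true), np.array(est)
    rho = stats.spearmanr(true_arr, est_arr).statistic
    # monotonicity of the recovery curve itself: aggregate estimates per
    # generative alpha before ranking
    means = pd.DataFrame({"true": true_arr, "est": est_arr}).groupby("true")["est"].mean()
    rho_curve = stats.spearmanr(means.index.to_numpy(), means.to_numpy()).statistic
    return {
        "spearman_true_vs_estimated": float(rho),
        "spearman_recovery_curve": float(rho_curve),
        "n_fits": len(est),
    }


def developmental_dissociation(seed: int = 0, n_agents: int = 60, grid_step: float = 0.001) -> dict:
    """End-to-end cohort run; age slopes and learning-rate correspondences.

    The expected qualitative pattern for self-protective agents with
    age-declining learning rates: current-feedback influence falls with age,
    accumulated-feedback influence rises, estimated alpha falls; estimated
    alpha correlates positively with the current-feedback influence and
    negatively with the accumulated-feedback influence.
    """
    design = generate_design(DesignSpec(seed=seed))
    trials, participants = simulate_cohort(CohortSpec(n_agents=n_agents, seed=seed + 3), design)
    pred = cohort_design_matrix(trials)
    glm = fit_cohort(pred).to_frame()
    rl = rl_fits_frame(fit_rl_cohort(pred, grid_step=grid_step))
    merged = (
        glm[~glm["excluded"]]
        .merge(participants, on="participant")
        .merge(rl[~rl["excluded"] & ~rl["violator"]], on="participant")
    )
    return {
        "n": int(len(merged)),
        "slope_beta_cfb_on_age": regress_on_age(merged["beta_cfb"], merged["age"]).estimate,
        "slope_beta_accfb_on_age": regress_on_age(merged["beta_accfb"], merged["age"]).estimate,
        "slope_alpha_on_age": regress_on_age(merged["alpha_hat"], merged["age"]).estimate,
        "spearman_alpha_beta_cfb": spearman_correlation(
            merged["alpha_hat"], merged["beta_cfb"]
        ).estimate,
        "spearman_alpha_beta_accfb": spearman_correlation(
            merged["alpha_hat"], merged["beta_accfb"]
        ).estimate,
    }


def _brute_force_ll(X: np.ndarray, y: np.ndarray, box: float = 10.0) -> float:
    """Iteratively refined dense-grid likelihood maximization (oracle)."""
    k = X.shape[1]
    center = np.zeros(k)
    half = box
    best_ll = -np.inf
    for _ in range(9):
        axes = [np.linspace(c - half, c + half, 11) for c in center]
        grids = np.meshgrid(*axes, indexing="ij")
        B = np.stack([g.ravel() for g in grids], axis=1)
        eta = X @ B.T
        ll = y @ eta - np.sum(np.logaddexp(0.0, eta), axis=0)
        i = int(np.argmax(ll))
        best_ll = float(ll[i])
        center = B[i]
        half = half / 4.0
    return best_ll


def logit_oracle_gap(seed: int = 0, n_instances: int = 25, n_trials: int = 12) -> float:
    """Worst |Newton - refined-grid| log-likelihood gap on small instances.

    Instances with separation (unbounded MLE) are regenerated, since neither
    route has a finite optimum there.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_instances:
        X = np.column_stack(
            [
                rng.choice([-1.0, 0.0, 1.0], n_trials),
                rng.uniform(-1, 1, n_trials),
                np.ones(n_trials),
            ]
        )
        y = rng.integers(0, 2, n_trials).astype(float)
        if min((y == 0).sum(), (y == 1).sum()) < 3:
            continue
        res = fit_logit(X, y, firth_fallback=False)
        if res.separated or np.max(np.abs(res.params)) > 8:
            continue
        grid_ll = _brute_force_ll(X, y)
        worst = max(worst, abs(res.llf - grid_ll))
        done += 1
    return worst


def type1_calibration(seed: int = 0, reps: int = 5000, alpha_level: float = 0.05) -> dict:
    """Type-I error of the group tests under their null generators."""
    rng = np.random.default_rng(seed)

    rej_w = rej_s = rej_a = rej_b = 0
    n = 56
    for i in range(reps):
        v = rng.normal(0.0, 1.0, 30)
        rej_w += wilcoxon_signed_rank(v, 0.0).p_value < alpha_level

        x = rng.normal(size=30)
        y = rng.normal(size=30)
        rej_s += spearman_correlation(x, y).p_value < alpha_level

        ages = rng.uniform(10, 25, 29)
        tab = pd.DataFrame(
            {
                "participant": list(range(29)) * 2,
                "feedback_type": ["cFB"] * 29 + ["accFB"] * 29,
                "estimate": rng.normal(0, 1, 58),
                "age": np.concatenate([ages, ages]),
            }
        )
        rej_a += ancova_interaction(tab).p_value < alpha_level

        ages_b = rng.uniform(10, 25, n)
        vals_b = rng.normal(0.0, 1.0, n)
        rej_b += bootstrap_regression(
            vals_b, ages_b, n_boot=999, seed=int(rng.integers(2**31 - 1))
        ).significant
    return {
        "wilcoxon": rej_w / reps,
        "spearman": rej_s / reps,
        "ancova_interaction": rej_a / reps,
        "bootstrap_regression": rej_b / reps,
        "reps": reps,
    }


def mediation_calibration(
    seed: int = 0, reps: int = 500, n: int = 56, n_boot: int = 2000
) -> dict:
    """CI coverage of the true indirect effect and null false-positive rate."""
    rng = np.random.default_rng(seed)
    cover = 0
    spec0 = MediationCohortSpec(n=n, a_path=0.5, b_path=0.4)
    for _ in range(reps):
        df = simulate_mediation_cohort(
            MediationCohortSpec(n=n, a_path=0.5, b_path=0.4, seed=int(rng.integers(2**31 - 1)))
        )
        res = MediationModel(df["age"], df["mediator"], df["outcome"]).fit(
            n_boot=n_boot, seed=int(rng.integers(2**31 - 1))
        )
        cover += res.ci[0] <= spec0.indirect <= res.ci[1]
    false_pos = 0
    for _ in range(reps):
        df = simulate_mediation_cohort(
            MediationCohortSpec(n=n, a_path=0.5, b_path=0.0, seed=int(rng.integers(2**31 - 1)))
        )
        res = MediationModel(df["age"], df["mediator"], df["outcome"]).fit(
            n_boot=n_boot, seed=int(rng.integers(2**31 - 1))
        )
        false_pos += res.significant
    return {
        "coverage": cover / reps,
        "null_false_positive_rate": false_pos / reps,
        "reps": reps,
        "n": n,
    }


def grubbs_rates(seed: int = 0, reps: int = 2000, n: int = 56, magnitude_sd: float = 6.0) -> dict:
    """Detection rate for an injected outlier; removal rate on clean data."""
    rng = np.random.default_rng(seed)
    detected = 0
    for _ in range(reps):
        v = rng.normal(0.0, 1.0, n)
        i = int(rng.integers(n))
        v[i] += float(rng.choice([-1.0, 1.0])) * magnitude_sd
        _, removed = grubbs_screen(v)
        detected += removed == [i]
    clean_removed = 0
    for _ in range(reps):
        _, removed = grubbs_screen(rng.normal(0.0, 1.0, n))
        clean_removed += bool(removed)
    return {
        "detection_rate": detected / reps,
        "clean_removal_rate": clean_removed / reps,
        "reps": reps,
    }
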