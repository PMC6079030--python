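"""Synthetic cohorts for the reciprocal social-evaluation analysis.

No participant data are deposited for this task, so every downstream stage
is exercised on simulated agents.  The generative model is the fitted model
itself — the standard parameter-recovery convention: agents update a value
of self-protection (VSP) by the delta rule over reverse-coded feedback and
make binary partner evaluations through the logistic policy on VSP and
objective creativity.  Learning rates decline linearly with age
(default slope -0.029 per year, the fitted developmental effect), with
Gaussian perturbation clipped to [0, 1].

For the mediation stage, participant-level (age, mediator, outcome) triads
are generated from a linear path model with a configurable indirect effect;
the mediator plays the role of a region-of-interest parametric-modulation
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import TaskDesign
from .predictors import rescale_oc
from .rl import reverse_code_fb, update_vsp


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one synthetic participant."""

    alpha: float
    beta_vsp: float
    beta_oc: float
    beta_0: float
    age: float = np.nan

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")


@dataclass(frozen=True)
class CohortSpec:
    """Population-level generative settings for a synthetic cohort.

    ``alpha_intercept`` is alpha at ``reference_age``; agent alphas follow
    ``alpha_intercept + alpha_age_slope * (age - reference_age) + noise``
    clipped to [0, 1].  Policy weights are drawn i.i.d. Gaussian; the default
    beta_vsp mean is negative (self-protective agents).
    """

    n_agents: int = 60
    age_range: tuple[float, float] = (10.0, 25.0)
    alpha_age_slope: float = -0.029
    alpha_intercept: float = 0.65
    reference_age: float = 10.0
    alpha_noise_sd: float = 0.1
    beta_vsp_mean: float = -3.0
    beta_vsp_sd: float = 0.5
    beta_oc_mean: float = 1.0
    beta_oc_sd: float = 0.3
    beta_0_mean: float = 0.0
    beta_0_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be ordered")


@dataclass(frozen=True)
class MediationCohortSpec:
    """Generative settings for (age, mediator, outcome) mediation triads."""

    n: int = 56
    a_path: float = 0.5
    b_path: float = 0.4
    c_prime: float = 0.0
    age_range: tuple[float, float] = (10.0, 25.0)
    mediator_noise_sd: float = 1.0
    outcome_noise_sd: float = 1.0
    n_outliers: int = 0
    outlier_magnitude_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("n must be >= 4 (outlier screening + regression)")

    @property
    def indirect(self) -> float:
        return self.a_path * self.b_path


def simulate_agent(params: AgentParams, design: TaskDesign, seed: int) -> pd.DataFrame:
    """Simulate one agent's 75 binary decisions on a task design.

    The decision at trial t is Bernoulli with probability
    ``logistic(beta_vsp * VSP_t + beta_oc * OC_t + beta_0)`` where VSP_t is
    the value updated through the current trial's feedback.
    """
    rng = np.random.default_rng(seed)
    fb = np.array([reverse_code_fb(v) for v in design.valences], dtype=float)
    traj = update_vsp(fb, params.alpha)
    oc = rescale_oc(np.asarray(design.oc_levels, dtype=float))
    eta = params.beta_vsp * traj.vsp[1:] + params.beta_oc * oc + params.beta_0
    p = 1.0 / (1.0 + np.exp(-eta))
    decisions = (rng.random(p.size) < p).astype(int)
    return pd.DataFrame(
        {
            "trial": np.arange(1, len(design) + 1),
            "valence": design.valences,
            "oc_level": design.oc_levels,
            "decision": decisions,
            "p_decision": p,
            "vsp": traj.vsp[1:],
        }
    )


def sample_agents(spec: CohortSpec) -> pd.DataFrame:
    """Draw agent-level parameters (ages, alphas, policy weights)."""
    rng = np.random.default_rng(spec.seed)
    ages = rng.uniform(*spec.age_range, size=spec.n_agents)
    alpha_mean = spec.alpha_intercept + spec.alpha_age_slope * (ages - spec.reference_age)
    alphas = np.clip(
        alpha_mean + rng.normal(0.0, spec.alpha_noise_sd, spec.n_agents), 0.0, 1.0
    )
    return pd.DataFrame(
        {
            "participant": [f"agent{i:03d}" for i in range(spec.n_agents)],
            "age": ages,
            "true_alpha": alphas,
            "true_beta_vsp": rng.normal(spec.beta_vsp_mean, spec.beta_vsp_sd, spec.n_agents),
            "true_beta_oc": rng.normal(spec.beta_oc_mean, spec.beta_oc_sd, spec.n_agents),
            "true_beta_0": rng.normal(spec.beta_0_mean, spec.beta_0_sd, spec.n_agents),
        }
    )


def simulate_cohort(
    spec: CohortSpec, design: TaskDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort on a shared design.

    Returns ``(trial_table, participant_table)``: the trial table has
    ``n_agents * n_trials`` rows (participant, trial, valence, oc_level,
    decision); the participant table carries ages and true generative
    parameters.
    """
    participants = sample_agents(spec)
    rng = np.random.default_rng(spec.seed + 1)
    agent_seeds = rng.integers(0, 2**31 - 1, size=spec.n_agents)
    frames = []
    for i, row in participants.iterrows():
        params = AgentParams(
            alpha=row["true_alpha"],
            beta_vsp=row["true_beta_vsp"],
            beta_oc=row["true_beta_oc"],
            beta_0=row["true_beta_0"],
            age=row["age"],
        )
        df = simulate_agent(params, design, seed=int(agent_seeds[i]))
        df.insert(0, "participant", row["participant"])
        frames.append(df[["participant", "trial", "valence", "oc_level", "decision"]])
    return pd.concat(frames, ignore_index=True), participants


def simulate_mediation_cohort(spec: MediationCohortSpec) -> pd.DataFrame:
    """Simulate (age, mediator, outcome) triads from the linear path model.

    mediator = a * age + e_m;  outcome = b * mediator + c' * age + e_y.
    Optional outliers of ``outlier_magnitude_sd`` mediator-noise SDs are
    injected into the mediator column (flagged in ``is_outlier``).
    """
    rng = np.random.default_rng(spec.seed)
    age = rng.uniform(*spec.age_range, size=spec.n)
    mediator = spec.a_path * age + rng.normal(0.0, spec.mediator_noise_sd, spec.n)
    outcome = (
        spec.b_path * mediator
        + spec.c_prime * age
        + rng.normal(0.0, spec.outcome_noise_sd, spec.n)
    )
    is_outlier = np.zeros(spec.n, dtype=bool)
    if spec.n_outliers > 0:
        idx = rng.choice(spec.n, size=spec.n_outliers, replace=False)
        signs = rng.choice([-1.0, 1.0], size=spec.n_outliers)
        mediator[idx] += signs * spec.outlier_magnitude_sd * spec.mediator_noise_sd
        is_outlier[idx] = True
    return pd.DataFrame(
        {
            "participant": [f"p{i:03d}" for i in range(spec.n)],
            "age": age,
            "mediator": mediator,
            "outcome": outcome,
            "is_outlier": is_outlier,
        }
    )
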