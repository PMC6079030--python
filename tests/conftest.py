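import numpy as np
import pandas as pd
import pytest

from vsprl import AgentParams, CohortSpec, DesignSpec, generate_design, simulate_agent, simulate_cohort
from vsprl.predictors import cohort_design_matrix


@pytest.fixture(scope="session")
def default_design():
    return generate_design(DesignSpec(seed=11))


@pytest.fixture(scope="session")
def small_cohort(default_design):
    """12-agent cohort with trial table, predictors and participant truth."""
    spec = CohortSpec(n_agents=12, seed=3)
    trials, participants = simulate_cohort(spec, default_design)
    return cohort_design_matrix(trials), participants


@pytest.fixture(scope="session")
def self_protective_trials(default_design):
    """One strongly self-protective agent's trials with predictors."""
    params = AgentParams(alpha=0.4, beta_vsp=-3.0, beta_oc=1.0, beta_0=0.0)
    df = simulate_agent(params, default_design, seed=42)
    df.insert(0, "participant", "p0")
    return cohort_design_matrix(df[["participant", "trial", "valence", "oc_level", "decision"]])


def make_trials(valences, decisions, oc_levels=None):
    """Hand-built single-participant trial table."""
    n = len(valences)
    return pd.DataFrame(
        {
            "participant": ["p0"] * n,
            "trial": np.arange(1, n + 1),
            "valence": valences,
            "oc_level": oc_levels if oc_levels is not None else [3] * n,
            "decision": decisions,
        }
    )
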