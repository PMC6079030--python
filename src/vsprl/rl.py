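"""Reinforcement-learning model of the value of self-protection (VSP).

A latent value VSP, initialized at 0, is updated each trial by a delta rule
toward the *reverse-coded* feedback (negative feedback raises VSP):

    VSP_t = VSP_{t-1} + alpha * (FB_t - VSP_{t-1}),   FB in {+1, 0, -1}

so that VSP_t is an exponentially weighted sum of past feedback,

    VSP_t = (1-alpha)^t VSP_0 + sum_{i=1}^{t} (1-alpha)^{t-i} alpha FB_i.

A high learning rate alpha weights recent feedback (current-feedback-like
behavior); a low alpha integrates the full history (accumulated-feedback-like
behavior).  Decisions follow a logistic policy on VSP and objective
creativity:

    P(D=1) = logistic(b_vsp * VSP + b_oc * OC + b_0)

For each participant the learning rate is estimated by profiling: for every
alpha on a dense grid in [0, 1] the policy weights are fit by maximum
likelihood, and the alpha with the highest maximized log-likelihood is
selected.  Participants whose fitted b_vsp is positive (favorable evaluation
under high VSP) violate the self-protection assumption and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._logit import fit_logit, log_likelihood
from .behavioral import check_response_variability
from .predictors import build_design_matrix

REVERSE_CODE = {"negative": 1, "neutral": 0, "positive": -1}

DEFAULT_GRID_STEP = 0.0001


def reverse_code_fb(valence: str) -> int:
    """Reverse-code feedback for the VSP update: negative -> +1, positive -> -1."""
    try:
        return REVERSE_CODE[valence]
    except KeyError:
        raise ValueError(f"unknown feedback valence: {valence!r}") from None


@dataclass
class VSPTrajectory:
    """Latent value and prediction-error sequences for one (fb, alpha) pair."""

    vsp: np.ndarray  # length T+1, vsp[0] = 0
    pe: np.ndarray  # length T, pe[t-1] = fb[t-1] - vsp[t-1]
    fb: np.ndarray  # reverse-coded feedback, length T
    alpha: float


def update_vsp(fb, alpha: float) -> VSPTrajectory:
    """Run the delta-rule recursion over a reverse-coded feedback sequence."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    fb = np.asarray(fb, dtype=float)
    T = fb.size
    vsp = np.zeros(T + 1)
    pe = np.zeros(T)
    for t in range(T):
        pe[t] = fb[t] - vsp[t]
        vsp[t + 1] = vsp[t] + alpha * pe[t]
    return VSPTrajectory(vsp=vsp, pe=pe, fb=fb, alpha=alpha)


def closed_form_vsp(fb, alpha: float, t: int) -> float:
    """Closed-form VSP_t: exponentially weighted sum of the first t feedbacks."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    fb = np.asarray(fb, dtype=float)
    if t < 0 or t > fb.size:
        raise ValueError(f"t must be in 0..{fb.size}")
    if t == 0:
        return 0.0
    weights = (1.0 - alpha) ** (t - np.arange(1, t + 1)) * alpha
    return float(weights @ fb[:t])


def _vsp_grid(fb: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """VSP trajectories for many alphas at once: shape (len(alphas), T+1)."""
    T = fb.size
    V = np.zeros((alphas.size, T + 1))
    for t in range(T):
        V[:, t + 1] = V[:, t] + alphas * (fb[t] - V[:, t])
    return V


@dataclass
class SelfProtectionResults:
    """Grid-MLE estimates of the self-protection RL model for one participant."""

    participant: object
    alpha_hat: float
    params: pd.Series  # vsp, oc, const
    llf: float
    grid_step: float
    nobs: int
    identifiable: bool
    ll_range: float
    separated: bool
    penalized: bool
    converged: bool
    vsp: np.ndarray = field(repr=False, default=None)
    pe: np.ndarray = field(repr=False, default=None)
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def beta_vsp(self) -> float:
        return float(self.params["vsp"])

    @property
    def beta_oc(self) -> float:
        return float(self.params["oc"])

    @property
    def beta_0(self) -> float:
        return float(self.params["const"])

    @property
    def violator(self) -> bool:
        """Favorable evaluation under high VSP contradicts self-protection."""
        return flag_violator(self.beta_vsp)

    def summary(self) -> str:
        lines = [
            "Self-protection RL model (grid-profile MLE)",
            "=" * 46,
            f"participant: {self.participant}   n trials: {self.nobs}",
            f"alpha_hat: {self.alpha_hat:.4f}  (grid step {self.grid_step})",
            f"max log-likelihood: {self.llf:.4f}",
            f"beta_vsp: {self.beta_vsp:.4f}  beta_oc: {self.beta_oc:.4f}  "
            f"beta_0: {self.beta_0:.4f}",
            f"violator: {self.violator}   identifiable: {self.identifiable}",
        ]
        if self.separated:
            lines.append(
                "note: separation detected"
                + ("; Firth-penalized fit" if self.penalized else "")
            )
        return "\n".join(lines)


def flag_violator(beta_vsp: float) -> bool:
    """True iff the fitted VSP weight is positive (assumption violation)."""
    return bool(beta_vsp > 0)


class SelfProtectionModel:
    """Self-protection RL model for one participant's trial sequence.

    Parameters
    ----------
    trials : DataFrame
        One participant's trials (``trial``, ``valence``, ``oc_level``,
        ``decision``); the rescaled OC predictor is built if absent.
    vsp_timing : {"current", "previous"}
        Whether the decision at trial t is driven by VSP updated through the
        current trial's feedback (VSP_t, default) or by VSP_{t-1}.
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        vsp_timing: str = "current",
        min_minority: int = 3,
    ):
        if "oc" not in trials.columns:
            trials = build_design_matrix(trials)
        if vsp_timing not in ("current", "previous"):
            raise ValueError("vsp_timing must be 'current' or 'previous'")
        self.trials = trials.sort_values("trial").reset_index(drop=True)
        self.vsp_timing = vsp_timing
        self.min_minority = min_minority
        self.participant = (
            trials["participant"].iloc[0] if "participant" in trials else None
        )
        self.fb = np.array(
            [reverse_code_fb(v) for v in self.trials["valence"]], dtype=float
        )
        self.oc = self.trials["oc"].to_numpy(dtype=float)
        self.endog = self.trials["decision"].to_numpy(dtype=float)

    def _decision_vsp(self, V: np.ndarray) -> np.ndarray:
        """Map grid trajectories (G, T+1) to the per-trial decision VSP (G, T)."""
        return V[:, 1:] if self.vsp_timing == "current" else V[:, :-1]

    def _profile(self, alphas: np.ndarray):
        """Maximized log-likelihood (and fit) at each alpha on ``alphas``."""
        V = self._decision_vsp(_vsp_grid(self.fb, alphas))
        T = self.endog.size
        ones = np.ones(T)
        lls = np.empty(alphas.size)
        fits = []
        for i in range(alphas.size):
            X = np.column_stack([V[i], self.oc, ones])
            res = fit_logit(X, self.endog)
            lls[i] = res.llf
            fits.append(res)
        return lls, fits, V

    def fit(
        self,
        grid_step: float = DEFAULT_GRID_STEP,
        method: str = "two_stage",
        coarse_step: float = 0.01,
        flat_tol: float = 1e-6,
    ) -> SelfProtectionResults:
        """Grid-profile MLE of the learning rate.

        ``method="exhaustive"`` scans the full grid {0, grid_step, ..., 1}
        (the reference implementation); ``"two_stage"`` pre-scans at
        ``coarse_step`` and refines the winning cell at ``grid_step``, which
        finds the same optimum for the unimodal profiles this model produces.
        Ties are broken toward smaller alpha.  A flat profile
        (max - min < ``flat_tol``) is flagged non-identifiable and reported
        as alpha_hat = 0.
        """
        check = check_response_variability(self.endog, self.min_minority)
        if not check.passed:
            nan = pd.Series(np.nan, index=["vsp", "oc", "const"])
            return SelfProtectionResults(
                participant=self.participant,
                alpha_hat=np.nan,
                params=nan,
                llf=np.nan,
                grid_step=grid_step,
                nobs=self.endog.size,
                identifiable=False,
                ll_range=np.nan,
                separated=False,
                penalized=False,
                converged=False,
                excluded=True,
                exclusion_reason=check.reason,
            )

        if method == "exhaustive":
            n = int(round(1.0 / grid_step))
            alphas = np.linspace(0.0, 1.0, n + 1)
            lls, fits, V = self._profile(alphas)
            ll_range = float(lls.max() - lls.min())
            best = 0 if ll_range < flat_tol else int(np.argmax(lls))
        elif method == "two_stage":
            n_c = int(round(1.0 / coarse_step))
            coarse = np.linspace(0.0, 1.0, n_c + 1)
            lls_c, _, _ = self._profile(coarse)
            ll_range = float(lls_c.max() - lls_c.min())
            if ll_range < flat_tol:
                alphas = np.array([0.0])
                lls, fits, V = self._profile(alphas)
                best = 0
            else:
                a0 = coarse[int(np.argmax(lls_c))]
                lo = max(0.0, a0 - coarse_step)
                hi = min(1.0, a0 + coarse_step)
                # fine grid stays on the global {0, grid_step, ...} lattice
                i_lo = int(np.ceil(round(lo / grid_step, 9)))
                i_hi = int(np.floor(round(hi / grid_step, 9)))
                alphas = np.arange(i_lo, i_hi + 1) * grid_step
                lls, fits, V = self._profile(alphas)
                best = int(np.argmax(lls))
        else:
            raise ValueError(f"unknown method {method!r}")

        res = fits[best]
        traj = update_vsp(self.fb, float(alphas[best]))
        return SelfProtectionResults(
            participant=self.participant,
            alpha_hat=float(alphas[best]),
            params=pd.Series(res.params, index=["vsp", "oc", "const"]),
            llf=res.llf,
            grid_step=grid_step,
            nobs=self.endog.size,
            identifiable=ll_range >= flat_tol,
            ll_range=ll_range,
            separated=res.separated,
            penalized=res.penalized,
            converged=res.converged,
            vsp=traj.vsp,
            pe=traj.pe,
        )

    def loglike(self, alpha: float, beta_vsp: float, beta_oc: float, beta_0: float) -> float:
        """Log-likelihood of the full model at explicit parameter values."""
        traj = update_vsp(self.fb, alpha)
        v = traj.vsp[1:] if self.vsp_timing == "current" else traj.vsp[:-1]
        X = np.column_stack([v, self.oc, np.ones(self.endog.size)])
        return log_likelihood(X, self.endog, np.array([beta_vsp, beta_oc, beta_0]))


def fit_rl_cohort(
    trials: pd.DataFrame,
    grid_step: float = DEFAULT_GRID_STEP,
    method: str = "two_stage",
    vsp_timing: str = "current",
    min_minority: int = 3,
) -> list[SelfProtectionResults]:
    """Fit the self-protection RL model to every participant in a trial table."""
    if "participant" not in trials:
        raise ValueError("trial table needs a 'participant' column")
    out = []
    for _, grp in trials.groupby("participant", sort=True):
        model = SelfProtectionModel(grp, vsp_timing=vsp_timing, min_minority=min_minority)
        out.append(model.fit(grid_step=grid_step, method=method))
    return out


def rl_fits_frame(fits: list[SelfProtectionResults]) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append(
            {
                "participant": f.participant,
                "alpha_hat": f.alpha_hat,
                "beta_vsp": f.beta_vsp if not f.excluded else np.nan,
                "beta_oc": f.beta_oc if not f.excluded else np.nan,
                "beta_0": f.beta_0 if not f.excluded else np.nan,
                "max_ll": f.llf,
                "violator": f.violator if not f.excluded else False,
                "identifiable": f.identifiable,
                "excluded": f.excluded,
                "reason": f.exclusion_reason,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class VSPBiasResult:
    """Partner-derogation/enhancement bias conditioned on the sign of VSP.

    Per participant, trial-wise fitted decision probabilities are averaged
    within VSP > 0 ("high") and VSP < 0 ("low") trial sets; each set's group
    distribution is tested against chance (0.5) with a one-sample Wilcoxon
    signed-rank test, and the two sets are compared with a paired test.
    """

    per_participant: pd.DataFrame  # participant, mean_p_high, mean_p_low
    median_high: float
    iqr_high: float
    median_low: float
    iqr_low: float
    high_vs_chance: object  # GroupResult
    low_vs_chance: object
    high_vs_low: object


def vsp_bias_analysis(
    fits: list[SelfProtectionResults], trials: pd.DataFrame
) -> VSPBiasResult:
    """High- vs low-VSP decision-probability bias across a fitted cohort."""
    from .groupstats import wilcoxon_signed_rank

    rows = []
    for f in fits:
        if f.excluded or f.violator:
            continue
        grp = trials[trials["participant"] == f.participant]
        model = SelfProtectionModel(grp)
        v = f.vsp[1:]  # decision-phase VSP_t
        eta = f.beta_vsp * v + f.beta_oc * model.oc + f.beta_0
        p = 1.0 / (1.0 + np.exp(-eta))
        hi, lo = p[v > 0], p[v < 0]
        rows.append(
            {
                "participant": f.participant,
                "mean_p_high": hi.mean() if hi.size else np.nan,
                "mean_p_low": lo.mean() if lo.size else np.nan,
            }
        )
    if not rows:
        raise ValueError("no non-violator participants available")
    per = pd.DataFrame(rows)

    hi_vals = per["mean_p_high"].dropna().to_numpy()
    lo_vals = per["mean_p_low"].dropna().to_numpy()
    paired = per.dropna(subset=["mean_p_high", "mean_p_low"])

    def _iqr(x):
        return float(stats.iqr(x)) if x.size else np.nan

    return VSPBiasResult(
        per_participant=per,
        median_high=float(np.median(hi_vals)) if hi_vals.size else np.nan,
        iqr_high=_iqr(hi_vals),
        median_low=float(np.median(lo_vals)) if lo_vals.size else np.nan,
        iqr_low=_iqr(lo_vals),
        high_vs_chance=wilcoxon_signed_rank(hi_vals, 0.5) if hi_vals.size >= 5 else None,
        low_vs_chance=wilcoxon_signed_rank(lo_vals, 0.5) if lo_vals.size >= 5 else None,
        high_vs_low=(
            wilcoxon_signed_rank(
                paired["mean_p_high"].to_numpy() - paired["mean_p_low"].to_numpy(), 0.0
            )
            if len(paired) >= 5
            else None
        ),
    )
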