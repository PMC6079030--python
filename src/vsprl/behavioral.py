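"""Per-participant feedback-influence model (trial-wise logistic regression).

The decision model is

    Logit[P(Decision = 1)] = b_cfb * cfb + b_accfb * accfb + b_oc * oc + b_0

fitted by maximum likelihood to each participant's 75 binary partner
evaluations.  ``b_cfb`` and ``b_accfb`` measure the influence of the current
and the accumulated feedback on the decision, controlling for the objective
creativity of the partner's artwork.

Participants whose button presses are uniform or near-uniform carry no
information about the slopes and are excluded before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._logit import LogitFit, fit_logit
from .predictors import build_design_matrix

PREDICTORS = ("cfb", "accfb", "oc")


@dataclass
class VariabilityCheck:
    passed: bool
    reason: str
    n_minority: int


def check_response_variability(decisions, min_minority: int = 3) -> VariabilityCheck:
    """Flag uniform / near-uniform responders.

    Fails when the minority response class occurs fewer than ``min_minority``
    times; with fewer than 3 minority responses the three slopes of the
    decision model have essentially no leverage.
    """
    d = np.asarray(decisions)
    if d.size == 0:
        raise ValueError("empty decision sequence")
    n1 = int(np.sum(d == 1))
    n_minority = min(n1, d.size - n1)
    if n_minority == 0:
        return VariabilityCheck(False, "uniform button press", 0)
    if n_minority < min_minority:
        return VariabilityCheck(
            False,
            f"near-uniform button press (minority class {n_minority} < {min_minority})",
            n_minority,
        )
    return VariabilityCheck(True, "", n_minority)


@dataclass
class FeedbackInfluenceResults:
    """Fitted feedback-influence coefficients for one participant."""

    participant: object
    params: pd.Series  # index: cfb, accfb, oc, const
    bse: pd.Series
    llf: float
    nobs: int
    converged: bool
    separated: bool
    penalized: bool
    rank_deficient: bool
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def beta_cfb(self) -> float:
        return float(self.params["cfb"])

    @property
    def beta_accfb(self) -> float:
        return float(self.params["accfb"])

    @property
    def beta_oc(self) -> float:
        return float(self.params["oc"])

    @property
    def beta_0(self) -> float:
        return float(self.params["const"])

    def summary(self) -> str:
        lines = [
            "Feedback-influence logistic model",
            "=" * 44,
            f"participant: {self.participant}   n trials: {self.nobs}",
            f"log-likelihood: {self.llf:.4f}   converged: {self.converged}",
        ]
        if self.separated:
            lines.append(
                "note: quasi-complete separation detected"
                + ("; Firth-penalized fit reported" if self.penalized else "")
            )
        if self.rank_deficient:
            lines.append("note: rank-deficient design; some coefficients inestimable")
        lines.append(f"{'':8s}{'coef':>10s}{'std err':>10s}")
        for name in (*PREDICTORS, "const"):
            lines.append(
                f"{name:8s}{self.params[name]:10.4f}{self.bse[name]:10.4f}"
            )
        return "\n".join(lines)


class FeedbackInfluenceModel:
    """Trial-wise logistic decision model for one participant.

    Parameters
    ----------
    trials : DataFrame
        One participant's trials with columns ``trial``, ``valence``,
        ``oc_level``, ``decision`` (predictor columns ``cfb``/``accfb``/``oc``
        are built if absent).
    min_minority : int
        Response-variability exclusion threshold.
    """

    def __init__(self, trials: pd.DataFrame, min_minority: int = 3, accfb_bound: int = 3):
        if not set(PREDICTORS) <= set(trials.columns):
            trials = build_design_matrix(trials, bound=accfb_bound)
        self.trials = trials.reset_index(drop=True)
        self.min_minority = min_minority
        self.participant = (
            trials["participant"].iloc[0] if "participant" in trials else None
        )
        self.endog = self.trials["decision"].to_numpy(dtype=float)
        self.exog = np.column_stack(
            [self.trials[c].to_numpy(dtype=float) for c in PREDICTORS]
            + [np.ones(len(self.trials))]
        )

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> FeedbackInfluenceResults:
        check = check_response_variability(self.endog, self.min_minority)
        if not check.passed:
            nan = pd.Series(np.nan, index=[*PREDICTORS, "const"])
            return FeedbackInfluenceResults(
                participant=self.participant,
                params=nan,
                bse=nan.copy(),
                llf=np.nan,
                nobs=len(self.endog),
                converged=False,
                separated=False,
                penalized=False,
                rank_deficient=False,
                excluded=True,
                exclusion_reason=check.reason,
            )
        res: LogitFit = fit_logit(
            self.exog, self.endog, tol=tol, max_iter=max_iter, compute_bse=True
        )
        names = [*PREDICTORS, "const"]
        return FeedbackInfluenceResults(
            participant=self.participant,
            params=pd.Series(res.params, index=names),
            bse=pd.Series(res.bse, index=names),
            llf=res.llf,
            nobs=len(self.endog),
            converged=res.converged,
            separated=res.separated,
            penalized=res.penalized,
            rank_deficient=res.rank_deficient,
        )


@dataclass
class CohortFitSummary:
    fits: list[FeedbackInfluenceResults] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return sum(f.excluded for f in self.fits)

    @property
    def n_fitted(self) -> int:
        return sum(not f.excluded for f in self.fits)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            rows.append(
                {
                    "participant": f.participant,
                    "beta_cfb": f.beta_cfb,
                    "beta_accfb": f.beta_accfb,
                    "beta_oc": f.beta_oc,
                    "beta_0": f.beta_0,
                    "ll": f.llf,
                    "converged": f.converged,
                    "separated": f.separated,
                    "excluded": f.excluded,
                    "reason": f.exclusion_reason,
                }
            )
        return pd.DataFrame(rows)


def fit_cohort(trials: pd.DataFrame, min_minority: int = 3) -> CohortFitSummary:
    """Fit the feedback-influence model to every participant in a trial table."""
    if len(trials) == 0:
        raise ValueError("empty trial table")
    if "participant" not in trials:
        raise ValueError("trial table needs a 'participant' column")
    fits = []
    for _, grp in trials.groupby("participant", sort=True):
        fits.append(FeedbackInfluenceModel(grp, min_minority=min_minority).fit())
    return CohortFitSummary(fits=fits)
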