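"""Trial-wise regressors for the feedback-influence decision model.

Three predictors drive the per-trial logistic model of partner evaluation:

* ``cfb`` — current feedback, coded -1 (negative), 0 (neutral), +1 (positive);
* ``accfb`` — accumulated feedback, the running sum of cfb codes from trial 1
  through the immediately preceding trial, rescaled by the design bound
  (default 3) into [-1, +1]; accfb of trial 1 is 0;
* ``oc`` — objective creativity level 1..5, rescaled linearly to [-1, +1].

No mean-centering is applied; codings enter the model raw.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import VALENCE_CODE

__all__ = [
    "code_cfb",
    "compute_accfb",
    "rescale_oc",
    "build_design_matrix",
    "cohort_design_matrix",
]


class AccfbBoundWarning(UserWarning):
    """Raw accumulated-feedback sum exceeded the rescaling bound."""


def code_cfb(valence: str) -> int:
    """Code a feedback valence as -1 (negative), 0 (neutral) or +1 (positive)."""
    try:
        return VALENCE_CODE[valence]
    except KeyError:
        raise ValueError(f"unknown feedback valence: {valence!r}") from None


def compute_accfb(valences: Sequence[str] | Iterable[str], bound: int = 3) -> np.ndarray:
    """Accumulated-feedback regressor for a valence sequence.

    ``accfb[t] = sum_{i<t} cfb[i] / bound`` with ``accfb[0] = 0`` (1-based
    trial t corresponds to index t-1).  Emits :class:`AccfbBoundWarning` when
    the raw running sum leaves ``[-bound, bound]`` — a non-conforming design.
    """
    codes = np.array([code_cfb(v) for v in valences], dtype=float)
    if codes.size == 0:
        raise ValueError("valence sequence is empty")
    raw = np.concatenate([[0.0], np.cumsum(codes)[:-1]])
    if np.max(np.abs(raw)) > bound:
        warnings.warn(
            f"raw accumulated feedback reaches {np.max(np.abs(raw)):.0f}, "
            f"beyond the bound {bound}; rescaled values exceed [-1, 1]",
            AccfbBoundWarning,
            stacklevel=2,
        )
    return raw / bound


def rescale_oc(oc_level) -> float | np.ndarray:
    """Map objective-creativity level 1..5 linearly onto [-1, +1]."""
    arr = np.asarray(oc_level, dtype=float)
    if np.any((arr < 1) | (arr > 5)):
        raise ValueError(f"oc_level out of range 1..5: {oc_level!r}")
    out = (arr - 3.0) / 2.0
    return out if out.ndim else float(out)


def build_design_matrix(trials: pd.DataFrame, bound: int = 3) -> pd.DataFrame:
    """Analysis-ready predictor table for one participant.

    Parameters
    ----------
    trials : DataFrame
        Columns ``trial`` (1-based), ``valence``, ``oc_level`` and optionally
        ``decision`` and ``participant``; one participant, sorted by trial.
    bound : int
        Accumulated-feedback rescaling bound.

    Returns
    -------
    DataFrame with the input columns plus ``cfb``, ``accfb``, ``oc``.
    """
    trials = trials.sort_values("trial").reset_index(drop=True)
    idx = trials["trial"].to_numpy()
    if len(np.unique(idx)) != len(idx):
        raise ValueError("duplicate trial indices")
    if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
        raise ValueError("trial indices must be 1..T without gaps")
    if "participant" in trials and trials["participant"].nunique() > 1:
        raise ValueError("build_design_matrix expects a single participant")

    out = trials.copy()
    out["cfb"] = [code_cfb(v) for v in trials["valence"]]
    out["accfb"] = compute_accfb(trials["valence"], bound=bound)
    out["oc"] = rescale_oc(trials["oc_level"].to_numpy())
    return out


def cohort_design_matrix(trials: pd.DataFrame, bound: int = 3) -> pd.DataFrame:
    """Apply :func:`build_design_matrix` per participant and re-stack."""
    if "participant" not in trials:
        raise ValueError("trial table needs a 'participant' column")
    parts = [
        build_design_matrix(grp, bound=bound)
        for _, grp in trials.groupby("participant", sort=True)
    ]
    return pd.concat(parts, ignore_index=True)
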