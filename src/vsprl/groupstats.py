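"""Group-level inferential statistics for the behavioral analyses.

Covers the analyses run on per-participant parameter estimates: ordinary
and bootstrap regression on age, the feedback-type x age interaction
(ANCOVA), one-sample t and Wilcoxon signed-rank tests, Spearman rank
correlation, and the Shapiro-Wilk normality gate used to route analyses to
nonparametric branches.  All tests are two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupResult",
    "regress_on_age",
    "bootstrap_regression",
    "ancova_interaction",
    "one_sample_t",
    "wilcoxon_signed_rank",
    "spearman_correlation",
    "shapiro_wilk",
]


@dataclass
class GroupResult:
    """Uniform container for one group-level analysis."""

    analysis: str
    estimate: float
    se: float | None = None
    statistic: float | None = None
    df: tuple | float | None = None
    p_value: float | None = None
    ci: tuple[float, float] | None = None
    n: int | None = None
    extras: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        if self.ci is not None:
            lo, hi = self.ci
            return not (lo <= 0.0 <= hi)
        return self.p_value is not None and self.p_value < 0.05

    def to_dict(self) -> dict:
        d = {
            "analysis": self.analysis,
            "estimate": _f(self.estimate),
            "se": _f(self.se),
            "statistic": _f(self.statistic),
            "df": list(self.df) if isinstance(self.df, tuple) else _f(self.df),
            "p_value": _f(self.p_value),
            "ci": [_f(self.ci[0]), _f(self.ci[1])] if self.ci else None,
            "n": self.n,
        }
        d.update({k: _f(v) if isinstance(v, (int, float, np.floating)) else v
                  for k, v in self.extras.items()})
        return d


def _f(x):
    return None if x is None else float(x)


def _check_pairs(values, ages, min_n=3):
    v = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if v.size != a.size:
        raise ValueError("values and ages must be paired")
    if v.size < min_n:
        raise ValueError(f"need at least {min_n} observations")
    return v, a


def regress_on_age(values, ages, name: str = "regress_on_age") -> GroupResult:
    """OLS of a per-participant estimate on age, F-test on the age term."""
    v, a = _check_pairs(values, ages)
    if np.var(a) == 0 or np.var(v) == 0:
        raise ValueError("degenerate variance in values or ages")
    res = stats.linregress(a, v)
    n = v.size
    f_stat = res.rvalue**2 / max(1 - res.rvalue**2, 1e-300) * (n - 2)
    return GroupResult(
        analysis=name,
        estimate=float(res.slope),
        se=float(res.stderr),
        statistic=float(f_stat),
        df=(1, n - 2),
        p_value=float(res.pvalue),
        n=n,
        extras={"intercept": float(res.intercept), "r_squared": float(res.rvalue**2)},
    )


def _boot_slopes(v: np.ndarray, a: np.ndarray, n_boot: int, rng) -> np.ndarray:
    """Case-resampling bootstrap slopes, vectorized across resamples."""
    n = v.size
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = a[idx], v[idx]
    xm = xb.mean(axis=1, keepdims=True)
    ym = yb.mean(axis=1, keepdims=True)
    sxx = np.sum((xb - xm) ** 2, axis=1)
    sxy = np.sum((xb - xm) * (yb - ym), axis=1)
    return np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)


def bootstrap_regression(
    values, ages, n_boot: int = 5000, seed: int = 0, ci_level: float = 0.95
) -> GroupResult:
    """Nonparametric case-resampling bootstrap of the OLS slope.

    Percentile confidence interval; the effect is called significant when
    the interval excludes zero.
    """
    v, a = _check_pairs(values, ages)
    rng = np.random.default_rng(seed)
    sxx = np.sum((a - a.mean()) ** 2)
    slope = float(np.sum((a - a.mean()) * (v - v.mean())) / sxx) if sxx > 0 else 0.0
    slopes = _boot_slopes(v, a, n_boot, rng)
    q = (1 - ci_level) / 2
    lo, hi = np.quantile(slopes, [q, 1 - q])
    # two-tailed bootstrap p: smallest level at which the CI excludes zero
    p = 2 * min(np.mean(slopes <= 0.0), np.mean(slopes >= 0.0))
    return GroupResult(
        analysis="bootstrap_regression",
        estimate=slope,
        se=float(np.std(slopes, ddof=1)),
        p_value=float(min(1.0, p)),
        ci=(float(lo), float(hi)),
        n=v.size,
        extras={"n_boot": n_boot},
    )


def ancova_interaction(table: pd.DataFrame) -> GroupResult:
    """Feedback-type x age interaction on per-participant influence estimates.

    Expects a long table with columns ``participant``, ``feedback_type``
    (two levels), ``estimate``, ``age``; every participant must contribute
    one row per feedback type.  Fits estimate ~ type + age + type:age and
    F-tests the interaction term.
    """
    required = {"participant", "feedback_type", "estimate", "age"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    types = sorted(table["feedback_type"].unique())
    if len(types) != 2:
        raise ValueError(f"feedback_type must have exactly 2 levels, got {types}")
    counts = table.groupby("participant")["feedback_type"].nunique()
    if (counts != 2).any():
        bad = counts[counts != 2].index.tolist()
        raise ValueError(f"participants missing a feedback-type row: {bad}")

    y = table["estimate"].to_numpy(dtype=float)
    t = (table["feedback_type"] == types[1]).to_numpy(dtype=float)
    a = table["age"].to_numpy(dtype=float)
    n = y.size
    X_full = np.column_stack([np.ones(n), t, a, t * a])
    X_red = X_full[:, :3]
    beta_full, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    rss_full = float(np.sum((y - X_full @ beta_full) ** 2))
    beta_red, *_ = np.linalg.lstsq(X_red, y, rcond=None)
    rss_red = float(np.sum((y - X_red @ beta_red) ** 2))
    df2 = n - X_full.shape[1]
    if df2 <= 0:
        # saturated case: interaction coefficient is exact, no F-test
        return GroupResult(
            analysis="ancova_interaction",
            estimate=float(beta_full[3]),
            df=(1, df2),
            n=n,
            extras={"types": types},
        )
    if rss_full <= 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (rss_red - rss_full) / (rss_full / df2)
        p = float(stats.f.sf(f_stat, 1, df2))
    return GroupResult(
        analysis="ancova_interaction",
        estimate=float(beta_full[3]),
        statistic=float(f_stat),
        df=(1, df2),
        p_value=p,
        n=n,
        extras={"types": types},
    )


def one_sample_t(values, mu0: float = 0.0) -> GroupResult:
    """Two-tailed one-sample t test of the mean against ``mu0``."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 observations")
    if np.var(v) == 0:
        raise ValueError("zero variance")
    res = stats.ttest_1samp(v, mu0)
    return GroupResult(
        analysis="one_sample_t",
        estimate=float(v.mean() - mu0),
        se=float(stats.sem(v)),
        statistic=float(res.statistic),
        df=v.size - 1,
        p_value=float(res.pvalue),
        n=v.size,
    )


def wilcoxon_signed_rank(values, mu0: float = 0.0) -> GroupResult:
    """Two-tailed one-sample Wilcoxon signed-rank test against ``mu0``.

    Exact enumeration for n <= 25 (after dropping exact ties with mu0),
    continuity-corrected normal approximation above.  Reports the median
    and interquartile range as descriptives.
    """
    v = np.asarray(values, dtype=float)
    d = v - mu0
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all values tie with mu0")
    if d.size < 5:
        raise ValueError("need at least 5 non-tied observations")
    method = "exact" if d.size <= 25 else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    z = getattr(res, "zstatistic", None)
    return GroupResult(
        analysis="wilcoxon_signed_rank",
        estimate=float(np.median(v)),
        statistic=float(z) if z is not None else float(res.statistic),
        p_value=float(res.pvalue),
        n=int(d.size),
        extras={
            "median": float(np.median(v)),
            "iqr": float(stats.iqr(v)),
            "W": float(res.statistic),
            "method": method,
        },
    )


def spearman_correlation(x, y) -> GroupResult:
    """Spearman rank-order correlation (mid-ranks for ties), two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector")
    r, p = stats.spearmanr(x, y)
    return GroupResult(
        analysis="spearman_correlation",
        estimate=float(r),
        statistic=float(r),
        df=x.size - 2,
        p_value=float(p),
        n=x.size,
    )


def shapiro_wilk(residuals) -> GroupResult:
    """Shapiro-Wilk normality test; gates the nonparametric analysis branch."""
    r = np.asarray(residuals, dtype=float)
    if not 3 <= r.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    w, p = stats.shapiro(r)
    return GroupResult(
        analysis="shapiro_wilk",
        estimate=float(w),
        statistic=float(w),
        p_value=float(p),
        n=r.size,
        extras={"normal_at_05": bool(p >= 0.05)},
    )
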