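"""Behavioral statistics for temporal-adaptation sessions.

Three analyses: trailing moving averages for visualising single-subject
adaptation curves, the Pearson correlation between baseline response
variability and total adaptation-phase response time (noisier baselines
predict weaker adaptation), and the paired one-sided t-test comparing
adaptation under multisensory vs unisensory feedback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import baseline_variance
from .simulate import SessionData

__all__ = [
    "StatsReport",
    "moving_average",
    "variability_adaptation_correlation",
    "paired_one_sided_t",
    "adaptation_summary_table",
    "cohort_report",
]


@dataclass
class StatsReport:
    """Correlation and paired-test results for a cohort of sessions."""

    r: float
    r_df: int
    r_p: float  # two-sided
    t: float
    t_df: int
    t_p_one_sided: float
    per_session: pd.DataFrame
    flags: list[str]

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.r,
            "r_df": self.r_df,
            "r_p_two_sided": self.r_p,
            "paired_t": self.t,
            "t_df": self.t_df,
            "t_p_one_sided": self.t_p_one_sided,
            "flags": self.flags,
        }

    def __str__(self) -> str:
        return (
            f"baseline variance vs adaptation: r({self.r_df}) = {self.r:.3f}, "
            f"p = {self.r_p:.4g} (two-sided)\n"
            f"MC vs UC adaptation: t({self.t_df}) = {self.t:.3f}, "
            f"p = {self.t_p_one_sided:.4g} (one-sided)"
        )


def moving_average(series, window: int = 10) -> np.ndarray:
    """Trailing simple moving average with partial windows at the start.

    Entry ``t`` averages the last ``window`` values up to and including
    ``t``; the first ``window − 1`` entries average what is available, so
    the output has the input's length.  Window 1 is the identity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(series, dtype=float))
    return s.rolling(window, min_periods=1).mean().to_numpy()


def variability_adaptation_correlation(
    sessions: list[SessionData],
) -> tuple[float, int, float]:
    """Pearson correlation of baseline variance with summed adaptation RsT.

    One point per session: the unbiased baseline-phase response variance
    against the sum of adaptation-phase response times (equivalent to the
    mean up to the fixed trial count).  Returns ``(r, df, p)`` with
    ``df = n − 2`` and a two-sided p value.
    """
    if len(sessions) < 3:
        raise ValueError("need at least 3 sessions for a correlation")
    bvar = np.array([baseline_variance(s) for s in sessions])
    adapt_sum = np.array([s.phase_rst("adaptation").sum() for s in sessions])
    if np.ptp(bvar) == 0 or np.ptp(adapt_sum) == 0:
        raise ValueError("correlation undefined: a variable has zero variance")
    r, p = sps.pearsonr(bvar, adapt_sum)
    return float(r), len(sessions) - 2, float(p)


def paired_one_sided_t(
    mc_values, uc_values, alternative: str = "mc_greater"
) -> tuple[float, int, float]:
    """Paired t-test between matched MC and UC measurements.

    ``alternative='mc_greater'`` tests whether the multisensory values
    exceed the unisensory ones (the expected direction: more reliable
    feedback supports stronger adaptation).  Zero-variance differences
    give an infinite t, resolved to p = 0 or 1 by the sign of the mean
    difference.  Returns ``(t, df, p_one_sided)``.
    """
    mc = np.asarray(mc_values, dtype=float)
    uc = np.asarray(uc_values, dtype=float)
    if mc.shape != uc.shape:
        raise ValueError("paired vectors must have equal length")
    n = len(mc)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if alternative not in ("mc_greater", "uc_greater"):
        raise ValueError(f"unknown alternative {alternative!r}")

    diff = mc - uc
    df = n - 1
    if np.std(diff, ddof=1) == 0:
        mean = diff.mean()
        if mean == 0:
            return 0.0, df, 0.5
        t = np.inf if mean > 0 else -np.inf
        wanted_positive = alternative == "mc_greater"
        p = 0.0 if (mean > 0) == wanted_positive else 1.0
        return float(t), df, p

    scipy_alt = "greater" if alternative == "mc_greater" else "less"
    res = sps.ttest_rel(mc, uc, alternative=scipy_alt)
    return float(res.statistic), df, float(res.pvalue)


def adaptation_summary_table(sessions: list[SessionData]) -> pd.DataFrame:
    """Per-session baseline variance and adaptation-phase RsT aggregates."""
    rows = []
    for s in sessions:
        adapt = s.phase_rst("adaptation")
        rows.append(
            {
                "participant": s.participant,
                "condition": s.condition,
                "baseline_var": baseline_variance(s),
                "adaptation_rst_sum": float(adapt.sum()),
                "adaptation_rst_mean": float(adapt.mean()),
            }
        )
    return pd.DataFrame(rows)


def cohort_report(sessions: list[SessionData]) -> StatsReport:
    """Full behavioral analysis of a two-condition cohort.

    Pools all sessions for the variability-adaptation correlation, then
    pairs MC and UC sessions by participant for the one-sided comparison
    of mean adaptation-phase RsT.
    """
    flags: list[str] = []
    table = adaptation_summary_table(sessions)
    r, r_df, r_p = variability_adaptation_correlation(sessions)

    wide = table.pivot_table(
        index="participant", columns="condition", values="adaptation_rst_mean"
    )
    if not {"MC", "UC"}.issubset(wide.columns):
        raise ValueError("cohort must contain both MC and UC sessions")
    wide = wide.dropna(subset=["MC", "UC"])
    t, t_df, t_p = paired_one_sided_t(wide["MC"], wide["UC"])
    if not np.isfinite(t):
        flags.append("degenerate paired t (zero-variance differences)")
    return StatsReport(
        r=r, r_df=r_df, r_p=r_p, t=t, t_df=t_df, t_p_one_sided=t_p,
        per_session=table, flags=flags,
    )
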