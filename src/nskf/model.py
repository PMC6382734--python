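"""Fitting the NSKF to a behavioral session.

The filter has five parameters, but only the measurement-variance growth
rate Δ(σᵐ)² is free: the baseline measurement variance (σ₀ᵐ)² is fixed to
the session's own baseline response variance, and the initial state, its
variance and the process variance are fixed a priori (0 s, 0.25 s²,
4e-6 s²).  The fit minimises the squared error between the filter's
one-step-ahead prediction (the prior mean Xₜ⁻, the model's forecast
before seeing trial t's feedback) and the observed response times,
centred on the session's baseline mean so the filter tracks adjustment
*from* baseline.

Usage follows the Model/Results convention::

    model = AdaptationModel.from_session(session)
    res = model.fit()
    print(res.summary())

The objective is continuous and, on data generated by the model itself,
unimodal in Δ(σᵐ)²; a deterministic grid pre-scan followed by bounded
Brent refinement makes the fit reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .core import FilterTrace, ModelParams, run_filter
from .schedules import PerturbationSchedule
from .simulate import SessionData, session_from_dataframe

__all__ = [
    "AdaptationModel",
    "AdaptationResults",
    "ConditionSummary",
    "baseline_variance",
    "fit_delta",
    "fit_condition",
]

DEFAULT_DELTA_MAX = 1e-2  # s²·ms⁻¹ upper search bound
DEFAULT_GRID_POINTS = 200


def baseline_variance(session: SessionData) -> float:
    """Unbiased sample variance (s²) of the baseline-phase response times.

    Used as the fixed baseline measurement variance (σ₀ᵐ)² of the fit —
    the response variability with no perturbation is the model's proxy
    for the feedback noise of the unperturbed state.
    """
    base = session.phase_rst("baseline")
    if len(base) < 2:
        raise ValueError("need at least 2 baseline trials to estimate variance")
    return float(np.var(base, ddof=1))


class AdaptationModel:
    """NSKF adaptation model for one participant-condition session.

    Parameters
    ----------
    rst : array-like
        Per-trial response times (s).
    schedule : PerturbationSchedule
        Per-trial imposed delays with phase labels.
    base_meas_var : float, optional
        Fixed baseline measurement variance (σ₀ᵐ)².  Defaults to the
        unbiased variance of the baseline-phase responses.
    x0_prior, var0_prior, process_var : float
        Fixed initial state (s), initial state variance (s²) and process
        variance (s²).
    center : bool
        Subtract the baseline-mean response before computing residuals
        (default True): the filter's state is the adjustment relative to
        the participant's own baseline.
    adaptation_only : bool
        Restrict the loss to adaptation-phase trials (default False:
        all trials enter the sum).
    """

    def __init__(
        self,
        rst,
        schedule: PerturbationSchedule,
        base_meas_var: float | None = None,
        x0_prior: float = 0.0,
        var0_prior: float = 0.25,
        process_var: float = 4e-6,
        center: bool = True,
        adaptation_only: bool = False,
    ):
        self.rst = np.asarray(rst, dtype=float)
        if len(self.rst) != len(schedule):
            raise ValueError("rst and schedule lengths differ")
        self.schedule = schedule
        self.center = center
        self.adaptation_only = adaptation_only

        base_idx = [i for i, ph in enumerate(schedule.phase_labels) if ph == "baseline"]
        self.baseline_mean = float(np.mean(self.rst[base_idx])) if base_idx else 0.0
        if base_meas_var is None:
            if len(base_idx) < 2:
                raise ValueError(
                    "base_meas_var must be given when the session has "
                    "fewer than 2 baseline trials"
                )
            base_meas_var = float(np.var(self.rst[base_idx], ddof=1))
        if base_meas_var <= 0:
            raise ValueError("base_meas_var must be > 0")
        self.base_meas_var = base_meas_var
        self.x0_prior = x0_prior
        self.var0_prior = var0_prior
        self.process_var = process_var

        if adaptation_only:
            self._loss_idx = np.array(
                [i for i, ph in enumerate(schedule.phase_labels) if ph == "adaptation"]
            )
        else:
            self._loss_idx = np.arange(len(self.rst))

    @classmethod
    def from_session(cls, session: SessionData, **kwargs) -> "AdaptationModel":
        return cls(session.rst, session.schedule(), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "AdaptationModel":
        """Build from a session table in the package's CSV dialect."""
        return cls.from_session(session_from_dataframe(df), **kwargs)

    def _params(self, delta: float) -> ModelParams:
        return ModelParams(
            x0_prior=self.x0_prior,
            var0_prior=self.var0_prior,
            process_var=self.process_var,
            base_meas_var=self.base_meas_var,
            delta_meas_var=delta,
        )

    def _prior_means(self, delta: float) -> np.ndarray:
        # Bare-float replica of core.run_filter's recursion (same clipping),
        # kept free of per-step object construction: the grid scan calls it
        # hundreds of times per fit.
        from .core import VAR_FLOOR

        delays = self.schedule.delays
        out = np.empty(len(delays))
        mean, var = self.x0_prior, self.var0_prior
        for t, d in enumerate(delays):
            out[t] = mean
            r = max(self.base_meas_var + delta * d, VAR_FLOOR)
            k = var / (var + r)
            mean = mean + k * (d / 1000.0 - mean)
            var = max((1.0 - k) * var + self.process_var, VAR_FLOOR)
        return out

    def sse(self, delta: float) -> float:
        """Sum of squared residuals at a given Δ(σᵐ)²."""
        priors = self._prior_means(delta)
        target = self.rst - self.baseline_mean if self.center else self.rst
        resid = priors[self._loss_idx] - target[self._loss_idx]
        return float(np.dot(resid, resid))

    def fit(
        self,
        delta_max: float = DEFAULT_DELTA_MAX,
        grid_points: int = DEFAULT_GRID_POINTS,
        stationary: bool = False,
        fixed_delta: float | None = None,
    ) -> "AdaptationResults":
        """Estimate Δ(σᵐ)² by least squares.

        A ``grid_points``-point scan over [0, ``delta_max``] locates the
        basin; Brent's method then refines within the bracketing grid
        cell.  With ``stationary=True`` no search is run and Δ is fixed
        at 0 (the SKF fit, used for model comparison); ``fixed_delta``
        likewise evaluates the model at a given Δ without searching.
        """
        if stationary:
            fixed_delta = 0.0
        if fixed_delta is not None:
            if fixed_delta < 0:
                raise ValueError("fixed_delta must be >= 0")
            return self._results(fixed_delta, bound_hit=False,
                                 stationary=fixed_delta == 0.0)

        grid = np.linspace(0.0, delta_max, grid_points)
        sse_grid = np.array([self.sse(d) for d in grid])
        k = int(np.argmin(sse_grid))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        if lo == hi:
            delta_hat = grid[k]
        else:
            res = minimize_scalar(self.sse, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-12})
            delta_hat = float(res.x)
            if self.sse(grid[k]) < self.sse(delta_hat):
                delta_hat = float(grid[k])

        bound_hit = k == len(grid) - 1
        if bound_hit:
            warnings.warn(
                "fitted delta_meas_var is at the upper search bound; "
                "increase delta_max", RuntimeWarning, stacklevel=2,
            )
        return self._results(delta_hat, bound_hit=bound_hit, stationary=False)

    def _results(self, delta_hat: float, bound_hit: bool, stationary: bool):
        trace = run_filter(self._params(delta_hat), self.schedule)
        return AdaptationResults(
            model=self,
            delta_hat=float(delta_hat),
            sse=self.sse(delta_hat),
            base_meas_var_used=self.base_meas_var,
            trace=trace,
            n_trials_used=len(self._loss_idx),
            bound_hit=bound_hit,
            stationary=stationary,
        )


@dataclass
class AdaptationResults:
    """Fit of the (N)SKF to one session."""

    model: AdaptationModel
    delta_hat: float  # Δ(σᵐ)² estimate (s²·ms⁻¹)
    sse: float  # squared-error objective at the optimum (s²)
    base_meas_var_used: float  # fixed (σ₀ᵐ)² (s²)
    trace: FilterTrace  # filter run at the optimum
    n_trials_used: int
    bound_hit: bool = False
    stationary: bool = False

    @property
    def predictions(self) -> np.ndarray:
        """One-step-ahead predictions (prior means) on the RsT scale."""
        offset = self.model.baseline_mean if self.model.center else 0.0
        return self.trace.prior_means + offset

    def summary(self) -> str:
        m = self.model
        kind = "SKF (stationary)" if self.stationary else "NSKF"
        lines = [
            f"{kind} adaptation fit",
            "=" * 46,
            f"{'n trials (in loss / total)':34s} {self.n_trials_used} / {len(m.rst)}",
            f"{'baseline meas. var (σ0m)² [s²]':34s} {self.base_meas_var_used:.6g}",
            f"{'Δ(σm)² [s²/ms]':34s} {self.delta_hat:.6g}",
            f"{'SSE [s²]':34s} {self.sse:.6g}",
            f"{'final gain K':34s} {self.trace.gains[-1]:.4g}",
            f"{'final prediction [s]':34s} {self.predictions[-1]:.4g}",
        ]
        if self.bound_hit:
            lines.append("WARNING: estimate at upper search bound")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "delta_hat": self.delta_hat,
            "sse": self.sse,
            "base_meas_var_used": self.base_meas_var_used,
            "n_trials_used": self.n_trials_used,
            "bound_hit": self.bound_hit,
            "stationary": self.stationary,
        }


def fit_delta(session: SessionData, **kwargs) -> AdaptationResults:
    """Functional wrapper: fit Δ(σᵐ)² to one session."""
    fit_kwargs = {k: kwargs.pop(k)
                  for k in ("delta_max", "grid_points", "stationary", "fixed_delta")
                  if k in kwargs}
    return AdaptationModel.from_session(session, **kwargs).fit(**fit_kwargs)


@dataclass
class ConditionSummary:
    """Per-condition aggregates of the per-session fits."""

    condition: str
    n_sessions: int
    base_meas_var_mean: float
    base_meas_var_ci: tuple[float, float] | None
    delta_hat_mean: float
    delta_hat_ci: tuple[float, float] | None
    per_session: pd.DataFrame = field(repr=False)
    ci_flagged: bool = False  # True when a CI could not be formed

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "n_sessions": self.n_sessions,
            "base_meas_var_mean": self.base_meas_var_mean,
            "base_meas_var_ci": list(self.base_meas_var_ci) if self.base_meas_var_ci else None,
            "delta_hat_mean": self.delta_hat_mean,
            "delta_hat_ci": list(self.delta_hat_ci) if self.delta_hat_ci else None,
            "ci_flagged": self.ci_flagged,
        }


def fit_condition(
    sessions: list[SessionData],
    n_boot: int = 10_000,
    seed: int = 0,
    **fit_kwargs,
) -> dict[str, ConditionSummary]:
    """Fit every session and summarise per condition.

    Returns, for each condition present, the mean baseline variance and
    mean Δ(σᵐ)² across sessions with percentile bootstrap 95% CIs over
    participants (``n_boot`` resamples, seeded).  Single-session
    conditions get no CI and are flagged.
    """
    rows = []
    for s in sessions:
        res = fit_delta(s, **fit_kwargs)
        rows.append(
            {
                "participant": s.participant,
                "condition": s.condition,
                "base_meas_var": res.base_meas_var_used,
                "delta_hat": res.delta_hat,
                "sse": res.sse,
            }
        )
    table = pd.DataFrame(rows)

    rng = np.random.default_rng(seed)
    out: dict[str, ConditionSummary] = {}
    for cond, sub in table.groupby("condition"):
        bv = sub["base_meas_var"].to_numpy()
        dh = sub["delta_hat"].to_numpy()
        n = len(sub)
        if n >= 2:
            bv_ci = _percentile_boot_ci(bv, n_boot, rng)
            dh_ci = _percentile_boot_ci(dh, n_boot, rng)
            flagged = False
        else:
            bv_ci = dh_ci = None
            flagged = True
        out[cond] = ConditionSummary(
            condition=cond,
            n_sessions=n,
            base_meas_var_mean=float(bv.mean()),
            base_meas_var_ci=bv_ci,
            delta_hat_mean=float(dh.mean()),
            delta_hat_ci=dh_ci,
            per_session=sub.reset_index(drop=True),
            ci_flagged=flagged,
        )
    return out


def _percentile_boot_ci(
    values: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[float, float]:
    """95% percentile bootstrap CI of the mean over participants."""
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    boot_means = values[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    return float(lo), float(hi)
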