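"""Scalar Kalman filtering with delay-dependent measurement noise.

The model treats trial-by-trial temporal adaptation as optimal state
estimation.  The latent state is the response-lead adjustment (in seconds,
relative to the participant's own baseline) required to compensate an
imposed feedback delay.  On every trial the imposed delay ``D_t`` (ms) is
presented to the learner as a noisy measurement of that state, and the
estimate is updated by the standard scalar Kalman recursion

    prior mean:      X_t^-      = X̂_{t-1}
    prior variance:  (σ_t^-)²   = (σ_{t-1})² + (σ^p)²
    gain:            K_t        = (σ_t^-)² / ((σ_t^-)² + (σ_t^m)²)
    posterior mean:  X̂_t       = X_t^- + K_t (X_t^m − X_t^-)
    posterior var.:  (σ_t)²     = (1 − K_t)(σ_t^-)²

The stationary filter (SKF) keeps the measurement variance fixed at
(σ₀^m)².  The non-stationary filter (NSKF) lets it grow linearly with the
imposed delay,

    (σ_t^m)² = (σ₀^m)² + Δ(σ^m)² · D_t ,

so that larger temporal perturbations are measured less reliably and the
gain — hence the per-trial learning rate — shrinks as the perturbation
grows.  Setting the growth rate Δ(σ^m)² to zero recovers the SKF exactly.

Units: times and their variances in seconds / s²; delays in milliseconds;
the growth rate Δ(σ^m)² in s² per ms of delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "StateSpaceParams",
    "FilterStep",
    "FilterTrace",
    "measurement_variance",
    "kalman_step",
    "run_filter",
    "state_space_run",
    "riccati_fixed_point",
]

# Variances are clipped below at this floor to keep the gain well defined
# in degenerate configurations.
VAR_FLOOR = 1e-15


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the (N)SKF learner.

    Parameters
    ----------
    x0_prior : float
        Initial state estimate X̂₀⁻ (s).  Default 0: no adjustment expected
        before any feedback.
    var0_prior : float
        Initial state-estimate variance (σ₀⁻)² (s²).
    process_var : float
        Process variance (σᵖ)² (s²): assumed per-trial drift of the world.
    base_meas_var : float
        Baseline measurement variance (σ₀ᵐ)² (s²), the feedback noise with
        no imposed delay.
    delta_meas_var : float
        Growth of the measurement variance per millisecond of imposed
        delay, Δ(σᵐ)² (s²·ms⁻¹).  Zero yields the stationary filter.
    """

    x0_prior: float = 0.0
    var0_prior: float = 0.25
    process_var: float = 4e-6
    base_meas_var: float = 1e-3
    delta_meas_var: float = 0.0

    def __post_init__(self) -> None:
        if self.var0_prior <= 0:
            raise ValueError("var0_prior must be > 0")
        if self.process_var <= 0:
            raise ValueError("process_var must be > 0")
        if self.base_meas_var <= 0:
            raise ValueError("base_meas_var must be > 0")
        if self.delta_meas_var < 0:
            raise ValueError("delta_meas_var must be >= 0")

    def with_delta(self, delta_meas_var: float) -> "ModelParams":
        """Copy with a different measurement-variance growth rate."""
        return ModelParams(
            x0_prior=self.x0_prior,
            var0_prior=self.var0_prior,
            process_var=self.process_var,
            base_meas_var=self.base_meas_var,
            delta_meas_var=delta_meas_var,
        )


@dataclass(frozen=True)
class StateSpaceParams:
    """Retention/learning-rate parameterisation of trial-by-trial learning.

    The classical single-rate state-space model
    ``x_t = A·x_{t-1} + B·e_{t-1}`` with retention factor ``A`` and
    learning rate ``B``, both in [0, 1].  The Kalman filter is this model
    with A = 1 and a trial-varying, uncertainty-derived B = K_t.
    """

    retention: float
    learning_rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError("retention must lie in [0, 1]")
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in [0, 1]")


@dataclass(frozen=True)
class FilterStep:
    """All quantities produced by the filter on one trial."""

    trial: int  # 1-based
    delay_ms: float
    meas: float  # measurement X_t^m (s)
    prior_mean: float  # X_t^- (s)
    prior_var: float  # (σ_t^-)² (s²)
    meas_var: float  # (σ_t^m)² (s²)
    gain: float  # K_t
    post_mean: float  # X̂_t (s)
    post_var: float  # (σ_t)² (s²)


@dataclass
class FilterTrace:
    """Ordered per-trial filter output plus the generating parameters."""

    steps: list[FilterStep]
    params: ModelParams
    phase_labels: list[str] | None = field(default=None)

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self):
        return iter(self.steps)

    @property
    def prior_means(self) -> np.ndarray:
        return np.array([s.prior_mean for s in self.steps])

    @property
    def post_means(self) -> np.ndarray:
        return np.array([s.post_mean for s in self.steps])

    @property
    def prior_vars(self) -> np.ndarray:
        return np.array([s.prior_var for s in self.steps])

    @property
    def post_vars(self) -> np.ndarray:
        return np.array([s.post_var for s in self.steps])

    @property
    def gains(self) -> np.ndarray:
        return np.array([s.gain for s in self.steps])

    @property
    def meas_vars(self) -> np.ndarray:
        return np.array([s.meas_var for s in self.steps])

    @property
    def delays_ms(self) -> np.ndarray:
        return np.array([s.delay_ms for s in self.steps])

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "trial": [s.trial for s in self.steps],
                "delay_ms": self.delays_ms,
                "meas_s": [s.meas for s in self.steps],
                "prior_mean_s": self.prior_means,
                "prior_var_s2": self.prior_vars,
                "meas_var_s2": self.meas_vars,
                "gain": self.gains,
                "post_mean_s": self.post_means,
                "post_var_s2": self.post_vars,
            }
        )
        if self.phase_labels is not None:
            df["phase"] = self.phase_labels
        return df


def measurement_variance(params: ModelParams, delay_ms: float) -> float:
    """Measurement variance (σ_t^m)² for an imposed delay of ``delay_ms``.

    Linear growth with delay; with ``delta_meas_var == 0`` the result is
    the constant baseline variance of the stationary filter.
    """
    if delay_ms < 0:
        raise ValueError(f"imposed delay must be >= 0, got {delay_ms}")
    return params.base_meas_var + params.delta_meas_var * delay_ms


def kalman_step(
    prior_mean: float, prior_var: float, meas: float, meas_var: float
) -> tuple[float, float, float]:
    """One scalar Kalman update.

    Returns ``(gain, post_mean, post_var)``.  The posterior mean is the
    reliability-weighted combination of prediction and measurement, i.e.
    the prediction moved *toward* the measurement by the gain fraction of
    the prediction error.
    """
    if prior_var <= 0:
        raise ValueError("prior_var must be > 0")
    if meas_var <= 0:
        raise ValueError("meas_var must be > 0")
    gain = prior_var / (prior_var + meas_var)
    post_mean = prior_mean + gain * (meas - prior_mean)
    post_var = (1.0 - gain) * prior_var
    return gain, post_mean, post_var


def run_filter(params: ModelParams, schedule) -> FilterTrace:
    """Run the (N)SKF over a perturbation schedule.

    On trial ``t`` the measurement is the imposed delay ``D_t`` expressed
    in seconds, with variance from :func:`measurement_variance`.  The
    prior of trial 1 is ``(x0_prior, var0_prior)``; afterwards the prior
    mean is the previous posterior mean and the prior variance is the
    previous posterior variance plus the process variance.

    Parameters
    ----------
    params : ModelParams
    schedule : PerturbationSchedule or sequence of delays (ms)

    Returns
    -------
    FilterTrace
        One :class:`FilterStep` per trial, phase labels attached when the
        schedule carries them.
    """
    delays, labels = _coerce_schedule(schedule)
    if len(delays) == 0:
        raise ValueError("schedule must contain at least one trial")

    steps: list[FilterStep] = []
    prior_mean = params.x0_prior
    prior_var = params.var0_prior
    for t, d in enumerate(delays, start=1):
        meas = d / 1000.0  # delay measured in seconds
        meas_var = max(measurement_variance(params, d), VAR_FLOOR)
        gain, post_mean, post_var = kalman_step(prior_mean, prior_var, meas, meas_var)
        steps.append(
            FilterStep(
                trial=t,
                delay_ms=float(d),
                meas=meas,
                prior_mean=prior_mean,
                prior_var=prior_var,
                meas_var=meas_var,
                gain=gain,
                post_mean=post_mean,
                post_var=post_var,
            )
        )
        prior_mean = post_mean
        prior_var = max(post_var + params.process_var, VAR_FLOOR)
    return FilterTrace(steps=steps, params=params, phase_labels=labels)


def state_space_run(ss: StateSpaceParams, errors: Sequence[float]) -> np.ndarray:
    """Forward-run the single-rate state-space learner.

    ``x_t = A·x_{t-1} + B·e_{t-1}`` with x₀ = 0; returns x₁..x_T.
    """
    errors = np.asarray(errors, dtype=float)
    x = np.empty(len(errors))
    prev = 0.0
    for t, e in enumerate(errors):
        prev = ss.retention * prev + ss.learning_rate * e
        x[t] = prev
    return x


def riccati_fixed_point(process_var: float, meas_var: float) -> float:
    """Steady-state *prior* variance of the scalar filter at constant noise.

    Solves v = (1 − v/(v+r))·v + q, i.e. v² − q·v − q·r = 0, and returns
    the positive root v* = (q + sqrt(q² + 4qr)) / 2.
    """
    q, r = process_var, meas_var
    return 0.5 * (q + np.sqrt(q * q + 4.0 * q * r))


def _coerce_schedule(schedule) -> tuple[np.ndarray, list[str] | None]:
    """Accept a PerturbationSchedule or a bare delay sequence."""
    labels = None
    if hasattr(schedule, "delays"):
        delays = np.asarray(schedule.delays, dtype=float)
        labels = list(schedule.phase_labels) if schedule.phase_labels is not None else None
    else:
        delays = np.asarray(schedule, dtype=float)
    if np.any(delays < 0):
        raise ValueError("schedule contains negative delays")
    return delays, labels
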