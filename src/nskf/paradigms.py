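"""Forward simulation of perturbation paradigms and time-constant fits.

Runs the fitted filter under paradigms beyond the incremental-delay
experiment — a stationary perturbation block, a block followed by
washout, and blocks of varying length — and characterises the model's
adaptation and de-adaptation speed by fitting saturating exponentials

    x(t) = asymptote + amplitude · exp(−t / tau)

to the phase-segmented prediction curves (t counted in trials from phase
onset, 1-based).  Everything here is deterministic: no random numbers
enter the simulations or the fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import FilterTrace, ModelParams, run_filter
from .schedules import PerturbationSchedule, build_schedule

__all__ = [
    "ExpFit",
    "simulate_paradigm",
    "trials_to_converge",
    "fit_exponential",
    "adaptation_washout_taus",
    "deadaptation_vs_length",
]

NOT_REACHED = -1  # sentinel from trials_to_converge


@dataclass(frozen=True)
class ExpFit:
    """Parameters of a saturating-exponential fit to a trace segment."""

    asymptote: float  # s
    amplitude: float  # s
    tau: float  # trials
    rss: float  # s²
    flagged: bool = False  # degenerate segment or non-convergence


def simulate_paradigm(params: ModelParams, schedule: PerturbationSchedule) -> FilterTrace:
    """Run the filter over a paradigm schedule (thin wrapper, keeps the
    schedule's phase labels on the returned trace for segmentation)."""
    return run_filter(params, schedule)


def phase_segment(trace: FilterTrace, phase: str) -> np.ndarray:
    """Prior-mean predictions of one contiguous phase of a trace."""
    if trace.phase_labels is None:
        raise ValueError("trace carries no phase labels")
    idx = [i for i, ph in enumerate(trace.phase_labels) if ph == phase]
    if not idx:
        raise ValueError(f"trace has no {phase!r} trials")
    return trace.prior_means[idx[0] : idx[-1] + 1]


def trials_to_converge(
    trace: FilterTrace,
    target: float,
    tol_frac: float = 0.05,
    phase: str = "adaptation",
    abs_tol: float | None = None,
) -> int:
    """Trials from phase onset until the prediction is within tolerance.

    Returns the 1-based index, counted from the onset of ``phase``, of
    the first trial whose prior-mean prediction lies within
    ``tol_frac · |target|`` of ``target`` (or within ``abs_tol`` when
    given — required when the target is 0, where a fractional band is
    empty).  Returns :data:`NOT_REACHED` (−1) if never satisfied.
    """
    seg = phase_segment(trace, phase)
    if abs_tol is None:
        if target == 0:
            raise ValueError("target 0 needs abs_tol (fractional band is empty)")
        band = tol_frac * abs(target)
    else:
        band = abs_tol
    hit = np.nonzero(np.abs(seg - target) <= band)[0]
    return int(hit[0]) + 1 if len(hit) else NOT_REACHED


def fit_exponential(segment, tau_grid=None) -> ExpFit:
    """Least-squares saturating-exponential fit to a trace segment.

    Deterministic multi-start: for each tau on a log-spaced grid the
    conditionally-linear asymptote and amplitude are solved in closed
    form, and the best start seeds a local refinement.  A constant
    segment (or one the optimiser cannot improve) comes back flagged,
    with tau from the best grid start.
    """
    y = np.asarray(segment, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 points to fit an exponential")
    t = np.arange(1, n + 1, dtype=float)

    if np.ptp(y) < 1e-14:
        return ExpFit(asymptote=float(y.mean()), amplitude=0.0, tau=np.nan,
                      rss=0.0, flagged=True)

    if tau_grid is None:
        tau_grid = np.geomspace(0.5, 10.0 * n, 60)

    # profile over tau: asymptote/amplitude are linear given tau
    best = None
    for tau in tau_grid:
        basis = np.exp(-t / tau)
        X = np.column_stack([np.ones(n), basis])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((X @ coef - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, tau, coef)
    rss0, tau0, (a0, b0) = best

    def f(tt, a, b, tau):
        return a + b * np.exp(-tt / tau)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(f, t, y, p0=[a0, b0, tau0], maxfev=5000)
        rss = float(np.sum((f(t, *popt) - y) ** 2))
        if rss <= rss0 and popt[2] > 0:
            return ExpFit(asymptote=float(popt[0]), amplitude=float(popt[1]),
                          tau=float(popt[2]), rss=rss)
    except RuntimeError:
        pass
    return ExpFit(asymptote=float(a0), amplitude=float(b0), tau=float(tau0),
                  rss=rss0, flagged=True)


def adaptation_washout_taus(
    params: ModelParams,
    n_baseline: int = 135,
    n_adapt: int = 500,
    max_delay_ms: float = 135.0,
    n_washout: int = 500,
) -> tuple[ExpFit, ExpFit]:
    """Time constants of adaptation and of the following de-adaptation.

    Simulates baseline → constant-delay block → washout and fits one
    exponential to each post-onset segment.  Returns
    ``(adaptation_fit, washout_fit)``.
    """
    sched = build_schedule("washout", n_baseline=n_baseline, n_adapt=n_adapt,
                           max_delay_ms=max_delay_ms, n_washout=n_washout)
    trace = simulate_paradigm(params, sched)
    fit_adapt = fit_exponential(phase_segment(trace, "adaptation"))
    fit_wash = fit_exponential(phase_segment(trace, "washout"))
    return fit_adapt, fit_wash


def deadaptation_vs_length(
    params: ModelParams,
    lengths,
    n_baseline: int = 135,
    max_delay_ms: float = 135.0,
    n_washout: int = 500,
) -> list[tuple[int, float]]:
    """De-adaptation time constant as a function of adaptation length.

    For each block length, simulates baseline → block → washout and fits
    the washout exponential.  Returns ``[(length, tau), ...]`` in input
    order.  Under delay-dependent measurement noise the block's unreliable
    feedback lets state uncertainty accumulate toward a higher steady
    level; longer blocks enter washout with more uncertainty, so the
    suddenly-reliable zero-delay feedback gets a larger gain and washout
    is (weakly) faster after longer adaptation.
    """
    lengths = [int(n) for n in lengths]
    if len(set(lengths)) < 1:
        raise ValueError("need at least one adaptation length")
    out = []
    for n_adapt in lengths:
        _, wash = adaptation_washout_taus(
            params, n_baseline=n_baseline, n_adapt=n_adapt,
            max_delay_ms=max_delay_ms, n_washout=n_washout,
        )
        out.append((n_adapt, wash.tau))
    return out
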