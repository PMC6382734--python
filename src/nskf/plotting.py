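"""Static figures: single-subject adaptation curves and paradigm traces."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core import FilterTrace
from .simulate import SessionData
from .stats import moving_average

__all__ = ["plot_session", "plot_paradigm"]


def plot_session(session: SessionData, window: int = 10, ax=None):
    """Per-trial responses, their moving average, and the delay ramp."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    trials = np.arange(1, len(session) + 1)
    rst_ms = session.rst * 1000.0
    ax.plot(trials, rst_ms, ".", ms=3, alpha=0.4, label="RsT")
    ax.plot(trials, moving_average(rst_ms, window), lw=1.5,
            label=f"moving average ({window})")
    ax.plot(trials, session.delays_ms, "k--", lw=1, label="imposed delay")
    ax.set_xlabel("trial")
    ax.set_ylabel("response time (ms)")
    ax.set_title(f"{session.participant} / {session.condition}")
    ax.legend(frameon=False)
    return ax


def plot_paradigm(trace: FilterTrace, ax=None):
    """Model prediction against the perturbation for a paradigm run."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    trials = np.arange(1, len(trace) + 1)
    ax.plot(trials, trace.prior_means * 1000.0, lw=1.5, label="model prediction")
    ax.plot(trials, trace.delays_ms, "k--", lw=1, label="perturbation")
    ax.set_xlabel("trial")
    ax.set_ylabel("time (ms)")
    ax.legend(frameon=False)
    return ax
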