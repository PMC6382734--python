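"""Perturbation schedules: per-trial imposed delays with phase labels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PerturbationSchedule", "build_schedule"]

BASELINE = "baseline"
ADAPTATION = "adaptation"
WASHOUT = "washout"


@dataclass(frozen=True)
class PerturbationSchedule:
    """Imposed delay (ms) and phase label for every trial of a session."""

    delays: tuple[float, ...]
    phase_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.delays) != len(self.phase_labels):
            raise ValueError("delays and phase_labels must have equal length")
        if any(d < 0 for d in self.delays):
            raise ValueError("delays must be >= 0")
        for d, ph in zip(self.delays, self.phase_labels):
            if ph == BASELINE and d != 0:
                raise ValueError("baseline trials must carry zero delay")
            if ph == WASHOUT and d != 0:
                raise ValueError("washout trials must carry zero delay")

    def __len__(self) -> int:
        return len(self.delays)

    @property
    def n_baseline(self) -> int:
        return sum(1 for ph in self.phase_labels if ph == BASELINE)

    @property
    def n_adapt(self) -> int:
        return sum(1 for ph in self.phase_labels if ph == ADAPTATION)

    @property
    def n_washout(self) -> int:
        return sum(1 for ph in self.phase_labels if ph == WASHOUT)

    def phase_slice(self, phase: str) -> slice:
        """Contiguous index range of a phase (phases are contiguous by
        construction in :func:`build_schedule`)."""
        idx = [i for i, ph in enumerate(self.phase_labels) if ph == phase]
        if not idx:
            raise ValueError(f"schedule has no {phase!r} trials")
        return slice(idx[0], idx[-1] + 1)


def build_schedule(
    kind: str,
    n_baseline: int = 135,
    n_adapt: int = 135,
    max_delay_ms: float = 135.0,
    n_washout: int = 0,
    step_ms: float | None = None,
) -> PerturbationSchedule:
    """Construct a standard perturbation schedule.

    Kinds
    -----
    ``incremental``
        Baseline of zeros, then the delay ramps by ``step_ms`` per trial
        (default 1 ms/trial) up to ``max_delay_ms`` — the experiment's own
        paradigm: 135 baseline trials then delays 1, 2, …, 135 ms.
    ``stationary``
        Baseline of zeros, then ``n_adapt`` trials at the constant
        ``max_delay_ms`` block height.
    ``washout``
        As ``stationary``, followed by ``n_washout`` zero-delay trials.

    Custom delay sequences can be built directly via
    :class:`PerturbationSchedule`.
    """
    if n_baseline < 0 or n_adapt < 0 or n_washout < 0:
        raise ValueError("phase lengths must be >= 0")
    if max_delay_ms < 0:
        raise ValueError("max_delay_ms must be >= 0")

    base = [0.0] * n_baseline
    base_labels = [BASELINE] * n_baseline

    if kind == "incremental":
        if step_ms is None:
            if n_adapt > 0 and n_adapt != max_delay_ms:
                raise ValueError(
                    "incremental schedule at 1 ms/trial requires "
                    "n_adapt == max_delay_ms; pass step_ms to override"
                )
            step_ms = 1.0
        ramp = [min(step_ms * k, max_delay_ms) for k in range(1, n_adapt + 1)]
        delays = base + ramp
        labels = base_labels + [ADAPTATION] * n_adapt
    elif kind == "stationary":
        delays = base + [float(max_delay_ms)] * n_adapt
        labels = base_labels + [ADAPTATION] * n_adapt
    elif kind == "washout":
        delays = base + [float(max_delay_ms)] * n_adapt + [0.0] * n_washout
        labels = base_labels + [ADAPTATION] * n_adapt + [WASHOUT] * n_washout
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")

    if not delays:
        raise ValueError("schedule would be empty")
    return PerturbationSchedule(delays=tuple(delays), phase_labels=tuple(labels))
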