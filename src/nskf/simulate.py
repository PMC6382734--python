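"""Synthetic behavioral sessions from a simulated adapting participant.

Emulates the timing experiment: a ball moves toward a reference line, the
participant presses a button when it arrives, and the sensory consequence
of the press is delayed by a per-trial perturbation schedule.  The
response time (RsT) is the interval between button press and ball
arrival; positive RsT means the press preceded arrival, so adapting to an
imposed delay means producing increasingly positive RsT.

The simulated participant is an NSKF learner (see :mod:`nskf.core`): on
each trial it updates its estimate of the required response lead from the
imposed delay, and its response is that learned lead entering the trial
plus Gaussian motor/execution noise.  Measurement noise shapes *learning*
(through the filter's gain), while the added response scatter comes from
``motor_sd`` alone — the generator separates perception from execution.

Default condition parameters follow the study's fitted per-condition
values: baseline response variance 0.0010 s² (multisensory feedback, MC)
vs 0.0015 s² (unisensory, UC), and measurement-variance growth 1.7e-4 vs
3.7e-4 s² per ms of delay.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import ModelParams, run_filter
from .schedules import PerturbationSchedule, build_schedule

__all__ = [
    "TrialRecord",
    "SessionData",
    "AgentConfig",
    "CONDITION_DEFAULTS",
    "default_agent",
    "generate_session",
    "generate_cohort",
    "session_to_dataframe",
    "session_from_dataframe",
    "write_session_csv",
    "read_session_csv",
]

SPEEDS_CMS = (20.0, 23.0, 26.0)
TTCS_S = (1.0, 1.2, 1.4)

CSV_COLUMNS = [
    "participant",
    "condition",
    "trial",
    "phase",
    "speed_cms",
    "ttc_s",
    "delay_ms",
    "rst_s",
]

#: Study-level generating parameters per feedback condition:
#: (base_meas_var s², delta_meas_var s²·ms⁻¹).
CONDITION_DEFAULTS = {
    "MC": {"base_meas_var": 0.0010, "delta_meas_var": 1.7e-4},
    "UC": {"base_meas_var": 0.0015, "delta_meas_var": 3.7e-4},
}


@dataclass(frozen=True)
class TrialRecord:
    trial: int  # 1-based
    phase: str
    speed: float  # cm/s
    ttc: float  # s
    delay_ms: float
    rst: float  # response time (s); positive = press precedes arrival


@dataclass
class SessionData:
    """All trials of one participant in one feedback condition."""

    participant: str
    condition: str  # "UC" or "MC"
    trials: list[TrialRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def rst(self) -> np.ndarray:
        return np.array([t.rst for t in self.trials])

    @property
    def delays_ms(self) -> np.ndarray:
        return np.array([t.delay_ms for t in self.trials])

    @property
    def phases(self) -> list[str]:
        return [t.phase for t in self.trials]

    def phase_rst(self, phase: str) -> np.ndarray:
        return np.array([t.rst for t in self.trials if t.phase == phase])

    def schedule(self) -> PerturbationSchedule:
        return PerturbationSchedule(
            delays=tuple(t.delay_ms for t in self.trials),
            phase_labels=tuple(t.phase for t in self.trials),
        )


@dataclass(frozen=True)
class AgentConfig:
    """Generative simulated participant: NSKF learner + execution noise."""

    model_params: ModelParams
    motor_sd: float = 0.0316  # s; execution-noise SD added per response
    baseline_bias: float = 0.0  # s; mean RsT with no learned adjustment
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motor_sd < 0:
            raise ValueError("motor_sd must be >= 0")


def default_agent(condition: str, seed: int = 0, **overrides) -> AgentConfig:
    """Agent with the study's per-condition generating parameters.

    ``motor_sd`` defaults to the square root of the condition's baseline
    response variance, so the generated baseline phase reproduces the
    reported baseline variability.
    """
    cond = condition.upper()
    if cond not in CONDITION_DEFAULTS:
        raise ValueError(f"unknown condition {condition!r}; expected UC or MC")
    d = CONDITION_DEFAULTS[cond]
    params = ModelParams(
        base_meas_var=d["base_meas_var"], delta_meas_var=d["delta_meas_var"]
    )
    cfg = AgentConfig(model_params=params, motor_sd=float(np.sqrt(d["base_meas_var"])), seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def generate_session(
    agent: AgentConfig,
    schedule: PerturbationSchedule | None = None,
    condition: str = "MC",
    participant: str = "sim01",
    seed: int | None = None,
) -> SessionData:
    """Simulate one session of the adapting agent on a schedule.

    The response on trial ``t`` is the agent's learned adjustment
    *entering* the trial (the filter's posterior after trial ``t − 1``;
    zero on trial 1) plus ``baseline_bias`` and Gaussian motor noise.
    Feedback from trial ``t`` then updates the learner.  Deterministic
    given the seed (which defaults to ``agent.seed``).
    """
    if schedule is None:
        schedule = build_schedule("incremental")
    rng = np.random.default_rng(agent.seed if seed is None else seed)

    trace = run_filter(agent.model_params, schedule)
    # adjustment entering trial t = posterior after trial t-1
    learned = np.concatenate([[agent.model_params.x0_prior], trace.post_means[:-1]])
    noise = rng.normal(0.0, agent.motor_sd, size=len(schedule))
    rst = agent.baseline_bias + learned + noise

    covariates = _balanced_covariates(len(schedule), rng)
    trials = [
        TrialRecord(
            trial=t + 1,
            phase=schedule.phase_labels[t],
            speed=covariates[t][0],
            ttc=covariates[t][1],
            delay_ms=schedule.delays[t],
            rst=float(rst[t]),
        )
        for t in range(len(schedule))
    ]
    return SessionData(participant=participant, condition=condition, trials=trials)


def generate_cohort(
    n_participants: int = 10,
    conditions: tuple[str, ...] = ("MC", "UC"),
    schedule: PerturbationSchedule | None = None,
    seed: int = 0,
    motor_sd: float | None = None,
) -> list[SessionData]:
    """Simulate a cohort: every participant runs every condition.

    Per-session seeds are drawn from one seeded generator so the cohort
    is reproducible as a whole.  ``motor_sd`` overrides the per-condition
    default (useful for matching execution noise across conditions).
    """
    rng = np.random.default_rng(seed)
    sessions = []
    for i in range(n_participants):
        pid = f"p{i + 1:02d}"
        for cond in conditions:
            s = int(rng.integers(0, 2**31 - 1))
            overrides = {"seed": s}
            if motor_sd is not None:
                overrides["motor_sd"] = motor_sd
            agent = default_agent(cond, **overrides)
            sessions.append(
                generate_session(agent, schedule=schedule, condition=cond, participant=pid)
            )
    return sessions


def _balanced_covariates(n: int, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Speed/TTC pairs in balanced random order over the 9 combinations."""
    combos = list(itertools.product(SPEEDS_CMS, TTCS_S))
    out: list[tuple[float, float]] = []
    while len(out) < n:
        block = [combos[i] for i in rng.permutation(len(combos))]
        out.extend(block)
    return out[:n]


# ---------------------------------------------------------------------------
# CSV interchange: one row per trial, times in seconds, delays integer ms.

def session_to_dataframe(session: SessionData) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant": session.participant,
            "condition": session.condition,
            "trial": [t.trial for t in session.trials],
            "phase": [t.phase for t in session.trials],
            "speed_cms": [t.speed for t in session.trials],
            "ttc_s": [t.ttc for t in session.trials],
            "delay_ms": [t.delay_ms for t in session.trials],
            "rst_s": [t.rst for t in session.trials],
        }
    )


def session_from_dataframe(df: pd.DataFrame) -> SessionData:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"session table is missing columns: {', '.join(missing)}")
    df = df.sort_values("trial")
    trials = [
        TrialRecord(
            trial=int(r.trial),
            phase=str(r.phase),
            speed=float(r.speed_cms),
            ttc=float(r.ttc_s),
            delay_ms=float(r.delay_ms),
            rst=float(r.rst_s),
        )
        for r in df.itertuples()
    ]
    return SessionData(
        participant=str(df["participant"].iloc[0]),
        condition=str(df["condition"].iloc[0]),
        trials=trials,
    )


def write_session_csv(session: SessionData, path) -> None:
    df = session_to_dataframe(session)
    df["delay_ms"] = df["delay_ms"].round().astype(int)
    df["rst_s"] = df["rst_s"].map(lambda v: f"{v:.6f}")
    df.to_csv(path, index=False)


def read_session_csv(path) -> SessionData:
    return session_from_dataframe(pd.read_csv(path))
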