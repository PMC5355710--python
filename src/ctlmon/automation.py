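"""Closed-loop adaptive-automation (AA) simulation.

The simulated system couples three blocks in negative feedback:

* a **data generator** standing in for the operator: given the current
  number of manual tasks n(k), it draws an epoch record (x'(k), y(k)) at
  random from the test session's task-load bin for n(k) (n = 2, absent
  from the sessions, maps to the n = 1 bin),
* the **dynamic load classifier** (a fitted LSSVM2 NARX model) predicting
  performance y~(k) from the drawn features,
* a **controller** turning the tracking error e(k) = r - y~(k), r = 1,
  into a task reallocation Delta-n >= 0 (tasks only move to the machine):

  - *proportional + threshold*: Delta-n = 0 / 1 / 2 for Ke in [0, 0.2) /
    [0.2, 0.8) / otherwise, applied every step;
  - *rule-based*: same thresholds, but any reallocation freezes n for the
    next two steps (30 s), giving the operator time to recover.

A run lasts 90 steps (900 s) over the usual six-block schedule with
15 steps per block; n resets to the scheduled block value at each block
boundary and is clamped to [1, 4] in between.  Summaries (n_MEAN, C_MEAN,
y_MEAN) average the trajectories over steps and (by default 10) seeded runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .narx import CtlNarxResults, OnlinePredictor
from .performance import discretize_performance
from .synthetic import LoadSchedule

SIM_SCHEDULE = LoadSchedule(block_len=15)  # 90 steps of 10 s


@dataclass
class SessionPool:
    """Epoch records of a session binned by task count, sampled with replacement."""

    bins: dict[int, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for n, (X, y) in self.bins.items():
            if len(y) == 0:
                raise ValueError(f"empty bin for task count n = {n}")

    @classmethod
    def from_session(
        cls, features: np.ndarray, y: np.ndarray, schedule: LoadSchedule | None = None
    ) -> "SessionPool":
        if schedule is None:
            schedule = LoadSchedule()
        X = np.asarray(features, float)
        y = np.asarray(y, float).ravel()
        n_per_epoch = schedule.expand()
        if n_per_epoch.size != y.size:
            raise ValueError("schedule length must match the session length")
        bins = {}
        for n in sorted(set(schedule.counts)):
            mask = n_per_epoch == n
            bins[int(n)] = (X[mask], y[mask])
        return cls(bins)

    def draw(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, float]:
        """Random epoch record for task count n; n = 2 maps to the n = 1 bin."""
        if n == 2:
            n = 1
        if n not in self.bins:
            raise ValueError(f"no bin for task count n = {n}")
        X, y = self.bins[n]
        i = int(rng.integers(len(y)))
        return X[i], float(y[i])


@dataclass
class ControllerState:
    """Threshold controller with optional post-reallocation hold."""

    kind: str = "rule"  # "rule" | "prop"
    gain: float = 1.0
    thresholds: tuple[float, float] = (0.2, 0.8)
    hold_steps: int = 2
    hold: int = 0  # steps remaining with n frozen

    def reset(self) -> None:
        self.hold = 0

    def step(self, e: float) -> int:
        """Task increment Delta-n >= 0 for tracking error e (clamped to [0, 1])."""
        if self.kind not in ("rule", "prop"):
            raise ValueError(f"unknown controller kind {self.kind!r}")
        if self.kind == "rule" and self.hold > 0:
            self.hold -= 1
            return 0
        ke = self.gain * min(max(e, 0.0), 1.0)
        lo, hi = self.thresholds
        if ke < lo:
            dn = 0
        elif ke < hi:
            dn = 1
        else:
            dn = 2
        if self.kind == "rule" and dn > 0:
            self.hold = self.hold_steps
        return dn


def proportional_threshold_control(e: float, state: ControllerState | None = None) -> int:
    """Delta-n of the proportional + threshold law (stateless)."""
    if state is None:
        state = ControllerState(kind="prop")
    state.kind = "prop"
    return state.step(e)


def rule_based_control(e: float, state: ControllerState) -> tuple[int, ControllerState]:
    """Delta-n of the rule-based law; mutates and returns the hold state."""
    state.kind = "rule"
    return state.step(e), state


@dataclass
class SimulationResult:
    """Per-run trajectories (runs x steps) and run-averaged summaries."""

    n: np.ndarray
    y: np.ndarray  # measured performance drawn by the generator
    y_hat: np.ndarray  # classifier prediction
    C_hat: np.ndarray  # predicted load class
    controller: str | None

    @property
    def n_mean(self) -> float:
        return float(self.n.mean())

    @property
    def c_mean(self) -> float:
        return float(self.C_hat.mean())

    @property
    def y_mean(self) -> float:
        return float(self.y.mean())

    @property
    def n_change_count(self) -> float:
        """Average number of steps per run where n changes."""
        return float((np.diff(self.n, axis=1) != 0).sum(axis=1).mean())

    def summaries(self) -> dict[str, float]:
        return {"n_mean": self.n_mean, "c_mean": self.c_mean, "y_mean": self.y_mean}


def summarize(result: SimulationResult) -> tuple[float, float, float]:
    """(n_MEAN, C_MEAN, y_MEAN) averaged over all steps and runs."""
    return result.n_mean, result.c_mean, result.y_mean


def run_simulation(
    pool: SessionPool,
    results: CtlNarxResults,
    controller: str | None = "rule",
    sigma_o: float = 0.15,
    z: tuple[float, float, float] = (2.3, 2.7, 3.0),
    steps: int = 90,
    runs: int = 10,
    seed: int = 0,
    schedule: LoadSchedule | None = None,
    gain: float = 1.0,
    thresholds: tuple[float, float] = (0.2, 0.8),
) -> SimulationResult:
    """Simulate the closed loop; ``controller=None`` gives the without-AA runs.

    Run i uses the child seed ``seed + i``.  Within each 15-step block the
    controller can only remove tasks (n non-increasing, clamped to >= 1);
    block boundaries reset n to the scheduled value and clear any hold.
    """
    if schedule is None:
        schedule = LoadSchedule(block_len=max(1, steps // 6))
    sched = schedule.expand()[:steps]
    if sched.size < steps:
        raise ValueError("schedule shorter than the requested number of steps")
    n_traj = np.empty((runs, steps), dtype=int)
    y_traj = np.empty((runs, steps))
    yhat_traj = np.empty((runs, steps))
    chat_traj = np.empty((runs, steps), dtype=int)
    block_len = schedule.block_len
    for run in range(runs):
        rng = np.random.default_rng(seed + run)
        predictor = OnlinePredictor(results)
        state = ControllerState(kind=controller or "prop", gain=gain, thresholds=thresholds)
        n_prev = int(sched[0])
        y_prev_meas: float | None = None
        for k in range(steps):
            if k % block_len == 0:
                n_k = int(sched[k])
                state.reset()
            elif controller is None:
                n_k = int(sched[k])
            else:
                e = 1.0 - yhat_traj[run, k - 1]
                dn = state.step(e)
                n_k = max(1, min(4, n_prev - dn))
            x_k, y_k = pool.draw(n_k, rng)
            y_hat = predictor.step(x_k, y_prev_meas)
            n_traj[run, k] = n_k
            y_traj[run, k] = y_k
            yhat_traj[run, k] = y_hat
            chat_traj[run, k] = discretize_performance(float(y_hat), sigma_o, z)
            y_prev_meas = y_k
            n_prev = n_k
    return SimulationResult(n_traj, y_traj, yhat_traj, chat_traj, controller)
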