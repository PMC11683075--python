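"""Named conditions, replicate execution, and behavioural metrics.

Intake-task metrics (per 100-step episode): average reward per intake (on
the perceived reward scale the agent learns from), summed punishment and
summed drive (on the objective eta = 1 scale: what the body sustains), and
total intake count.  Mountain-task metrics (per 15-episode trial): S7-rate
(fraction of timesteps spent at the summit), total timesteps, and the number
of small bottom-state intakes.

A condition is the control configuration with one or two parameters moved:
interoceptive gain eta (0.3 blunted / 1.7 exaggerated), inverse temperature
beta (quartered), or discount gamma (0.2 vs 0.9).  ``run_condition`` runs
independent replicates (fresh agent, seed = base_seed + i) and assembles one
metric row per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agent import AgentState
from .config import CONDITION_VALUES, DEFAULTS, RunConfig, resolve_config
from .tasks import Trajectory, run_episode, run_trial

__all__ = [
    "Condition",
    "ConditionResult",
    "avg_reward_per_intake",
    "sum_punishment",
    "sum_drive",
    "total_intake",
    "s7_rate",
    "total_timesteps",
    "a00_timesteps",
    "paper_conditions",
    "run_condition",
    "run_replicate",
]

INTAKE_METRICS = ("avg_reward_per_intake", "sum_punishment", "sum_drive", "total_intake")
MOUNTAIN_METRICS = ("s7_rate", "total_timesteps", "a00_timesteps")


# -- metrics ---------------------------------------------------------------

def avg_reward_per_intake(traj: Trajectory, intake_action: str = "intake") -> float:
    """Total reward earned on intake steps divided by the number of intakes.

    Uses the perceived (eta-modulated) reward: this metric characterises the
    activity of the reward signal itself.  Returns NaN when the trajectory
    contains no intake at all.
    """
    rewards = [t.reward for t in traj if t.action == intake_action]
    if not rewards:
        return float("nan")
    return float(np.mean(rewards))


def sum_punishment(traj: Trajectory) -> float:
    """Total punishment sustained in the episode, sum_t max(0, -r_t) >= 0.

    Measured on the objective (eta = 1) reward scale: the interoceptive gain
    shapes the learning signal, but the punishment an agent actually incurs
    is the increase in its objective drive.
    """
    r = traj.objective_rewards
    return float(np.sum(np.maximum(0.0, -r))) if len(r) else 0.0


def sum_drive(traj: Trajectory) -> float:
    """Sum of the pre-action objective (eta = 1) drive over all timesteps.

    This is the body's accumulated homeostatic deficit, independent of how
    strongly the deficit is perceived.
    """
    return float(traj.objective_drives.sum()) if len(traj) else 0.0


def total_intake(traj: Trajectory, intake_action: str = "intake") -> int:
    """Number of intake actions in the episode."""
    return sum(1 for t in traj if t.action == intake_action)


def _trial_steps(trial: list[Trajectory]):
    for traj in trial:
        yield from traj


def s7_rate(trial: list[Trajectory]) -> float:
    """Fraction of a trial's timesteps whose pre-action state is the summit."""
    total = 0
    summit = 0
    for t in _trial_steps(trial):
        total += 1
        summit += t.state == "S7"
    return summit / total if total else float("nan")


def total_timesteps(trial: list[Trajectory]) -> int:
    """Sum of per-episode lengths over the trial."""
    return sum(len(traj) for traj in trial)


def a00_timesteps(trial: list[Trajectory]) -> int:
    """Number of small bottom-state intakes over the trial."""
    return sum(1 for t in _trial_steps(trial) if t.action == "small_intake")


# -- conditions ------------------------------------------------------------

@dataclass(frozen=True)
class Condition:
    """A named manipulation of the control configuration."""

    name: str
    task: str                              # "intake" or "mountain"
    space_overrides: dict = field(default_factory=dict)
    agent_overrides: dict = field(default_factory=dict)
    n_replicates: int | None = None        # None -> task default
    base_seed: int = 0

    def config(self) -> RunConfig:
        overrides: dict = {}
        if self.space_overrides:
            overrides["homeostat"] = dict(self.space_overrides)
        if self.agent_overrides:
            overrides["agent"] = dict(self.agent_overrides)
        exp: dict = {"base_seed": self.base_seed}
        if self.n_replicates is not None:
            exp["n_replicates"] = self.n_replicates
        overrides["experiment"] = exp
        return resolve_config(self.task, overrides)


def paper_conditions(task: str, base_seed: int = 0,
                     n_replicates: int | None = None) -> dict[str, Condition]:
    """The five canonical conditions: control, low/high eta, low beta, low gamma."""
    control_beta = DEFAULTS[task]["agent"]["beta"]
    low_beta = control_beta * CONDITION_VALUES["low_beta_factor"]
    make = lambda name, space=None, agent=None: Condition(
        name=name, task=task,
        space_overrides=space or {}, agent_overrides=agent or {},
        n_replicates=n_replicates, base_seed=base_seed,
    )
    return {
        "control": make("control"),
        "low_eta": make("low_eta", space=dict(CONDITION_VALUES["low_eta"])),
        "high_eta": make("high_eta", space=dict(CONDITION_VALUES["high_eta"])),
        "low_beta": make("low_beta", agent={"beta": low_beta}),
        "low_gamma": make("low_gamma", agent=dict(CONDITION_VALUES["low_gamma"])),
    }


@dataclass
class ConditionResult:
    """Per-replicate metric vectors for one condition."""

    condition: Condition
    metrics: pd.DataFrame        # one row per replicate, indexed by seed
    n_censored: int = 0

    def vector(self, metric: str, dropna: bool = False) -> np.ndarray:
        v = self.metrics[metric].to_numpy(dtype=float)
        return v[~np.isnan(v)] if dropna else v

    def summary(self) -> dict:
        out = {"condition": self.condition.name, "n": len(self.metrics),
               "n_censored": self.n_censored}
        for col in self.metrics.columns:
            if col in ("seed", "replicate"):
                continue
            v = self.vector(col, dropna=True)
            out[col] = {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)),
                        "n": int(len(v))}
        return out


def run_replicate(config: RunConfig, seed: int,
                  space_overrides: dict | None = None,
                  agent_overrides: dict | None = None):
    """One fresh agent through one episode (intake) or one trial (mountain).

    Returns ``(trajectories, agent)``; the intake task yields a single
    trajectory in the list.
    """
    space = config.space(**(space_overrides or {}))
    params = config.agent_params(**(agent_overrides or {}))
    task = config.task()
    agent = AgentState.for_task(task)
    rng = np.random.default_rng(seed)
    if config.task_name == "intake":
        traj, agent = run_episode(task, space, params, agent, rng)
        return [traj], agent
    return run_trial(task, space, params, agent, rng, n_episodes=config.n_episodes)


def run_condition(cond: Condition, n_replicates: int | None = None,
                  base_seed: int | None = None) -> ConditionResult:
    """Run all replicates of a condition and collect the metric table.

    Replicate i uses seed ``base_seed + i`` with a fresh agent and
    environment; metric vectors therefore are independent samples.
    """
    config = cond.config()
    n = n_replicates if n_replicates is not None else config.n_replicates
    seed0 = base_seed if base_seed is not None else config.base_seed
    if n < 2:
        raise ValueError(f"need at least 2 replicates, got {n}")

    rows = []
    n_censored = 0
    for i in range(n):
        seed = seed0 + i
        try:
            trial, agent = run_replicate(config, seed)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"condition {cond.name!r} failed at seed {seed}") from exc
        row: dict = {"replicate": i, "seed": seed}
        if cond.task == "intake":
            traj = trial[0]
            row["avg_reward_per_intake"] = avg_reward_per_intake(traj)
            row["sum_punishment"] = sum_punishment(traj)
            row["sum_drive"] = sum_drive(traj)
            row["total_intake"] = total_intake(traj)
        else:
            row["s7_rate"] = s7_rate(trial)
            row["total_timesteps"] = total_timesteps(trial)
            row["a00_timesteps"] = a00_timesteps(trial)
            row["n_censored_episodes"] = sum(t.censored for t in trial)
            n_censored += sum(t.censored for t in trial)
        rows.append(row)
    return ConditionResult(condition=cond, metrics=pd.DataFrame(rows),
                           n_censored=n_censored)
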