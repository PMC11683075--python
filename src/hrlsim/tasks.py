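"""The two decision environments and the simulation loop.

* Intake-after-food-restriction: a single external state ``S0`` with two
  actions, ``do_nothing`` (K = 0) and ``intake`` (K = K_intake), run for a
  fixed horizon starting from a nutrient deficit (H_0 = 100 against a
  setpoint of 200).  Characterises feeding under deprivation.

* Mountain-climbing: eight states ``S0``..``S7``.  At the bottom the agent
  can take a small immediate intake or start moving; climbing S1..S6 costs a
  fixed nutrient amount per step (an immediate punishment); the summit S7
  offers a large intake that ends the episode.  Probes the balance between
  small immediate and large delayed rewards.

``run_episode`` implements the learning loop: softmax choice from Q, reward
from the *predicted* intake K̂ (including the action's climb cost), actual
state transition, TD update of Q, delta-rule update of K̂.  ``run_trial``
chains episodes with Q and K̂ carried over while the external and internal
states reset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agent import (
    AgentParams,
    AgentState,
    action_probabilities,
    select_action,
    td_error,
    update_k_hat,
    update_q,
)
from .homeostat import HomeostaticSpace, drive, next_internal, reward

__all__ = [
    "TaskSpec",
    "Transition",
    "Trajectory",
    "build_intake_task",
    "build_mountain_task",
    "run_episode",
    "run_trial",
    "trajectory_frame",
    "write_trajectory_csv",
]


@dataclass(frozen=True)
class TaskSpec:
    """Explicit state/action/transition/intake/cost specification."""

    name: str
    states: tuple
    actions_of: dict          # state -> ordered tuple of action ids
    next_state: dict          # (state, action) -> state
    intake_of: dict           # (state, action) -> actual intake K >= 0
    cost_of: dict             # (state, action) -> climb cost >= 0
    terminal: frozenset       # (state, action) pairs ending an episode
    initial_state: str
    initial_H: float = 100.0
    episode_length: int | None = None   # fixed horizon (intake task)
    step_cap: int | None = None         # censoring cap (mountain task)

    def __post_init__(self) -> None:
        if self.initial_state not in self.states:
            raise ValueError(f"initial state {self.initial_state!r} not in states")
        for s in self.states:
            for a in self.actions_of[s]:
                key = (s, a)
                for table, label in (
                    (self.next_state, "next_state"),
                    (self.intake_of, "intake_of"),
                    (self.cost_of, "cost_of"),
                ):
                    if key not in table:
                        raise ValueError(f"{label} missing entry for {key}")
                if self.intake_of[key] < 0 or self.cost_of[key] < 0:
                    raise ValueError(f"negative intake or cost at {key}")

    def pairs(self):
        """All (state, action) pairs, in state order then action order."""
        return [(s, a) for s in self.states for a in self.actions_of[s]]


@dataclass(frozen=True)
class Transition:
    """One timestep of a trajectory.

    ``reward`` and ``drive_*`` are on the agent's perceived scale (they
    include the interoceptive gain eta and are what learning sees);
    ``reward_objective`` and ``drive_objective_before`` are the same
    quantities on the objective scale (eta = 1), i.e. the body's actual
    drive change, which is what outcome metrics are measured on.
    """

    state: str
    action: str
    next_state: str
    H_before: float
    H_after: float
    reward: float
    drive_before: float
    drive_after: float
    reward_objective: float
    drive_objective_before: float
    action_probabilities: tuple
    episode_index: int
    timestep: int


@dataclass
class Trajectory:
    """Per-timestep record of one episode; ``censored`` marks a step-cap hit."""

    transitions: list = field(default_factory=list)
    episode_index: int = 0
    censored: bool = False

    def __len__(self) -> int:
        return len(self.transitions)

    def __iter__(self):
        return iter(self.transitions)

    @property
    def rewards(self) -> np.ndarray:
        return np.array([t.reward for t in self.transitions])

    @property
    def drives(self) -> np.ndarray:
        return np.array([t.drive_before for t in self.transitions])

    @property
    def objective_rewards(self) -> np.ndarray:
        return np.array([t.reward_objective for t in self.transitions])

    @property
    def objective_drives(self) -> np.ndarray:
        return np.array([t.drive_objective_before for t in self.transitions])

    @property
    def H(self) -> np.ndarray:
        """Internal state before each step, plus the final post-step state."""
        if not self.transitions:
            return np.array([])
        return np.array(
            [t.H_before for t in self.transitions] + [self.transitions[-1].H_after]
        )


def build_intake_task(k_intake: float = 40.0, episode_length: int = 100,
                      initial_H: float = 100.0) -> TaskSpec:
    """One state, two actions (do nothing / intake), fixed-horizon episode."""
    if k_intake <= 0:
        raise ValueError(f"k_intake must be > 0, got {k_intake}")
    if episode_length <= 0:
        raise ValueError(f"episode_length must be > 0, got {episode_length}")
    actions = ("do_nothing", "intake")
    return TaskSpec(
        name="intake",
        states=("S0",),
        actions_of={"S0": actions},
        next_state={("S0", a): "S0" for a in actions},
        intake_of={("S0", "do_nothing"): 0.0, ("S0", "intake"): float(k_intake)},
        cost_of={("S0", a): 0.0 for a in actions},
        terminal=frozenset(),
        initial_state="S0",
        initial_H=initial_H,
        episode_length=int(episode_length),
    )


def build_mountain_task(k_small: float = 20.0, k_large: float = 120.0,
                        climb_cost: float = 10.0, step_cap: int = 5000,
                        initial_H: float = 100.0) -> TaskSpec:
    """Eight-state chain with a small intake at the bottom and a large,
    episode-ending intake at the summit; climbing costs nutrient.

    Exactly two actions per state: S0 = {small_intake (self-loop), move ->
    S1}; S1 = {climb -> S2 (costly), move -> S0}; S2..S6 = {climb (costly),
    descend}; S7 = {large_intake (terminal, -> S0), descend -> S6}.  The
    summit intake is labelled a^70 / a71 ("major feeding") in the source
    literature; canonical id here is ``large_intake``.
    """
    if step_cap <= 0:
        raise ValueError(f"step_cap must be > 0, got {step_cap}")
    if k_small <= 0 or k_large <= 0:
        raise ValueError("intake amounts must be > 0")
    if climb_cost < 0:
        raise ValueError("climb_cost must be >= 0")

    states = tuple(f"S{i}" for i in range(8))
    actions_of = {
        "S0": ("small_intake", "move"),
        "S1": ("climb", "move"),
        "S7": ("large_intake", "descend"),
    }
    for i in range(2, 7):
        actions_of[f"S{i}"] = ("climb", "descend")

    next_state = {
        ("S0", "small_intake"): "S0",
        ("S0", "move"): "S1",
        ("S1", "climb"): "S2",
        ("S1", "move"): "S0",
        ("S7", "large_intake"): "S0",
        ("S7", "descend"): "S6",
    }
    for i in range(2, 7):
        next_state[(f"S{i}", "climb")] = f"S{i + 1}"
        next_state[(f"S{i}", "descend")] = f"S{i - 1}"

    intake_of = {key: 0.0 for key in next_state}
    intake_of[("S0", "small_intake")] = float(k_small)
    intake_of[("S7", "large_intake")] = float(k_large)

    cost_of = {key: 0.0 for key in next_state}
    for i in range(1, 7):
        cost_of[(f"S{i}", "climb")] = float(climb_cost)

    return TaskSpec(
        name="mountain",
        states=states,
        actions_of=actions_of,
        next_state=next_state,
        intake_of=intake_of,
        cost_of=cost_of,
        terminal=frozenset({("S7", "large_intake")}),
        initial_state="S0",
        initial_H=initial_H,
        step_cap=int(step_cap),
    )


def run_episode(task: TaskSpec, space: HomeostaticSpace, params: AgentParams,
                agent: AgentState, rng: np.random.Generator,
                episode_index: int = 0) -> tuple[Trajectory, AgentState]:
    """Run one episode, updating the agent in place and recording every step.

    The episode ends when a terminal (state, action) fires, when the fixed
    horizon is reached, or when the step cap is hit (recorded as censoring,
    not an error).  Terminal transitions bootstrap from the initial state of
    the next episode because values are carried over across episodes.
    """
    traj = Trajectory(episode_index=episode_index)
    s = task.initial_state
    H = np.atleast_1d(np.asarray(task.initial_H, dtype=float))
    limit = task.episode_length if task.episode_length is not None else task.step_cap
    if limit is None:
        raise ValueError("task must define episode_length or step_cap")
    # objective (eta = 1) copy of the space, used only for outcome recording
    space_obj = space if space.eta == 1.0 else space.replace(eta=1.0)

    for t in range(limit):
        actions = task.actions_of[s]
        probs = action_probabilities(agent.q_values(s, actions), params.beta)
        a = actions[select_action(probs, rng)]
        key = (s, a)

        k_hat = agent.k_hat[key]
        cost = task.cost_of[key]
        r = reward(H, k_hat, cost, space)
        r_obj = r if space_obj is space else reward(H, k_hat, cost, space_obj)

        H_next = next_internal(H, task.intake_of[key], cost, space)
        s_next = task.next_state[key]
        is_terminal = key in task.terminal

        # values persist across episodes, so the terminal transition
        # bootstraps from the next episode's start state
        bootstrap_state = task.initial_state if is_terminal else s_next
        max_next = agent.max_q(bootstrap_state, task.actions_of[bootstrap_state])
        delta = td_error(r, params.gamma, max_next, agent.q[key])
        update_q(s, a, delta, params, agent)
        update_k_hat(s, a, task.intake_of[key], params, agent)

        d_before = drive(H, space)
        traj.transitions.append(Transition(
            state=s, action=a, next_state=s_next,
            H_before=float(H[0]), H_after=float(H_next[0]),
            reward=r,
            drive_before=d_before, drive_after=drive(H_next, space),
            reward_objective=r_obj,
            drive_objective_before=(d_before if space_obj is space
                                    else drive(H, space_obj)),
            action_probabilities=tuple(probs),
            episode_index=episode_index, timestep=t,
        ))

        H = H_next
        s = s_next
        if is_terminal:
            return traj, agent

    if task.step_cap is not None and task.terminal:
        traj.censored = True
    return traj, agent


def run_trial(task: TaskSpec, space: HomeostaticSpace, params: AgentParams,
              agent: AgentState, rng: np.random.Generator,
              n_episodes: int = 15) -> tuple[list[Trajectory], AgentState]:
    """Run ``n_episodes`` back-to-back episodes.

    The external state resets to the initial state and the internal state to
    its initial value at each episode start; Q and K̂ carry over.
    """
    if n_episodes < 1:
        raise ValueError(f"n_episodes must be >= 1, got {n_episodes}")
    trajectories = []
    for ep in range(n_episodes):
        traj, agent = run_episode(task, space, params, agent, rng, episode_index=ep)
        trajectories.append(traj)
    return trajectories, agent


def trajectory_frame(trajectories, trial: int = 0) -> pd.DataFrame:
    """Flatten trajectories into one row per timestep."""
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    rows = []
    for traj in trajectories:
        for tr in traj:
            row = {
                "trial": trial,
                "episode": tr.episode_index,
                "t": tr.timestep,
                "state": tr.state,
                "action": tr.action,
                "next_state": tr.next_state,
                "H_before": tr.H_before,
                "H_after": tr.H_after,
                "reward": tr.reward,
                "drive": tr.drive_before,
                "reward_objective": tr.reward_objective,
                "drive_objective": tr.drive_objective_before,
                "censored": traj.censored,
            }
            for i, p in enumerate(tr.action_probabilities):
                row[f"p_action{i}"] = p
            rows.append(row)
    return pd.DataFrame(rows)


def write_trajectory_csv(path, trajectories, trial: int = 0) -> None:
    trajectory_frame(trajectories, trial=trial).to_csv(path, index=False)
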