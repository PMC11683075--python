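"""Tabular Q-learning agent with softmax policy and learned intake prediction.

State-action values Q(s, a) are updated from the temporal-difference error

    delta = r + gamma * max_a' Q(s', a') - Q(s, a)
    Q(s, a) <- Q(s, a) + alpha_q * delta

and actions are drawn from the softmax policy P(a) ∝ exp(beta * Q(s, a)).
A second table K̂(s, a) learns, by a delta rule with rate alpha_k, the amount
of nutrient each action actually delivers; this prediction (not the actual
amount) enters the drive-reduction reward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AgentParams",
    "AgentState",
    "action_probabilities",
    "select_action",
    "td_error",
    "update_q",
    "update_k_hat",
]


@dataclass(frozen=True)
class AgentParams:
    """Learning parameters of the agent.

    alpha_q : learning rate for Q, in [0, 1] (0 disables Q learning).
    alpha_k : learning rate for the intake prediction K̂, in [0, 1]
              (0 freezes the prediction).
    beta    : softmax inverse temperature, >= 0.  Drives span ~|H*-H|^m
              (order 1e6 at the default deficit), so useful betas are small.
    gamma   : discount rate, in [0, 1].
    """

    alpha_q: float = 0.1
    alpha_k: float = 0.5
    beta: float = 1e-5
    gamma: float = 0.9

    def __post_init__(self) -> None:
        if not (0 <= self.alpha_q <= 1):
            raise ValueError(f"alpha_q must be in [0, 1], got {self.alpha_q}")
        if not (0 <= self.alpha_k <= 1):
            raise ValueError(f"alpha_k must be in [0, 1], got {self.alpha_k}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not (0 <= self.gamma <= 1):
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")

    def replace(self, **kwargs) -> "AgentParams":
        current = {
            "alpha_q": self.alpha_q,
            "alpha_k": self.alpha_k,
            "beta": self.beta,
            "gamma": self.gamma,
        }
        current.update(kwargs)
        return AgentParams(**current)


@dataclass
class AgentState:
    """Q and K̂ tables, keyed by (external state, action).

    Both tables start at zero: zero Q-values make the first choices random,
    and zero K̂ makes the first reward estimate conservative.
    """

    q: dict = field(default_factory=dict)
    k_hat: dict = field(default_factory=dict)

    @classmethod
    def for_task(cls, task) -> "AgentState":
        """Zero-initialised tables covering every (state, action) of a task."""
        q = {}
        k_hat = {}
        for s in task.states:
            for a in task.actions_of[s]:
                q[(s, a)] = 0.0
                k_hat[(s, a)] = 0.0
        return cls(q=q, k_hat=k_hat)

    def q_values(self, state, actions) -> np.ndarray:
        return np.array([self.q[(state, a)] for a in actions])

    def max_q(self, state, actions) -> float:
        return max(self.q[(state, a)] for a in actions)

    def copy(self) -> "AgentState":
        return AgentState(q=dict(self.q), k_hat=dict(self.k_hat))


def action_probabilities(q_values, beta: float) -> np.ndarray:
    """Softmax policy P(a_k) = exp(beta q_k) / sum_j exp(beta q_j).

    Shift-invariant (computed with max subtraction for overflow safety);
    beta = 0 gives the uniform distribution.
    """
    q = np.asarray(q_values, dtype=float)
    if q.size == 0:
        raise ValueError("q_values must be non-empty")
    if not np.all(np.isfinite(q)):
        raise ValueError("q_values must be finite")
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    z = beta * q
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def select_action(probs, rng: np.random.Generator) -> int:
    """Draw an action index from a probability vector, reproducibly."""
    p = np.asarray(probs, dtype=float)
    if p.size == 0:
        raise ValueError("probability vector must be non-empty")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"not a probability distribution: {p}")
    # inverse-CDF draw: one uniform per decision keeps the stream compact
    u = rng.random()
    return int(np.searchsorted(np.cumsum(p), u, side="right").clip(0, p.size - 1))


def td_error(r: float, gamma: float, max_next_q: float, current_q: float) -> float:
    """Temporal-difference error delta = r + gamma * max_a' Q(a') - Q(a)."""
    return r + gamma * max_next_q - current_q


def update_q(state, action, delta: float, params: AgentParams, agent: AgentState) -> AgentState:
    """In-place Q update Q(s, a) <- Q(s, a) + alpha_q * delta; returns agent."""
    key = (state, action)
    if key not in agent.q:
        raise KeyError(f"unknown (state, action) pair {key}")
    agent.q[key] += params.alpha_q * delta
    return agent


def update_k_hat(state, action, actual_k: float, params: AgentParams, agent: AgentState) -> AgentState:
    """Delta-rule intake-prediction update K̂ <- K̂ + alpha_k (K - K̂)."""
    key = (state, action)
    if key not in agent.k_hat:
        raise KeyError(f"unknown (state, action) pair {key}")
    agent.k_hat[key] += params.alpha_k * (actual_k - agent.k_hat[key])
    return agent
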