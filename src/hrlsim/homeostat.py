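"""Homeostatic space: drive, interoceptive gain, decay, and drive-reduction reward.

The homeostatic space is a metric space whose axes are internal physiological
variables (here, a nutrient level).  The drive ``D(H)`` measures the distance
of the current internal state ``H`` from the ideal setpoint ``H*``:

    D(H) = ( sum_i  eta * |H*_i - H_i|**n ) ** (m / n)

with free exponents ``(m, n)`` shaping the space (default ``(3, 4)``) and a
non-negative interoceptive gain ``eta`` scaling the perceived deviation from
the setpoint.  ``eta = 1`` is the unmodulated drive; ``eta < 1`` models
blunted interoception, ``eta > 1`` exaggerated interoception.  The reward of
an action is the drive reduction it is predicted to produce, so behaviour
that restores homeostasis is what maximises reward.

All functions here are pure; the agent and task layers compose them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HomeostaticSpace",
    "drive",
    "decay",
    "next_internal",
    "reward",
]


def _as_state(H) -> np.ndarray:
    """Coerce a scalar or sequence internal state to a 1-D float array."""
    arr = np.atleast_1d(np.asarray(H, dtype=float))
    if arr.ndim != 1:
        raise ValueError(f"internal state must be scalar or 1-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("internal state must be finite")
    return arr


@dataclass(frozen=True)
class HomeostaticSpace:
    """Parameters of the homeostatic space.

    Parameters
    ----------
    setpoint:
        Ideal internal state ``H*`` (nutrient units); scalar or length-N
        vector, one entry per internal-state dimension.
    m, n:
        Positive exponents defining the distance metric.  The default
        ``(3, 4)`` is the standard choice in homeostatic reinforcement
        learning models.
    eta:
        Interoceptive gain, ``eta >= 0``.  Multiplies the n-th-power
        deviation term inside the sum; ``eta = 1`` leaves the drive
        unmodulated.
    tau:
        Decay constant (dimensionless timesteps, ``tau > 1``) of the natural
        per-step loss of nutrient: ``H -> (1 - 1/tau) H``.
    """

    setpoint: np.ndarray = field(default_factory=lambda: np.array([200.0]))
    m: float = 3.0
    n: float = 4.0
    eta: float = 1.0
    tau: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "setpoint", _as_state(self.setpoint))
        if self.setpoint.size < 1:
            raise ValueError("setpoint must have at least one dimension")
        if not (self.m > 0 and self.n > 0):
            raise ValueError(f"exponents must be positive, got m={self.m}, n={self.n}")
        if self.eta < 0:
            raise ValueError(f"interoceptive gain eta must be >= 0, got {self.eta}")
        if not self.tau > 1:
            raise ValueError(f"decay constant tau must be > 1, got {self.tau}")

    @property
    def ndim(self) -> int:
        return self.setpoint.size

    def replace(self, **kwargs) -> "HomeostaticSpace":
        """Return a copy with some parameters overridden."""
        current = {
            "setpoint": self.setpoint,
            "m": self.m,
            "n": self.n,
            "eta": self.eta,
            "tau": self.tau,
        }
        current.update(kwargs)
        return HomeostaticSpace(**current)


def _check_dims(H: np.ndarray, space: HomeostaticSpace) -> None:
    if H.size != space.ndim:
        raise ValueError(
            f"internal state has {H.size} dimension(s), space expects {space.ndim}"
        )


def drive(H, space: HomeostaticSpace) -> float:
    """Interoception-modulated drive D(H) = (sum_i eta*|H*_i - H_i|^n)^(m/n).

    Non-negative; zero iff ``H`` equals the setpoint (for ``eta > 0``);
    strictly increasing in each ``|H*_i - H_i|``.
    """
    H = _as_state(H)
    _check_dims(H, space)
    total = float(np.sum(space.eta * np.abs(space.setpoint - H) ** space.n))
    return total ** (space.m / space.n)


def decay(H, space: HomeostaticSpace) -> np.ndarray:
    """Natural nutrient loss over one timestep: H -> (1 - 1/tau) H."""
    H = _as_state(H)
    _check_dims(H, space)
    return (1.0 - 1.0 / space.tau) * H


def next_internal(H, K: float, cost: float, space: HomeostaticSpace) -> np.ndarray:
    """One-step internal-state transition: decay, then intake, then climb cost.

    ``H' = (1 - 1/tau) H + K - cost``.  Intake ``K`` and cost are applied
    after the decay so that a fixed cost is independent of ``tau``.  The
    state is not clamped; the equations impose no bounds and clamping would
    distort drive gradients.
    """
    H = _as_state(H)
    _check_dims(H, space)
    if K < 0:
        raise ValueError(f"intake K must be >= 0, got {K}")
    if cost < 0:
        raise ValueError(f"cost must be >= 0, got {cost}")
    return decay(H, space) + K - cost

def reward(H, K_hat: float, cost: float, space: HomeostaticSpace) -> float:
    """Drive-reduction reward r = D(H) - D((1 - 1/tau) H + K_hat - cost).

    The *predicted* intake ``K_hat`` (the agent's learned estimate of the
    nutrient an action delivers) enters the reward, while the actual intake
    drives the state transition.  For climb actions the cost is part of the
    predicted next state, so the nutrient loss of climbing is priced as a
    punishment (``r < 0``).
    """
    H = _as_state(H)
    predicted = decay(H, space) + K_hat - cost
    return drive(H, space) - drive(predicted, space)
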