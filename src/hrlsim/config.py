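"""Run configuration: defaults, validation, YAML round-trip.

All free parameters of the simulator live here.  The defaults were chosen so
that the control agent shows the canonical homeostatic pattern in the intake
task (convergence to the setpoint within the 100-step horizon, then
alternation of intake and doing nothing) and learns the summit route of the
mountain task within a 15-episode trial; everything is overridable.  The
two tasks use different free-parameter sets so that mountain trials converge
within a reasonable number of timesteps; docs/methods.md discusses the
calibration in detail.

Because the drive scales like |H* - H|^m (order 1e6 at the initial deficit
with the default exponents), useful softmax inverse temperatures are small
(order 1e-5 in the intake task, 1e-6 in the mountain task).
"""

from __future__ import annotations

import copy

import yaml

from .agent import AgentParams
from .homeostat import HomeostaticSpace
from .tasks import TaskSpec, build_intake_task, build_mountain_task

__all__ = [
    "DEFAULTS",
    "CONDITION_VALUES",
    "RunConfig",
    "resolve_config",
    "load_config",
]

# per-task defaults; the two tasks use different free parameters so that a
# mountain trial converges within a rational number of timesteps
DEFAULTS: dict = {
    "intake": {
        "homeostat": {"setpoint": 200.0, "m": 3.0, "n": 4.0, "eta": 1.0, "tau": 14.0},
        "agent": {"alpha_q": 0.05, "alpha_k": 0.5, "beta": 3.5e-5, "gamma": 0.9},
        "task": {"k_intake": 16.0, "episode_length": 100, "initial_H": 100.0},
        "experiment": {"n_replicates": 40, "base_seed": 0},
    },
    "mountain": {
        "homeostat": {"setpoint": 200.0, "m": 3.0, "n": 4.0, "eta": 1.0, "tau": 100.0},
        "agent": {"alpha_q": 0.5, "alpha_k": 0.05, "beta": 1.5e-6, "gamma": 0.95},
        "task": {
            "k_small": 0.8,
            "k_large": 110.0,
            "climb_cost": 0.3,
            "step_cap": 5000,
            "n_episodes": 15,
            "initial_H": 100.0,
        },
        "experiment": {"n_replicates": 30, "base_seed": 0},
    },
}

# manipulated-parameter values for the named conditions; eta is bounded in
# (0, 2) in the interoception sweep, low beta is a quarter of control
CONDITION_VALUES: dict = {
    "low_eta": {"eta": 0.3},
    "high_eta": {"eta": 1.7},
    "low_beta_factor": 0.25,
    "low_gamma": {"gamma": 0.2},
}


def _validate_section(section: dict, defaults: dict, path: str) -> dict:
    unknown = set(section) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config key(s) under {path}: {sorted(unknown)}")
    merged = dict(defaults)
    merged.update(section)
    return merged


class RunConfig:
    """A fully-resolved configuration for one task.

    Construct with :func:`resolve_config`; the resolved form (defaults plus
    overrides) is what gets echoed into output directories so that every run
    is reproducible from its artifacts alone.
    """

    SECTIONS = ("homeostat", "agent", "task", "experiment")

    def __init__(self, task_name: str, sections: dict):
        if task_name not in DEFAULTS:
            raise ValueError(f"unknown task {task_name!r}; expected one of {sorted(DEFAULTS)}")
        self.task_name = task_name
        self.sections = sections

    # -- builders ----------------------------------------------------------
    def space(self, **overrides) -> HomeostaticSpace:
        kw = dict(self.sections["homeostat"])
        kw.update(overrides)
        return HomeostaticSpace(**kw)

    def agent_params(self, **overrides) -> AgentParams:
        kw = dict(self.sections["agent"])
        kw.update(overrides)
        return AgentParams(**kw)

    def task(self) -> TaskSpec:
        kw = dict(self.sections["task"])
        if self.task_name == "intake":
            return build_intake_task(**kw)
        kw.pop("n_episodes")
        return build_mountain_task(**kw)

    @property
    def n_episodes(self) -> int:
        return int(self.sections["task"].get("n_episodes", 1))

    @property
    def n_replicates(self) -> int:
        return int(self.sections["experiment"]["n_replicates"])

    @property
    def base_seed(self) -> int:
        return int(self.sections["experiment"]["base_seed"])

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {"task_name": self.task_name, **copy.deepcopy(self.sections)}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        task_name = data.pop("task_name")
        return resolve_config(task_name, data)

    def __eq__(self, other) -> bool:
        return isinstance(other, RunConfig) and self.to_dict() == other.to_dict()


def resolve_config(task_name: str, overrides: dict | None = None) -> RunConfig:
    """Merge overrides into the task defaults, rejecting unknown keys."""
    if task_name not in DEFAULTS:
        raise ValueError(f"unknown task {task_name!r}; expected one of {sorted(DEFAULTS)}")
    overrides = overrides or {}
    unknown = set(overrides) - set(RunConfig.SECTIONS)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    sections = {}
    for name in RunConfig.SECTIONS:
        sections[name] = _validate_section(
            overrides.get(name, {}), DEFAULTS[task_name][name], f"{task_name}.{name}"
        )
    return RunConfig(task_name, sections)


def load_config(path) -> RunConfig:
    """Load a YAML config file (as written by :meth:`RunConfig.to_yaml`)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "task_name" not in data:
        raise ValueError(f"config file {path} must be a mapping with a 'task_name' key")
    return RunConfig.from_dict(data)
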