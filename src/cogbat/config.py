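"""Task configurations.

Each task has a small dataclass config that, together with a seed, fully
determines the trial schedule an engine produces.  Configs validate their
invariants on construction, serialise to plain dicts (for the JSONL session
header and for YAML round-trips), and hash stably so any scored output can be
traced back to the exact configuration that produced it.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from typing import Optional

import yaml

from .errors import ConfigurationError

TASKS = ("bart", "sst", "ddt", "vmac", "sdt")


@dataclass
class BartConfig:
    """Balloon-risk task, precommitment variant.

    Responders commit a pump count up front; the balloon bursts when the
    committed count reaches a predetermined threshold, forfeiting the trial's
    earnings.
    """

    n_practice: int = 3
    n_test: int = 30
    max_pumps: int = 128
    burst_mean: int = 64
    reward_per_pump: float = 1.0
    burst_sequence_mode: str = "fixed_permutation"  # or "seeded_random"

    def __post_init__(self) -> None:
        if self.burst_mean > self.max_pumps:
            raise ConfigurationError("burst_mean exceeds max_pumps")
        if self.burst_mean < 1 or self.max_pumps < 1:
            raise ConfigurationError("burst_mean and max_pumps must be >= 1")
        if self.burst_sequence_mode not in ("fixed_permutation", "seeded_random"):
            raise ConfigurationError(
                f"unknown burst_sequence_mode {self.burst_sequence_mode!r}"
            )
        if self.n_test < 1 or self.n_practice < 0:
            raise ConfigurationError("trial counts out of range")


@dataclass
class SstConfig:
    """Stop-signal task with a one-up/one-down SSD staircase.

    Go responses earn points that fall off linearly with reaction time; stop
    trials adapt the stop-signal delay by ``ssd_step`` to hold stopping
    success near 50%.
    """

    n_practice: int = 10
    n_test: int = 150
    p_stop: float = 0.30
    ssd_start: int = 200
    ssd_step: int = 50
    go_deadline: int = 2000
    max_trial_points: int = 25
    practice_gate_accuracy: float = 0.70
    max_practice_repeats: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.p_stop < 1:
            raise ConfigurationError("p_stop must lie strictly in (0, 1)")
        if self.ssd_step <= 0:
            raise ConfigurationError("ssd_step must be positive")
        if self.go_deadline <= 0:
            raise ConfigurationError("go_deadline must be positive")

    @property
    def n_stop_test(self) -> int:
        return round(self.n_test * self.p_stop)


@dataclass
class DdtConfig:
    """Experiential delay-discounting task on a grid.

    Each trial offers a smaller sum of coins close to the avatar against a
    larger sum farther away; delays are experienced in real time, derived as
    distance / travel_speed, so the discount rate k is per second.
    """

    n_trials: int = 60
    time_budget: float = 3600.0
    travel_speed: float = 1.0
    option_pairs: Optional[list] = None  # [(ss_amount, ss_dist, ll_amount, ll_dist)]
    delay_unit: str = "seconds"
    # generation ranges used when option_pairs is None
    ss_amount_range: tuple = (5, 40)
    ll_amount_extra_range: tuple = (5, 60)
    ss_distance_range: tuple = (1.0, 10.0)
    ll_distance_range: tuple = (3.0, 60.0)

    def __post_init__(self) -> None:
        if self.travel_speed <= 0:
            raise ConfigurationError("travel_speed must be positive")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.option_pairs is not None:
            for i, (ss_a, ss_d, ll_a, ll_d) in enumerate(self.option_pairs):
                if not (ll_a > ss_a and ll_d > ss_d):
                    raise ConfigurationError(
                        f"option pair {i}: larger-later must dominate in both "
                        "amount and distance"
                    )


@dataclass
class VmacConfig:
    """Value-modulated attentional-capture search task with reversal.

    A reward-signalling but task-irrelevant coloured distractor appears on
    most trials; one colour signals a large reward, the other a small one,
    and the contingency reverses after the training blocks.
    """

    n_blocks_training: int = 4
    n_blocks_reversal: int = 2
    trials_per_block: int = 24
    distractor_trials_per_block: int = 20
    high_points: int = 100
    low_points: int = 10
    fast_window: int = 1000
    slow_window: int = 2000
    rt_proportional_reward: bool = True
    high_color: str = "pink"  # high-value colour during training
    low_color: str = "green"

    def __post_init__(self) -> None:
        if self.distractor_trials_per_block % 2 != 0:
            raise ConfigurationError(
                "distractor trials must split equally between colours"
            )
        if self.distractor_trials_per_block > self.trials_per_block:
            raise ConfigurationError("more distractor trials than trials per block")
        if not 0 < self.fast_window < self.slow_window:
            raise ConfigurationError("need 0 < fast_window < slow_window")


@dataclass
class SdtConfig:
    """Two-step sequential decision task with deterministic transitions.

    Four first-stage options (two teams of two) map deterministically onto
    two terminal states whose point values drift as independent bounded
    Gaussian random walks.
    """

    n_practice: int = 25
    n_test: int = 125
    transition_map: dict = field(
        default_factory=lambda: {"a1": 0, "a2": 1, "b1": 0, "b2": 1}
    )
    walk_min: float = 0.0
    walk_max: float = 9.0
    walk_step_sd: float = 2.0
    walk_boundary: str = "reflect"  # or "truncate"

    def __post_init__(self) -> None:
        teams = {"a": [], "b": []}
        for opt, state in self.transition_map.items():
            team = opt[0]
            if team not in teams:
                raise ConfigurationError(f"option {opt!r} belongs to no team")
            teams[team].append(state)
        for team, states in teams.items():
            if sorted(states) != [0, 1]:
                raise ConfigurationError(
                    f"team {team!r} must contain exactly one option per terminal state"
                )
        if self.walk_min >= self.walk_max:
            raise ConfigurationError("walk bounds inverted")
        if self.walk_boundary not in ("reflect", "truncate"):
            raise ConfigurationError(f"unknown boundary rule {self.walk_boundary!r}")

    @property
    def walk_midpoint(self) -> float:
        return 0.5 * (self.walk_min + self.walk_max)

    @property
    def team_options(self) -> dict:
        out: dict = {}
        for opt in sorted(self.transition_map):
            out.setdefault(opt[0].upper(), []).append(opt)
        return out


CONFIG_TYPES = {
    "bart": BartConfig,
    "sst": SstConfig,
    "ddt": DdtConfig,
    "vmac": VmacConfig,
    "sdt": SdtConfig,
}


def default_config(task: str):
    try:
        return CONFIG_TYPES[task]()
    except KeyError:
        raise ConfigurationError(f"unknown task {task!r}") from None


def config_to_dict(config) -> dict:
    d = asdict(config)
    d["task"] = _task_of(config)
    return d


def config_from_dict(d: dict):
    d = dict(d)
    task = d.pop("task")
    cls = CONFIG_TYPES[task]
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigurationError(f"unknown {task} config fields: {sorted(unknown)}")
    kwargs = {}
    for k, v in d.items():
        if k == "option_pairs" and v is not None:
            v = [tuple(p) for p in v]
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def _task_of(config) -> str:
    for task, cls in CONFIG_TYPES.items():
        if isinstance(config, cls):
            return task
    raise ConfigurationError(f"not a task config: {type(config).__name__}")


def config_hash(config) -> str:
    """Stable 12-hex-digit digest of a config's canonical JSON form."""
    blob = json.dumps(config_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_configs(path) -> dict:
    """Read a YAML file with one section per task; missing fields keep defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for task, section in raw.items():
        if task not in CONFIG_TYPES:
            raise ConfigurationError(f"unknown task section {task!r}")
        section = dict(section or {})
        section["task"] = task
        out[task] = config_from_dict(section)
    return out


def dump_default_configs() -> str:
    """YAML text of every task's default configuration."""
    doc = {}
    for task in TASKS:
        d = config_to_dict(default_config(task))
        d.pop("task")
        doc[task] = d
    return yaml.safe_dump(doc, sort_keys=False)
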