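"""Session logs and their JSON-Lines serialisation.

A :class:`SessionLog` holds the ordered per-trial records of one participant
on one task, plus the header metadata (task, config, seed, participant,
version tag, occasion) needed to trace every downstream number back to the
run that produced it.  On disk a session is one JSONL file: a header object
followed by one object per trial.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from typing import Iterable, List, Optional

from .config import config_from_dict, config_hash, config_to_dict
from .errors import SchemaError

FORMAT_VERSION = 1


@dataclass
class BartTrialRecord:
    trial_index: int
    practice: bool
    committed_pumps: int
    burst_threshold: int
    burst: bool
    earned: float


@dataclass
class SstTrialRecord:
    trial_index: int
    practice: bool
    trial_type: str          # "go" | "stop"
    stimulus_side: str       # "left" | "right"
    response_side: str       # "left" | "right" | "none"
    rt: Optional[int]        # ms; None when no response recorded
    ssd: Optional[int]       # ms; stop trials only
    stop_success: Optional[bool]  # stop trials only
    points: int


@dataclass
class DdtTrialRecord:
    trial_index: int
    ss_amount: float
    ss_delay: float
    ll_amount: float
    ll_delay: float
    choice: str              # "smaller_sooner" | "larger_later"
    coins_earned: float
    time_spent: float


@dataclass
class VmacTrialRecord:
    trial_index: int
    block: int
    phase: str               # "training" | "reversal"
    distractor: str          # current contingency: "high" | "low" | "absent"
    color: str               # physical colour identity ("pink"/"green"/"none")
    target_side: str
    response_side: str
    rt: Optional[int]
    correct: bool
    points: int


@dataclass
class SdtTrialRecord:
    trial_index: int
    practice: bool
    team_shown: str          # "A" | "B"
    option_chosen: str
    terminal_state: int
    reward: int


RECORD_TYPES = {
    "bart": BartTrialRecord,
    "sst": SstTrialRecord,
    "ddt": DdtTrialRecord,
    "vmac": VmacTrialRecord,
    "sdt": SdtTrialRecord,
}


@dataclass
class SessionLog:
    task: str
    config: object
    seed: int
    participant: str = "p0"
    version: str = "gamified"   # version tag: gamified | standard
    occasion: str = "test"      # test | retest
    trials: List[object] = field(default_factory=list)

    @property
    def config_hash(self) -> str:
        return config_hash(self.config)

    def test_trials(self) -> list:
        """Trials that enter scoring (practice excluded where the task has any)."""
        return [t for t in self.trials if not getattr(t, "practice", False)]

    def practice_trials(self) -> list:
        return [t for t in self.trials if getattr(t, "practice", False)]

    # ---- serialisation -------------------------------------------------
    def header(self) -> dict:
        return {
            "record": "header",
            "format_version": FORMAT_VERSION,
            "task": self.task,
            "config": config_to_dict(self.config),
            "config_hash": self.config_hash,
            "seed": self.seed,
            "participant": self.participant,
            "version": self.version,
            "occasion": self.occasion,
        }

    def to_jsonl(self) -> str:
        lines = [json.dumps(self.header(), sort_keys=True)]
        for t in self.trials:
            d = {"record": "trial", **asdict(t)}
            lines.append(json.dumps(d, sort_keys=True))
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_jsonl())

    @classmethod
    def from_jsonl(cls, text: str) -> "SessionLog":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise SchemaError("empty session log")
        head = json.loads(lines[0])
        if head.get("record") != "header":
            raise SchemaError("first line of a session log must be the header")
        task = head["task"]
        try:
            rec_cls = RECORD_TYPES[task]
        except KeyError:
            raise SchemaError(f"unknown task {task!r} in header") from None
        names = [f.name for f in fields(rec_cls)]
        trials = []
        for ln in lines[1:]:
            d = json.loads(ln)
            if d.pop("record", None) != "trial":
                raise SchemaError("non-trial record after header")
            missing = [n for n in names if n not in d]
            if missing:
                raise SchemaError(f"trial record missing fields {missing}")
            trials.append(rec_cls(**{n: d[n] for n in names}))
        return cls(
            task=task,
            config=config_from_dict(head["config"]),
            seed=head["seed"],
            participant=head.get("participant", "p0"),
            version=head.get("version", "gamified"),
            occasion=head.get("occasion", "test"),
            trials=trials,
        )

    @classmethod
    def load(cls, path) -> "SessionLog":
        with open(path) as fh:
            return cls.from_jsonl(fh.read())


def load_sessions(paths: Iterable) -> List[SessionLog]:
    return [SessionLog.load(p) for p in paths]
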