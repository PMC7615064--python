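"""Data-exclusion rules applied before psychometrics.

Stop-signal sessions are excluded when go accuracy is worse than 90% or
when stop-trial inhibition lies outside 25-75% (ineffective staircasing);
attentional-capture sessions are excluded when accuracy falls below chance
in the pooled training or reversal blocks; any session can be excluded for
an implausibly short completion time.  All inequalities are strict, so
boundary values pass.  QC is pure and idempotent: re-running on an already
filtered cohort removes nothing.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

from .session import SessionLog

# nominal full-length task durations in seconds, from the tasks' stated lengths
NOMINAL_DURATION = {"bart": 300, "sst": 720, "ddt": 360, "vmac": 720, "sdt": 1500}
DEFAULT_MIN_FRACTION = 0.25


@dataclass
class QcReport:
    participant: str
    task: str
    passed: bool
    reasons: List[str] = field(default_factory=list)
    values: dict = field(default_factory=dict)
    indeterminate: List[str] = field(default_factory=list)

    def __post_init__(self):
        assert self.passed == (not self.reasons)


def qc_sst(log: SessionLog) -> QcReport:
    """Fail if go accuracy < 0.90, or stop inhibition < 0.25 or > 0.75."""
    test = log.test_trials()
    go = [t for t in test if t.trial_type == "go"]
    stop = [t for t in test if t.trial_type == "stop"]
    go_acc = float(np.mean([t.response_side == t.stimulus_side for t in go]))
    inhibition = float(np.mean([bool(t.stop_success) for t in stop]))
    reasons = []
    if go_acc < 0.90:
        reasons.append("go_accuracy")
    if inhibition < 0.25:
        reasons.append("inhibition_low")
    if inhibition > 0.75:
        reasons.append("inhibition_high")
    return QcReport(
        participant=log.participant, task="sst", passed=not reasons,
        reasons=reasons, values={"go_accuracy": go_acc, "inhibition": inhibition},
    )


def qc_vmac(log: SessionLog) -> QcReport:
    """Fail if accuracy is below chance (0.5 for the binary left/right
    response) in the pooled training or pooled reversal blocks."""
    reasons = []
    values = {}
    for phase, rule in (("training", "training_below_chance"),
                        ("reversal", "reversal_below_chance")):
        trials = [t for t in log.trials if t.phase == phase]
        acc = float(np.mean([t.correct for t in trials]))
        values[f"{phase}_accuracy"] = acc
        if acc < 0.5:
            reasons.append(rule)
    return QcReport(
        participant=log.participant, task="vmac", passed=not reasons,
        reasons=reasons, values=values,
    )


def _active_seconds(log: SessionLog) -> Optional[float]:
    if log.task == "ddt":
        return float(sum(t.time_spent for t in log.trials))
    if log.task == "sst":
        dl = log.config.go_deadline
        return sum((t.rt if t.rt is not None else dl) for t in log.trials) / 1000.0
    if log.task == "vmac":
        slow = log.config.slow_window
        return sum((t.rt if t.rt is not None else slow) for t in log.trials) / 1000.0
    return None  # balloon and two-step logs carry no per-trial timing


def qc_timing(log: SessionLog, min_duration: Optional[float] = None) -> QcReport:
    """Fail when total active time is below the plausibility threshold.

    The default threshold is a fraction (0.25) of the task's nominal
    duration.  Sessions without per-trial timing are flagged indeterminate,
    not failed.
    """
    if min_duration is None:
        min_duration = DEFAULT_MIN_FRACTION * NOMINAL_DURATION[log.task]
    total = _active_seconds(log)
    if total is None:
        return QcReport(
            participant=log.participant, task=log.task, passed=True,
            values={"active_seconds": None, "min_duration": min_duration},
            indeterminate=["timing_unavailable"],
        )
    reasons = [] if total >= min_duration else ["implausible_duration"]
    return QcReport(
        participant=log.participant, task=log.task, passed=not reasons,
        reasons=reasons,
        values={"active_seconds": total, "min_duration": min_duration},
    )


def qc_session(log: SessionLog, min_duration: Optional[float] = None) -> QcReport:
    """All applicable rules for one session, merged into one report."""
    reports = [qc_timing(log, min_duration)]
    if log.task == "sst":
        reports.append(qc_sst(log))
    elif log.task == "vmac":
        reports.append(qc_vmac(log))
    reasons = [r for rep in reports for r in rep.reasons]
    values = {k: v for rep in reports for k, v in rep.values.items()}
    indet = [f for rep in reports for f in rep.indeterminate]
    return QcReport(
        participant=log.participant, task=log.task, passed=not reasons,
        reasons=reasons, values=values, indeterminate=indet,
    )


def qc_cohort(table: pd.DataFrame, reports: Iterable[QcReport]):
    """Drop excluded rows from a scored cohort table.

    Returns ``(filtered_table, summary)``: the summary counts each rule
    violation separately, so a participant failing two rules is removed once
    from the table but appears in both rule counts.
    """
    reports = list(reports)
    failed_keys = {(r.participant, r.task) for r in reports if not r.passed}
    rule_counts: dict = {}
    for r in reports:
        for rule in r.reasons:
            rule_counts[rule] = rule_counts.get(rule, 0) + 1
    if {"participant", "task"} - set(table.columns):
        raise KeyError("cohort table needs 'participant' and 'task' columns")
    mask = [
        (p, t) not in failed_keys
        for p, t in zip(table["participant"], table["task"])
    ]
    filtered = table[mask].reset_index(drop=True)
    summary = pd.DataFrame(
        sorted(rule_counts.items()), columns=["rule", "n_violations"]
    )
    summary.attrs["n_excluded"] = int(len(table) - len(filtered))
    return filtered, summary
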