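"""Session-level metrics for the balloon-risk, stop-signal and
attentional-capture tasks.

The two likelihood-based estimators live in their own modules
(:mod:`cogbat.discounting` for the hyperbolic discount rate,
:mod:`cogbat.hybrid` for the two-step reinforcement-learning fit) and are
re-exported here so ``cogbat.scoring`` covers every task metric.

Practice trials never enter any metric.  All dispersion statistics use the
sample (n-1) standard deviation.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass


import numpy as np

from .errors import InsufficientDataError
from .session import SessionLog


@dataclass
class BartMetrics:
    bursts: int
    mean_pumps: float
    money_earned: float
    coefficient_of_variability: float


@dataclass
class SstMetrics:
    go_rt: float
    ssrt_mean_method: float
    ssrt_integration: float
    p_respond_given_stop: float
    mean_ssd: float
    integration_unreliable: bool = False


@dataclass
class VmacMetrics:
    vmac_training_score: float
    vmac_reversal_score: float
    total_points: int


def score_bart(log: SessionLog) -> BartMetrics:
    """Bursts, mean precommitted pumps, money earned and the coefficient of
    variability, over test trials only.

    Mean pumps includes burst trials' committed pumps: precommitment makes
    the intended risk observable even when the balloon bursts.
    """
    test = log.test_trials()
    if len(test) < 2:
        raise InsufficientDataError(
            "BART scoring needs at least 2 test trials (CV undefined otherwise)"
        )
    pumps = np.array([t.committed_pumps for t in test], dtype=float)
    mean_pumps = float(pumps.mean())
    cv = float(pumps.std(ddof=1) / mean_pumps) if mean_pumps > 0 else float("nan")
    return BartMetrics(
        bursts=int(sum(t.burst for t in test)),
        mean_pumps=mean_pumps,
        money_earned=float(sum(t.earned for t in test if not t.burst)),
        coefficient_of_variability=cv,
    )


def score_sst(log: SessionLog) -> SstMetrics:
    """Go RT, both SSRT estimates, stop-failure rate and mean SSD.

    Mean method: SSRT = mean correct go RT - mean SSD.  Integration method:
    go omissions are replaced with the maximum observed go RT, all go RTs
    are sorted, and SSRT is the RT at rank ceil(p_respond_given_stop * n_go)
    minus the mean SSD.  When the stop-failure rate is 0 or 1 the
    integration estimate is flagged unreliable.
    """
    test = log.test_trials()
    go = [t for t in test if t.trial_type == "go"]
    stop = [t for t in test if t.trial_type == "stop"]
    if not stop:
        raise InsufficientDataError("SST scoring needs at least one stop trial")
    responded = [t for t in go if t.response_side != "none"]
    correct = [t for t in responded if t.response_side == t.stimulus_side]
    if not correct:
        raise InsufficientDataError("SST scoring needs a responded correct go trial")

    go_rt = float(np.mean([t.rt for t in correct]))
    mean_ssd = float(np.mean([t.ssd for t in stop]))
    p_resp = float(np.mean([not t.stop_success for t in stop]))

    # integration method over ALL go trials, omissions replaced by the max RT
    observed = [t.rt for t in responded]
    max_rt = max(observed)
    all_rts = sorted(observed + [max_rt] * (len(go) - len(responded)))
    unreliable = p_resp in (0.0, 1.0)
    if unreliable:
        warnings.warn(
            "stop-failure rate is 0 or 1; integration SSRT is unreliable",
            stacklevel=2,
        )
    rank = min(max(math.ceil(p_resp * len(all_rts)), 1), len(all_rts))
    nth_rt = float(all_rts[rank - 1])
    return SstMetrics(
        go_rt=go_rt,
        ssrt_mean_method=go_rt - mean_ssd,
        ssrt_integration=nth_rt - mean_ssd,
        p_respond_given_stop=p_resp,
        mean_ssd=mean_ssd,
        integration_unreliable=unreliable,
    )


def _mean_rt(trials, label: str) -> float:
    rts = [t.rt for t in trials if t.correct and t.rt is not None]
    if not rts:
        raise InsufficientDataError(f"no correct responses in cell {label!r}")
    return float(np.mean(rts))


def score_vmac(log: SessionLog) -> VmacMetrics:
    """Capture scores and total points.

    Training score: mean correct RT with a currently-high-value distractor
    minus currently-low, pooled over the training blocks.  Reversal score:
    mean correct RT on the previously-high colour minus the previously-low
    colour (physical colour identity, not the reversed contingency), pooled
    over the reversal blocks.
    """
    trials = log.trials
    high_color = log.config.high_color
    low_color = log.config.low_color
    train = [t for t in trials if t.phase == "training"]
    rev = [t for t in trials if t.phase == "reversal"]
    training_score = (
        _mean_rt([t for t in train if t.distractor == "high"], "training/high")
        - _mean_rt([t for t in train if t.distractor == "low"], "training/low")
    )
    reversal_score = (
        _mean_rt([t for t in rev if t.color == high_color], "reversal/previously_high")
        - _mean_rt([t for t in rev if t.color == low_color], "reversal/previously_low")
    )
    return VmacMetrics(
        vmac_training_score=training_score,
        vmac_reversal_score=reversal_score,
        total_points=int(sum(t.points for t in trials)),
    )


def score_session(log: SessionLog):
    """Dispatch to the task-appropriate scorer."""
    from .discounting import score_ddt
    from .hybrid import fit_hybrid_model

    scorers = {
        "bart": score_bart,
        "sst": score_sst,
        "ddt": score_ddt,
        "vmac": score_vmac,
        "sdt": fit_hybrid_model,
    }
    return scorers[log.task](log)
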