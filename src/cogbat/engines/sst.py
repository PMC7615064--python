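"""Stop-signal engine.

Go trials are a two-choice reaction: respond on the stimulus side before the
deadline, earning points that fall off linearly with reaction time.  On a
minority of trials a stop signal follows the go stimulus after the current
stop-signal delay (SSD); withholding the response is a successful stop.  The
SSD tracks performance one-up/one-down: a successful stop makes the next
stop harder (+step), a failed stop easier (-step, floored at 0), which holds
stopping success near 50% for a stationary responder.

A practice block gates entry to the test phase: the responder must reach the
configured go accuracy, with a bounded number of practice repeats.  The
staircase state persists from practice into test.
"""
from __future__ import annotations

import numpy as np

from ..config import SstConfig
from ..errors import PracticeGateError
from ..session import SessionLog, SstTrialRecord


def _block_plan(n: int, p_stop: float, rng) -> list:
    """Trial types and stimulus sides for one block; stop count = round(n*p_stop)."""
    n_stop = round(n * p_stop)
    types = np.array(["stop"] * n_stop + ["go"] * (n - n_stop))
    rng.shuffle(types)
    sides = rng.choice(["left", "right"], size=n)
    return list(zip(types.tolist(), sides.tolist()))


def _go_points(rt: int, config: SstConfig) -> int:
    pts = round(config.max_trial_points * (1 - rt / config.go_deadline))
    return int(min(max(pts, 0), config.max_trial_points))


def run_sst(
    config: SstConfig,
    agent,
    seed: int,
    participant: str = "p0",
    version: str = "gamified",
    occasion: str = "test",
) -> SessionLog:
    """Run one session with a stop-capable responder.

    ``agent.respond(trial_type, stimulus_side, ssd)`` returns ``None`` (no
    response) or ``(side, rt)``.  On go trials a response with rt beyond the
    deadline is recorded as an omission.
    """
    rng = np.random.default_rng(seed)
    ssd = config.ssd_start
    trials = []
    idx = 0

    def run_block(plan, practice):
        nonlocal ssd, idx
        n_go_correct = 0
        n_go = 0
        for trial_type, side in plan:
            if trial_type == "go":
                n_go += 1
                resp = agent.respond("go", side, None)
                if resp is not None and resp[1] > config.go_deadline:
                    resp = None  # too slow: recorded as an omission
                if resp is None:
                    rec = SstTrialRecord(idx, practice, "go", side, "none",
                                         None, None, None, 0)
                else:
                    r_side, rt = resp[0], int(resp[1])
                    correct = r_side == side
                    pts = _go_points(rt, config) if correct else 0
                    if correct:
                        n_go_correct += 1
                    rec = SstTrialRecord(idx, practice, "go", side, r_side,
                                         rt, None, None, pts)
            else:
                resp = agent.respond("stop", side, ssd)
                trial_ssd = ssd
                if resp is None:
                    rec = SstTrialRecord(idx, practice, "stop", side, "none",
                                         None, trial_ssd, True, 0)
                    ssd += config.ssd_step
                else:
                    r_side, rt = resp[0], int(resp[1])
                    rec = SstTrialRecord(idx, practice, "stop", side, r_side,
                                         rt, trial_ssd, False, 0)
                    ssd = max(0, ssd - config.ssd_step)
            trials.append(rec)
            idx += 1
        return n_go_correct / n_go if n_go else 1.0

    # practice with accuracy gate
    if config.n_practice > 0:
        for attempt in range(config.max_practice_repeats + 1):
            acc = run_block(_block_plan(config.n_practice, config.p_stop, rng), True)
            if acc >= config.practice_gate_accuracy:
                break
        else:
            raise PracticeGateError(
                f"go accuracy below {config.practice_gate_accuracy:.0%} on "
                f"{config.max_practice_repeats + 1} practice attempts"
            )

    run_block(_block_plan(config.n_test, config.p_stop, rng), False)
    return SessionLog(
        task="sst", config=config, seed=seed, participant=participant,
        version=version, occasion=occasion, trials=trials,
    )
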