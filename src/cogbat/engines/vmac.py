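"""Value-modulated attentional-capture engine with reversal.

Responders locate a target and respond on its side.  On most trials a
task-irrelevant coloured distractor signals the reward magnitude available:
one colour high (100 points), the other low (10).  Correct responses within
the fast window earn points proportional to speed; responses in the slow
window (1000-2000 ms) or wrong earn nothing.  After the training blocks the
colour-reward contingency reverses; trial records keep the physical colour
so reversal scoring can reference the previously-high colour.
"""
from __future__ import annotations

import numpy as np

from ..config import VmacConfig
from ..session import SessionLog, VmacTrialRecord


def _block_plan(config: VmacConfig, rng) -> list:
    """(colour,) labels for one block: equal split of the two distractor
    colours plus distractor-absent fillers, shuffled."""
    half = config.distractor_trials_per_block // 2
    n_absent = config.trials_per_block - config.distractor_trials_per_block
    colors = [config.high_color] * half + [config.low_color] * half + ["none"] * n_absent
    rng.shuffle(colors)
    return colors


def _points(config: VmacConfig, magnitude: int, correct: bool, rt) -> int:
    if not correct or rt is None or rt >= config.fast_window:
        return 0
    if config.rt_proportional_reward:
        return int(round(magnitude * (1 - rt / config.fast_window)))
    return magnitude


def run_vmac(
    config: VmacConfig,
    agent,
    seed: int,
    participant: str = "p0",
    version: str = "gamified",
    occasion: str = "test",
) -> SessionLog:
    """Run one session.

    ``agent.respond(color, value, phase, target_side)`` returns
    ``(side, rt)``; ``value`` is the CURRENT contingency label for the
    distractor colour on that trial ("high"/"low"/"absent").
    """
    rng = np.random.default_rng(seed)
    trials = []
    idx = 0
    n_blocks = config.n_blocks_training + config.n_blocks_reversal
    for block in range(1, n_blocks + 1):
        phase = "training" if block <= config.n_blocks_training else "reversal"
        for color in _block_plan(config, rng):
            if color == "none":
                value = "absent"
                magnitude = config.low_points
            else:
                is_high_now = (color == config.high_color) == (phase == "training")
                value = "high" if is_high_now else "low"
                magnitude = config.high_points if is_high_now else config.low_points
            target_side = str(rng.choice(["left", "right"]))
            side, rt = agent.respond(color, value, phase, target_side)
            rt = None if rt is None else int(rt)
            correct = side == target_side
            pts = _points(config, magnitude, correct, rt)
            trials.append(
                VmacTrialRecord(
                    trial_index=idx, block=block, phase=phase, distractor=value,
                    color=color, target_side=target_side, response_side=side,
                    rt=rt, correct=correct, points=pts,
                )
            )
            idx += 1
    return SessionLog(
        task="vmac", config=config, seed=seed, participant=participant,
        version=version, occasion=occasion, trials=trials,
    )
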