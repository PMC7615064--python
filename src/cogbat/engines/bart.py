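"""Balloon-risk engine (precommitment variant).

The responder commits a pump count at balloon onset; the trial bursts when
the committed count reaches the trial's predetermined threshold, forfeiting
that balloon's earnings.  Burst thresholds come from a fixed pseudorandom
sequence whose test-trial mean is exactly the configured mean burst point,
so the design-level mean is a testable exact property rather than a
statistical one.
"""
from __future__ import annotations

from typing import Callable

import numpy as np

from ..config import BartConfig
from ..errors import ConfigurationError, InputError
from ..session import BartTrialRecord, SessionLog

# Fixed 30-trial burst-threshold sequence: 15 symmetric pairs around 64,
# all within [1, 128], in a frozen pseudorandom order.  Mean is exactly 64.
FIXED_TEST_THRESHOLDS = (
    2, 62, 117, 56, 126, 47, 41, 23, 87, 59, 105, 35, 53, 75, 20,
    29, 11, 90, 123, 99, 17, 38, 5, 111, 69, 72, 93, 66, 108, 81,
)
assert sum(FIXED_TEST_THRESHOLDS) == 64 * 30


def _balanced_thresholds(n: int, mean: int, max_pumps: int) -> list:
    """Threshold multiset of length n with arithmetic mean exactly `mean`.

    Built from symmetric pairs around the mean using a frozen delta pattern;
    an odd trailing element sits exactly at the mean.
    """
    dmax = max(1, min(mean - 1, max_pumps - mean))
    rng = np.random.default_rng(20230825)  # frozen: part of the design, not the seed
    deltas = rng.permutation(np.arange(1, dmax + 1))
    out: list = []
    i = 0
    while len(out) + 1 < n:
        d = int(deltas[i % len(deltas)])
        out += [mean - d, mean + d]
        i += 1
    if len(out) < n:
        out.append(mean)
    order = rng.permutation(len(out))
    return [out[j] for j in order]


def make_bart_schedule(config: BartConfig, seed: int) -> list:
    """Ordered burst thresholds for one session (practice first, then test).

    In ``fixed_permutation`` mode the test thresholds are the frozen design
    sequence (identical across seeds); ``seeded_random`` mode permutes the
    same multiset under the seed.  Practice thresholds are seeded uniform
    draws in [1, max_pumps] and never enter scoring.
    """
    if config.burst_mean > config.max_pumps:
        raise ConfigurationError("burst_mean exceeds max_pumps")
    rng = np.random.default_rng(seed)
    practice = [int(v) for v in rng.integers(1, config.max_pumps + 1, config.n_practice)]

    if (
        config.n_test == 30
        and config.burst_mean == 64
        and config.max_pumps == 128
    ):
        test = list(FIXED_TEST_THRESHOLDS)
    else:
        test = _balanced_thresholds(config.n_test, config.burst_mean, config.max_pumps)
    if config.burst_sequence_mode == "seeded_random":
        test = [test[j] for j in rng.permutation(len(test))]
    return practice + test


def run_bart(
    config: BartConfig,
    decide: Callable[[int], int],
    seed: int,
    participant: str = "p0",
    version: str = "gamified",
    occasion: str = "test",
) -> SessionLog:
    """Run one session: ``decide(trial_index)`` returns the committed pumps."""
    schedule = make_bart_schedule(config, seed)
    trials = []
    for i, threshold in enumerate(schedule):
        pumps = int(decide(i))
        if not 0 <= pumps <= config.max_pumps:
            raise InputError(
                f"trial {i}: committed pumps {pumps} outside [0, {config.max_pumps}]"
            )
        burst = pumps >= threshold
        earned = 0.0 if burst else pumps * config.reward_per_pump
        trials.append(
            BartTrialRecord(
                trial_index=i,
                practice=i < config.n_practice,
                committed_pumps=pumps,
                burst_threshold=threshold,
                burst=burst,
                earned=earned,
            )
        )
    return SessionLog(
        task="bart", config=config, seed=seed, participant=participant,
        version=version, occasion=occasion, trials=trials,
    )
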