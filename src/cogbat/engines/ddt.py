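"""Experiential delay-discounting engine.

Each trial offers a smaller sum of coins near the avatar against a larger
sum farther away on the grid; travelling to an option costs its delay
(distance / travel_speed, in seconds), so choices trade reward against
experienced waiting time.  The session ends after the configured number of
trials or when the time budget runs out, whichever comes first.
"""
from __future__ import annotations

import numpy as np

from ..config import DdtConfig
from ..errors import ConfigurationError
from ..session import DdtTrialRecord, SessionLog


def _generate_pairs(config: DdtConfig, rng, n: int) -> list:
    pairs = []
    for _ in range(n):
        ss_a = int(rng.integers(config.ss_amount_range[0], config.ss_amount_range[1] + 1))
        ll_a = ss_a + int(
            rng.integers(config.ll_amount_extra_range[0], config.ll_amount_extra_range[1] + 1)
        )
        ss_d = float(rng.uniform(*config.ss_distance_range))
        lo = max(config.ll_distance_range[0], ss_d + 1.0)
        ll_d = float(rng.uniform(lo, max(config.ll_distance_range[1], lo + 1.0)))
        pairs.append((ss_a, ss_d, ll_a, ll_d))
    return pairs


def run_ddt(
    config: DdtConfig,
    agent,
    seed: int,
    participant: str = "p0",
    version: str = "gamified",
    occasion: str = "test",
) -> SessionLog:
    """Run one session; ``agent(ss_amount, ss_delay, ll_amount, ll_delay)``
    returns ``"smaller_sooner"`` or ``"larger_later"``."""
    if config.travel_speed <= 0:
        raise ConfigurationError("travel_speed must be positive")
    rng = np.random.default_rng(seed)
    if config.option_pairs is not None:
        if len(config.option_pairs) < config.n_trials:
            raise ConfigurationError(
                f"{len(config.option_pairs)} option pairs for {config.n_trials} trials"
            )
        pairs = list(config.option_pairs[: config.n_trials])
    else:
        pairs = _generate_pairs(config, rng, config.n_trials)

    trials = []
    elapsed = 0.0
    for i, (ss_a, ss_d, ll_a, ll_d) in enumerate(pairs):
        ss_delay = ss_d / config.travel_speed
        ll_delay = ll_d / config.travel_speed
        choice = agent(ss_a, ss_delay, ll_a, ll_delay)
        if choice not in ("smaller_sooner", "larger_later"):
            raise ValueError(f"trial {i}: bad choice {choice!r}")
        if choice == "smaller_sooner":
            coins, spent = float(ss_a), ss_delay
        else:
            coins, spent = float(ll_a), ll_delay
        if elapsed + spent > config.time_budget:
            break
        elapsed += spent
        trials.append(
            DdtTrialRecord(
                trial_index=i, ss_amount=float(ss_a), ss_delay=ss_delay,
                ll_amount=float(ll_a), ll_delay=ll_delay, choice=choice,
                coins_earned=coins, time_spent=spent,
            )
        )
    return SessionLog(
        task="ddt", config=config, seed=seed, participant=participant,
        version=version, occasion=occasion, trials=trials,
    )
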