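"""Two-step sequential-decision engine with deterministic transitions.

Four first-stage options (two teams of two) each lead deterministically to
one of two terminal states; within a team, the two options cover both
states.  Terminal-state point values drift as independent Gaussian random
walks bounded by reflection (or truncation), and both walks advance on every
trial.  Which team is shown alternates pseudo-randomly with balanced counts.
"""
from __future__ import annotations

import numpy as np

from ..config import SdtConfig
from ..session import SdtTrialRecord, SessionLog


def _bounded_step(v: float, sd: float, lo: float, hi: float, rule: str, rng) -> float:
    v = v + rng.normal(0.0, sd)
    if rule == "truncate":
        return float(min(max(v, lo), hi))
    # reflect
    width = hi - lo
    while v < lo or v > hi:
        if v < lo:
            v = 2 * lo - v
        if v > hi:
            v = 2 * hi - v
    return float(v)


def _team_sequence(n: int, rng) -> list:
    teams = ["A"] * ((n + 1) // 2) + ["B"] * (n // 2)
    rng.shuffle(teams)
    return teams


def run_sdt(
    config: SdtConfig,
    agent,
    seed: int,
    participant: str = "p0",
    version: str = "gamified",
    occasion: str = "test",
) -> SessionLog:
    """Run one session.

    The agent exposes ``choose(team, options) -> option_id`` and
    ``observe(option, terminal_state, reward)``; ``options`` is the ordered
    pair of option ids on the presented team.
    """
    rng = np.random.default_rng(seed)
    walks = {
        s: float(rng.uniform(config.walk_min, config.walk_max))
        for s in sorted(set(config.transition_map.values()))
    }
    team_opts = config.team_options
    n_total = config.n_practice + config.n_test
    teams = _team_sequence(config.n_practice, rng) + _team_sequence(config.n_test, rng)

    trials = []
    for i in range(n_total):
        team = teams[i]
        options = team_opts[team]
        opt = agent.choose(team, options)
        if opt not in options:
            raise ValueError(f"trial {i}: option {opt!r} not on team {team}")
        state = config.transition_map[opt]
        reward = int(round(min(max(walks[state], config.walk_min), config.walk_max)))
        agent.observe(opt, state, reward)
        trials.append(
            SdtTrialRecord(
                trial_index=i, practice=i < config.n_practice, team_shown=team,
                option_chosen=opt, terminal_state=state, reward=reward,
            )
        )
        for s in walks:  # every walk advances every trial
            walks[s] = _bounded_step(
                walks[s], config.walk_step_sd, config.walk_min,
                config.walk_max, config.walk_boundary, rng,
            )
    return SessionLog(
        task="sdt", config=config, seed=seed, participant=participant,
        version=version, occasion=occasion, trials=trials,
    )
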