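"""Synthetic cohorts: draw ground-truth responder parameters once per
participant, replay them across occasions and task versions, and emit the
session logs alongside the ground-truth table.

Parameters are stable traits: each participant's generative parameters are
drawn once and reused on every occasion, with optional occasion-level
Gaussian jitter to emulate state variability.  When two version tags are
simulated the presentation order alternates across participants
(counterbalancing), recorded in the truth table.
"""
from __future__ import annotations

from dataclasses import asdict, fields
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from . import agents as ag
from .config import default_config
from .engines import run_bart, run_ddt, run_sdt, run_sst, run_vmac
from .errors import InputError
from .session import SessionLog

PARAM_TYPES = {
    "bart": ag.BartAgentParams,
    "sst": ag.RaceAgentParams,
    "ddt": ag.DiscounterParams,
    "vmac": ag.VmacAgentParams,
    "sdt": ag.HybridAgentParams,
}

# hard bounds used when occasion noise would push a trait outside its range
_CLIP = {
    ("bart", "target_pumps_mean"): (0.0, 128.0),
    ("bart", "target_pumps_sd"): (0.0, np.inf),
    ("sst", "true_ssrt"): (1.0, np.inf),
    ("sst", "go_omission_rate"): (0.0, 0.999),
    ("sst", "choice_error_rate"): (0.0, 0.999),
    ("ddt", "true_k"): (0.0, np.inf),
    ("ddt", "choice_temperature"): (1e-6, np.inf),
    ("vmac", "error_rate"): (0.0, 0.999),
    ("sdt", "w"): (0.0, 1.0),
    ("sdt", "alpha"): (0.0, 1.0),
    ("sdt", "beta"): (0.0, np.inf),
}


def _draw(spec, rng):
    if callable(spec):
        return float(spec(rng))
    if isinstance(spec, tuple) and len(spec) == 3 and spec[0] == "loguniform":
        lo, hi = np.log(spec[1]), np.log(spec[2])
        return float(np.exp(rng.uniform(lo, hi)))
    if isinstance(spec, tuple) and len(spec) == 2:
        return float(rng.uniform(*spec))
    return float(spec)


def draw_params(task: str, distribution: Dict, rng):
    """Draw one parameter set for ``task`` from a distribution spec.

    Each entry maps a parameter name to a fixed value, a ``(low, high)``
    uniform range, ``("loguniform", low, high)``, or a callable of the rng.
    Unspecified parameters keep their defaults.
    """
    cls = PARAM_TYPES[task]
    valid = {f.name for f in fields(cls)}
    unknown = set(distribution) - valid
    if unknown:
        raise InputError(f"unknown {task} agent parameters: {sorted(unknown)}")
    return cls(**{k: _draw(v, rng) for k, v in distribution.items()})


def _run_one(task: str, params, config, seed: int, **meta) -> SessionLog:
    if task == "bart":
        return run_bart(config, ag.bart_policy(params, seed, config.max_pumps),
                        seed, **meta)
    if task == "sst":
        return run_sst(config, ag.race_policy(params, seed), seed, **meta)
    if task == "ddt":
        return run_ddt(config, ag.hyperbolic_policy(params, seed), seed, **meta)
    if task == "vmac":
        return run_vmac(
            config,
            ag.vmac_policy(params, seed, trained_high_color=config.high_color),
            seed, **meta,
        )
    if task == "sdt":
        return run_sdt(config, ag.hybrid_policy(params, seed, config), seed, **meta)
    raise InputError(f"unknown task {task!r}")


def simulate_cohort(
    task: str,
    agent_param_distribution: Dict,
    n_participants: int,
    occasions: int = 1,
    seed: int = 0,
    occasion_noise: Optional[Dict[str, float]] = None,
    versions: Tuple[str, ...] = ("gamified",),
    config=None,
) -> Tuple[list, pd.DataFrame]:
    """Simulate ``n_participants`` x ``occasions`` x ``versions`` sessions.

    Returns ``(logs, truth)`` where ``truth`` has one row per participant
    with the drawn generative parameters (and the version order when two
    versions are counterbalanced).  ``occasion_noise`` maps parameter names
    to the SD of Gaussian jitter applied per occasion (clipped back into the
    parameter's valid range).
    """
    if n_participants <= 0:
        raise InputError("n_participants must be positive")
    if config is None:
        config = default_config(task)
    rng = np.random.default_rng(seed)
    occasion_noise = occasion_noise or {}
    occ_names = ["test", "retest"] + [f"occ{i}" for i in range(3, occasions + 1)]

    logs = []
    truth_rows = []
    for i in range(n_participants):
        pid = f"p{i:04d}"
        params = draw_params(task, agent_param_distribution, rng)
        row = {"participant": pid, "task": task}
        row.update({f"true_{k}": v for k, v in asdict(params).items()})
        if len(versions) == 2:
            order = list(versions) if i % 2 == 0 else list(versions[::-1])
            row["version_order"] = ">".join(order)
        truth_rows.append(row)
        # one engine/agent seed per (participant, version), reused across
        # occasions: with zero occasion noise a retest replays identically,
        # so all occasion-level variability is explicit via occasion_noise
        version_seeds = {v: int(rng.integers(0, 2**31)) for v in versions}
        for occ_i in range(occasions):
            occ_params = params
            if occasion_noise:
                d = asdict(params)
                for name, sd in occasion_noise.items():
                    v = d[name] + rng.normal(0.0, sd)
                    lo, hi = _CLIP.get((task, name), (-np.inf, np.inf))
                    d[name] = float(min(max(v, lo), hi))
                occ_params = PARAM_TYPES[task](**d)
            for version in versions:
                logs.append(
                    _run_one(
                        task, occ_params, config, version_seeds[version],
                        participant=pid, version=version,
                        occasion=occ_names[occ_i],
                    )
                )
    return logs, pd.DataFrame(truth_rows)


def score_cohort(logs: Iterable[SessionLog], sdt_restarts: int = 10,
                 seed: int = 0) -> pd.DataFrame:
    """Score every session into a tidy cohort table.

    One row per session: participant/task/version/occasion plus the task's
    metric columns (flag and diagnostic fields are dropped).
    """
    from .discounting import score_ddt
    from .hybrid import fit_hybrid_model
    from .scoring import score_bart, score_sst, score_vmac

    rows = []
    for log in logs:
        base = {
            "participant": log.participant, "task": log.task,
            "version": log.version, "occasion": log.occasion,
        }
        if log.task == "bart":
            m = asdict(score_bart(log))
        elif log.task == "sst":
            m = asdict(score_sst(log))
            m.pop("integration_unreliable", None)
        elif log.task == "ddt":
            d = score_ddt(log)
            m = {"k_hat": d.k_hat, "total_coins": d.total_coins,
                 "prop_smaller_sooner": d.prop_smaller_sooner}
        elif log.task == "vmac":
            m = asdict(score_vmac(log))
        elif log.task == "sdt":
            f = fit_hybrid_model(log, n_restarts=sdt_restarts, seed=seed)
            m = {"w_hat": f.w_hat, "beta_hat": f.beta_hat,
                 "alpha_hat": f.alpha_hat, "total_points": f.total_points}
        else:
            raise InputError(f"unknown task {log.task!r}")
        rows.append({**base, **m})
    return pd.DataFrame(rows)
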