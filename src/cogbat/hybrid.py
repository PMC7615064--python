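"""Maximum-likelihood fit of the hybrid model-based/model-free learner to
two-step session logs.

The choice model is the same one the synthetic hybrid agent generates from:
per-option model-free values Q_MF and per-terminal-state values V learned by
delta rule with rate alpha, model-based option values read off V through the
deterministic transition map, and a softmax with inverse temperature beta
over the blend w*Q_MB + (1-w)*Q_MF.  Fitting is teacher-forced — value
updates follow the recorded choices and rewards — with the likelihood
accumulated over scored (non-practice) trials.  Multi-start L-BFGS-B from a
Latin-hypercube design guards against local optima.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .config import SdtConfig
from .errors import FitError, InsufficientDataError
from .session import SessionLog

BETA_MAX = 20.0
BETA_UNIDENTIFIABLE = 0.1  # below this the softmax is ~flat and w means nothing


@dataclass
class SdtFit:
    w_hat: float
    beta_hat: float
    alpha_hat: float
    log_likelihood: float
    total_points: int
    converged: bool
    n_restarts_used: int
    n_trials: int = 0
    w_unidentifiable: bool = False
    flags: list = field(default_factory=list)


def _session_arrays(log: SessionLog):
    cfg: SdtConfig = log.config
    options = sorted(cfg.transition_map)
    opt_idx = {o: i for i, o in enumerate(options)}
    states = np.array([cfg.transition_map[o] for o in options])
    team_opts = cfg.team_options
    pres = []  # (chosen_idx, other_idx) per trial
    rewards = []
    scored = []
    for t in log.trials:
        opts = team_opts[t.team_shown]
        other = opts[0] if opts[1] == t.option_chosen else opts[1]
        pres.append((opt_idx[t.option_chosen], opt_idx[other]))
        rewards.append(t.reward)
        scored.append(not t.practice)
    return (
        np.array(pres, dtype=np.intp),
        np.array(rewards, dtype=float),
        np.array(scored, dtype=bool),
        states,
        cfg.walk_midpoint,
    )


def _nll(theta, pres, rewards, scored, opt_states, midpoint):
    w, beta, alpha = theta
    n_opts = len(opt_states)
    q_mf = [midpoint] * n_opts
    v_state = {int(s): midpoint for s in set(opt_states.tolist())}
    nll = 0.0
    for i in range(len(rewards)):
        c, o = pres[i]
        if scored[i]:
            qc = w * v_state[int(opt_states[c])] + (1 - w) * q_mf[c]
            qo = w * v_state[int(opt_states[o])] + (1 - w) * q_mf[o]
            z = beta * (qc - qo)
            # -log P(chosen) = log(1 + exp(-z))
            if z < -500:
                nll += -z
            else:
                nll += math.log1p(math.exp(-z))
        r = rewards[i]
        s = int(opt_states[c])
        q_mf[c] += alpha * (r - q_mf[c])
        v_state[s] += alpha * (r - v_state[s])
    return nll


def fit_hybrid_model(
    log: SessionLog,
    n_restarts: int = 10,
    seed: int = 0,
    beta_max: float = BETA_MAX,
) -> SdtFit:
    """Constrained MLE of (w, beta, alpha) on one session.

    Practice trials teacher-force the learning state but contribute no
    likelihood.  Deterministic given (log, n_restarts, seed).
    """
    arrays = _session_arrays(log)
    pres, rewards, scored, opt_states, midpoint = arrays
    n_scored = int(scored.sum())
    if n_scored < 50:
        raise InsufficientDataError(
            f"hybrid fit needs >= 50 scored trials, got {n_scored}"
        )
    bounds = [(0.0, 1.0), (0.0, beta_max), (0.0, 1.0)]
    sampler = qmc.LatinHypercube(d=3, seed=seed)
    starts = qmc.scale(sampler.random(n_restarts),
                       [0.0, 0.05, 0.05], [1.0, beta_max / 2, 0.95])

    best = None
    any_ok = False
    for x0 in starts:
        res = optimize.minimize(
            _nll, x0, args=arrays, method="L-BFGS-B", bounds=bounds,
        )
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("hybrid model optimisation failed on every restart")
    if not any_ok:
        raise FitError(
            f"no restart converged; best status: {best.message!r}"
        )

    w_hat, beta_hat, alpha_hat = (float(v) for v in best.x)
    flags = []
    unident = beta_hat <= BETA_UNIDENTIFIABLE
    if unident:
        flags.append("w_unidentifiable_low_beta")
    return SdtFit(
        w_hat=w_hat,
        beta_hat=beta_hat,
        alpha_hat=alpha_hat,
        log_likelihood=-float(best.fun),
        total_points=int(rewards[scored].sum()),
        converged=any_ok,
        n_restarts_used=n_restarts,
        n_trials=n_scored,
        w_unidentifiable=unident,
        flags=flags,
    )


def hybrid_nll(log: SessionLog, w: float, beta: float, alpha: float) -> float:
    """Negative log-likelihood of (w, beta, alpha) on a session; exposed so
    a brute-force grid can audit the optimiser."""
    return _nll((w, beta, alpha), *_session_arrays(log))


class HybridRLResults:
    """Fit results with observed-information standard errors."""

    def __init__(self, fit: SdtFit, bse: dict):
        self.fit = fit
        self.params = {
            "w": fit.w_hat, "beta": fit.beta_hat, "alpha": fit.alpha_hat,
        }
        self.bse = bse
        self.llf = fit.log_likelihood
        self.nobs = fit.n_trials

    def summary(self) -> str:
        rows = [
            "Hybrid model-based/model-free RL fit",
            "=" * 46,
            f"{'param':<8}{'estimate':>10}{'std err':>10}",
        ]
        for name in ("w", "beta", "alpha"):
            rows.append(
                f"{name:<8}{self.params[name]:>10.3f}"
                f"{self.bse.get(name, float('nan')):>10.3f}"
            )
        rows += [
            f"log-likelihood {self.llf:>10.3f}   n trials {self.nobs}",
            f"total points   {self.fit.total_points}",
        ]
        if self.fit.flags:
            rows.append("flags: " + ", ".join(self.fit.flags))
        return "\n".join(rows)


class HybridRLModel:
    """statsmodels-style face over :func:`fit_hybrid_model`."""

    def __init__(self, log: SessionLog):
        self.log = log

    def fit(self, n_restarts: int = 10, seed: int = 0) -> HybridRLResults:
        fit = fit_hybrid_model(self.log, n_restarts=n_restarts, seed=seed)
        bse = self._bse(fit)
        return HybridRLResults(fit, bse)

    def _bse(self, fit: SdtFit) -> dict:
        arrays = _session_arrays(self.log)
        x0 = np.array([fit.w_hat, fit.beta_hat, fit.alpha_hat])
        h = 1e-4
        hess = np.zeros((3, 3))

        def f(x):
            return _nll(np.clip(x, [0, 0, 0], [1, BETA_MAX, 1]), *arrays)

        for i in range(3):
            for j in range(3):
                ei = np.eye(3)[i] * h
                ej = np.eye(3)[j] * h
                hess[i, j] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej)
                    - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4 * h * h)
        try:
            cov = np.linalg.inv(hess)
            d = np.sqrt(np.clip(np.diag(cov), 0, None))
            return {"w": float(d[0]), "beta": float(d[1]), "alpha": float(d[2])}
        except np.linalg.LinAlgError:
            return {}
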