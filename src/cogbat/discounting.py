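"""Hyperbolic discount-rate estimation from experiential choices.

The discounted value of an amount A at delay D is V = A / (1 + k D); k is
the discount rate (here per second, since delays are experienced in real
time).  Because experiential choices are stochastic, k is estimated jointly
with a choice temperature tau by maximum likelihood of a logistic choice
rule P(larger-later) = logistic(tau * (V_ll - V_ss)), searched on a log grid
and polished with a quasi-Newton step.  One-sided choice sets pin k at a
boundary and are flagged rather than fitted.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .errors import DegenerateDesignError, InsufficientDataError
from .session import SessionLog

K_MAX_DEFAULT = 10.0


@dataclass
class DdtMetrics:
    k_hat: float
    total_coins: float
    prop_smaller_sooner: float
    tau_hat: float = float("nan")
    log_likelihood: float = float("nan")
    boundary: Optional[str] = None  # "all_larger_later" | "all_smaller_sooner"


class DiscountingResults:
    """MLE results for the hyperbolic choice model."""

    def __init__(self, k, tau, loglike, bse, n, metrics):
        self.k = k
        self.tau = tau
        self.llf = loglike
        self.bse = bse  # dict on the log10 scale of (k, tau)
        self.nobs = n
        self.metrics = metrics

    def summary(self) -> str:
        lines = [
            "Hyperbolic discounting model (V = A / (1 + kD))",
            "=" * 48,
            f"n choices            {self.nobs:>10d}",
            f"log-likelihood       {self.llf:>10.3f}",
            f"k (per second)       {self.k:>10.5f}",
            f"tau (choice temp.)   {self.tau:>10.3f}",
            f"se[log10 k]          {self.bse.get('log10_k', float('nan')):>10.3f}",
            f"prop smaller-sooner  {self.metrics.prop_smaller_sooner:>10.3f}",
            f"total coins          {self.metrics.total_coins:>10.1f}",
        ]
        if self.metrics.boundary:
            lines.append(f"boundary solution: {self.metrics.boundary}")
        return "\n".join(lines)


def _as_arrays(trials):
    ss_a = np.array([t[0] for t in trials], float)
    ss_d = np.array([t[1] for t in trials], float)
    ll_a = np.array([t[2] for t in trials], float)
    ll_d = np.array([t[3] for t in trials], float)
    chose_ll = np.array([t[4] == "larger_later" for t in trials], bool)
    return ss_a, ss_d, ll_a, ll_d, chose_ll


def _nll(log10_k, log10_tau, ss_a, ss_d, ll_a, ll_d, chose_ll):
    k = 10.0 ** log10_k
    tau = 10.0 ** log10_tau
    dv = ll_a / (1 + k * ll_d) - ss_a / (1 + k * ss_d)
    z = np.clip(tau * dv, -700, 700)
    # log P(observed): -log(1+exp(-z)) for LL choices, -log(1+exp(z)) for SS
    sign = np.where(chose_ll, 1.0, -1.0)
    return float(np.sum(np.log1p(np.exp(-sign * z))))


class HyperbolicDiscountingModel:
    """statsmodels-style face over :func:`estimate_k`.

    Parameters
    ----------
    trials : sequence of (ss_amount, ss_delay, ll_amount, ll_delay, choice)
        Choice may be "smaller_sooner" or "larger_later".
    """

    def __init__(self, trials: Sequence, k_max: float = K_MAX_DEFAULT):
        self.trials = list(trials)
        self.k_max = k_max

    @classmethod
    def from_session(cls, log: SessionLog, **kw) -> "HyperbolicDiscountingModel":
        trials = [
            (t.ss_amount, t.ss_delay, t.ll_amount, t.ll_delay, t.choice)
            for t in log.test_trials()
        ]
        return cls(trials, **kw)

    def fit(self) -> DiscountingResults:
        m = estimate_k(self.trials, k_max=self.k_max)
        bse = {"log10_k": float("nan"), "log10_tau": float("nan")}
        if m.boundary is None and np.isfinite(m.log_likelihood):
            bse = _mle_bse(m, self.trials)
        return DiscountingResults(
            k=m.k_hat, tau=m.tau_hat, loglike=m.log_likelihood, bse=bse,
            n=len(self.trials), metrics=m,
        )


def _mle_bse(m: DdtMetrics, trials) -> dict:
    """Observed-information standard errors on the log10 parameter scale."""
    arrays = _as_arrays(trials)
    x0 = np.array([np.log10(max(m.k_hat, 1e-12)), np.log10(m.tau_hat)])

    def f(x):
        return _nll(x[0], x[1], *arrays)

    h = 1e-4
    hess = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            e_i = np.eye(2)[i] * h
            e_j = np.eye(2)[j] * h
            hess[i, j] = (
                f(x0 + e_i + e_j) - f(x0 + e_i - e_j)
                - f(x0 - e_i + e_j) + f(x0 - e_i - e_j)
            ) / (4 * h * h)
    try:
        cov = np.linalg.inv(hess)
        d = np.sqrt(np.clip(np.diag(cov), 0, None))
        return {"log10_k": float(d[0]), "log10_tau": float(d[1])}
    except np.linalg.LinAlgError:
        return {"log10_k": float("nan"), "log10_tau": float("nan")}


def estimate_k(
    trials: Sequence,
    k_max: float = K_MAX_DEFAULT,
    n_grid_k: int = 81,
    n_grid_tau: int = 41,
) -> DdtMetrics:
    """Joint (k, tau) maximum likelihood from smaller-sooner/larger-later
    choices, with total coins and the smaller-sooner proportion.

    The likelihood is maximised on a log10 grid over k in [1e-4, k_max] and
    tau in [1e-2, 1e2], then polished with L-BFGS-B.  If every choice went
    the same way, k is returned at the corresponding boundary (0 or k_max)
    with ``boundary`` set.
    """
    trials = list(trials)
    if len(trials) < 2:
        raise InsufficientDataError("k estimation needs at least 2 choices")
    ss_a, ss_d, ll_a, ll_d, chose_ll = _as_arrays(trials)
    if np.all(ss_a == ll_a) and np.all(ss_d == ll_d):
        raise DegenerateDesignError("all options identical; k not estimable")

    chosen = np.where(chose_ll, ll_a, ss_a)
    total_coins = float(chosen.sum())
    prop_ss = float(1.0 - chose_ll.mean())

    if chose_ll.all():
        return DdtMetrics(0.0, total_coins, prop_ss, boundary="all_larger_later")
    if not chose_ll.any():
        return DdtMetrics(k_max, total_coins, prop_ss, boundary="all_smaller_sooner")

    lk = np.linspace(-4.0, np.log10(k_max), n_grid_k)
    lt = np.linspace(-2.0, 2.0, n_grid_tau)
    best = (np.inf, lk[0], lt[0])
    for t in lt:
        k_arr = 10.0 ** lk
        dv = ll_a[None, :] / (1 + k_arr[:, None] * ll_d[None, :]) - ss_a[None, :] / (
            1 + k_arr[:, None] * ss_d[None, :]
        )
        z = np.clip((10.0 ** t) * dv, -700, 700)
        sign = np.where(chose_ll, 1.0, -1.0)
        nlls = np.log1p(np.exp(-sign[None, :] * z)).sum(axis=1)
        i = int(np.argmin(nlls))
        if nlls[i] < best[0]:
            best = (float(nlls[i]), float(lk[i]), float(t))

    res = optimize.minimize(
        lambda x: _nll(x[0], x[1], ss_a, ss_d, ll_a, ll_d, chose_ll),
        x0=[best[1], best[2]],
        method="L-BFGS-B",
        bounds=[(-6.0, np.log10(k_max)), (-3.0, 3.0)],
    )
    nll, lk_hat, lt_hat = (
        (float(res.fun), float(res.x[0]), float(res.x[1]))
        if res.fun <= best[0]
        else best
    )
    return DdtMetrics(
        k_hat=10.0 ** lk_hat,
        total_coins=total_coins,
        prop_smaller_sooner=prop_ss,
        tau_hat=10.0 ** lt_hat,
        log_likelihood=-nll,
    )


def score_ddt(log: SessionLog, **kw) -> DdtMetrics:
    """Score a delay-discounting session log."""
    trials = [
        (t.ss_amount, t.ss_delay, t.ll_amount, t.ll_delay, t.choice)
        for t in log.test_trials()
    ]
    return estimate_k(trials, **kw)


def indifference_k(ss_amount: float, ll_amount: float, delay: float) -> float:
    """The k at which an immediate smaller amount equals a delayed larger one:
    ss = ll / (1 + k*delay)  =>  k = (ll/ss - 1) / delay."""
    return (ll_amount / ss_amount - 1.0) / delay
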