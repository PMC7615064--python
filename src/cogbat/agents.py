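"""Parametric synthetic responders with known ground truth.

Each agent embodies the construct its task measures — a normal pump policy
for risk propensity, an independent horse race for stopping, hyperbolic
discounting for delay choices, reward-conditioned slowing for attentional
capture, and a w-weighted blend of model-based and model-free values for the
two-step task — so scored metrics can be validated by parameter recovery
instead of human data.  Every agent is a pure function of (params, seed,
observed task events); replays are identical.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SdtConfig


# ---------------------------------------------------------------- BART ----
@dataclass
class BartAgentParams:
    """Commits pumps ~ round(Normal(mean, sd)) clamped to the pump range."""

    target_pumps_mean: float = 84.0
    target_pumps_sd: float = 9.0

    def __post_init__(self):
        if not 0 <= self.target_pumps_mean <= 128 or self.target_pumps_sd < 0:
            raise ValueError("BART agent parameters out of range")


def bart_policy(params: BartAgentParams, seed: int, max_pumps: int = 128):
    """Return a ``decide(trial_index) -> pumps`` callback."""
    rng = np.random.default_rng(seed)

    def decide(trial_index: int) -> int:
        pumps = round(rng.normal(params.target_pumps_mean, params.target_pumps_sd))
        return int(min(max(pumps, 0), max_pumps))

    return decide


# ----------------------------------------------------------------- SST ----
@dataclass
class RaceAgentParams:
    """Independent-race stopper: the go process finishes at a lognormal
    latency; a stop succeeds iff the stop process (SSD + fixed SSRT) beats it.
    """

    go_mu: float = np.log(600.0)     # log-ms
    go_sigma: float = 0.2            # log-ms (~20% RT coefficient of variation)
    true_ssrt: float = 250.0         # ms
    go_omission_rate: float = 0.0
    choice_error_rate: float = 0.0
    trigger_failure_rate: float = 0.0  # stop signal missed entirely

    def __post_init__(self):
        if self.true_ssrt <= 0:
            raise ValueError("true_ssrt must be positive")
        for r in (self.go_omission_rate, self.choice_error_rate,
                  self.trigger_failure_rate):
            if not 0 <= r < 1:
                raise ValueError("rates must lie in [0, 1)")


class RaceAgent:
    def __init__(self, params: RaceAgentParams, seed: int):
        self.params = params
        self.rng = np.random.default_rng(seed)

    def _go_sample(self, stimulus_side: str):
        p = self.params
        if self.rng.random() < p.go_omission_rate:
            return None
        rt = int(round(self.rng.lognormal(p.go_mu, p.go_sigma)))
        side = stimulus_side
        if self.rng.random() < p.choice_error_rate:
            side = "left" if stimulus_side == "right" else "right"
        return side, max(rt, 1)

    def respond(self, trial_type: str, stimulus_side: str, ssd):
        resp = self._go_sample(stimulus_side)
        if trial_type == "go":
            return resp
        if resp is None:
            return None  # no go process finished: trivially stopped
        if self.rng.random() < self.params.trigger_failure_rate:
            return resp
        # race: respond only if the go process beats the stop process
        return resp if resp[1] < ssd + self.params.true_ssrt else None


def race_policy(params: RaceAgentParams, seed: int) -> RaceAgent:
    return RaceAgent(params, seed)


# ----------------------------------------------------------------- DDT ----
@dataclass
class DiscounterParams:
    """Hyperbolic discounter: V = A / (1 + k*D), softmax choice."""

    true_k: float = 0.05             # per second
    choice_temperature: float = 2.0  # inverse value units

    def __post_init__(self):
        if self.true_k < 0 or self.choice_temperature <= 0:
            raise ValueError("discounter parameters out of range")


def hyperbolic_value(amount, delay, k):
    return np.asarray(amount) / (1.0 + k * np.asarray(delay))


def hyperbolic_policy(params: DiscounterParams, seed: int = 0):
    """Return a chooser ``(ss_a, ss_d, ll_a, ll_d) -> choice``.

    Picks larger-later with probability logistic(temperature * (V_ll - V_ss)).
    A non-finite temperature gives the deterministic argmax chooser.
    """
    rng = np.random.default_rng(seed)

    def choose(ss_amount, ss_delay, ll_amount, ll_delay) -> str:
        v_ss = float(hyperbolic_value(ss_amount, ss_delay, params.true_k))
        v_ll = float(hyperbolic_value(ll_amount, ll_delay, params.true_k))
        if not np.isfinite(params.choice_temperature):
            return "larger_later" if v_ll >= v_ss else "smaller_sooner"
        z = params.choice_temperature * (v_ll - v_ss)
        p_ll = 1.0 / (1.0 + np.exp(-z))
        return "larger_later" if rng.random() < p_ll else "smaller_sooner"

    return choose


# ---------------------------------------------------------------- VMAC ----
@dataclass
class VmacAgentParams:
    """Lognormal base RT, slowed by reward-signalling distractors.

    ``capture_effect`` is added on trials whose distractor is currently
    high-value; ``perseveration_effect`` is added during reversal on trials
    whose distractor colour was high-value in training.
    """

    base_rt_mu: float = np.log(500.0)
    base_rt_sigma: float = 0.2
    capture_effect: float = 40.0        # ms, may be negative
    perseveration_effect: float = 0.0   # ms
    error_rate: float = 0.05

    def __post_init__(self):
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")


class VmacAgent:
    def __init__(self, params: VmacAgentParams, seed: int,
                 trained_high_color: str = "pink"):
        self.params = params
        self.rng = np.random.default_rng(seed)
        self.trained_high_color = trained_high_color

    def respond(self, color: str, value: str, phase: str, target_side: str):
        p = self.params
        rt = self.rng.lognormal(p.base_rt_mu, p.base_rt_sigma)
        if value == "high":
            rt += p.capture_effect
        if phase == "reversal" and color == self.trained_high_color:
            rt += p.perseveration_effect
        side = target_side
        if self.rng.random() < p.error_rate:
            side = "left" if target_side == "right" else "right"
        return side, int(round(max(rt, 1)))


def vmac_policy(params: VmacAgentParams, seed: int,
                trained_high_color: str = "pink") -> VmacAgent:
    return VmacAgent(params, seed, trained_high_color)


# ----------------------------------------------------------------- SDT ----
@dataclass
class HybridAgentParams:
    """Hybrid two-step learner: softmax over beta*(w*Q_MB + (1-w)*Q_MF)."""

    w: float = 0.5       # 0 = model-free, 1 = model-based
    beta: float = 3.0    # inverse points
    alpha: float = 0.5   # learning rate

    def __post_init__(self):
        if not 0 <= self.w <= 1 or not 0 <= self.alpha <= 1 or self.beta < 0:
            raise ValueError("hybrid agent parameters out of range")


class HybridAgent:
    """Maintains per-option model-free values and per-state values.

    Model-based value of an option is the learned value of the terminal
    state it leads to, tying together the two same-destination options on
    different teams; model-free values are learned per option, so those two
    options are valued independently.  All values start at the reward-walk
    midpoint.
    """

    def __init__(self, params: HybridAgentParams, seed: int,
                 config: SdtConfig | None = None):
        self.params = params
        self.rng = np.random.default_rng(seed)
        self.config = config or SdtConfig()
        mid = self.config.walk_midpoint
        self.q_mf = {opt: mid for opt in self.config.transition_map}
        self.v_state = {s: mid for s in set(self.config.transition_map.values())}

    def _net_value(self, option: str) -> float:
        p = self.params
        q_mb = self.v_state[self.config.transition_map[option]]
        return p.w * q_mb + (1 - p.w) * self.q_mf[option]

    def choose(self, team: str, options) -> str:
        z = self.params.beta * np.array([self._net_value(o) for o in options])
        z -= z.max()
        p = np.exp(z)
        p /= p.sum()
        return options[int(self.rng.choice(len(options), p=p))]

    def observe(self, option: str, state: int, reward: float) -> None:
        a = self.params.alpha
        self.q_mf[option] += a * (reward - self.q_mf[option])
        self.v_state[state] += a * (reward - self.v_state[state])


def hybrid_policy(params: HybridAgentParams, seed: int,
                  config: SdtConfig | None = None) -> HybridAgent:
    return HybridAgent(params, seed, config)
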