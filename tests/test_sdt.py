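"""Two-step engine, hybrid learner and the maximum-likelihood fit."""
import collections

import numpy as np
import pytest

from cogbat import (
    HybridAgentParams, HybridRLModel, SdtConfig, fit_hybrid_model,
    hybrid_policy, run_sdt,
)
from cogbat.errors import ConfigurationError, InsufficientDataError
from cogbat.hybrid import hybrid_nll


class TestEngine:
    def test_terminal_state_follows_the_transition_map(self):
        cfg = SdtConfig()
        log = run_sdt(cfg, hybrid_policy(HybridAgentParams(), 0, cfg), 0)
        for t in log.trials:
            assert t.terminal_state == cfg.transition_map[t.option_chosen]

    def test_invalid_transition_map_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            SdtConfig(transition_map={"a1": 0, "a2": 0, "b1": 0, "b2": 1})

    def test_degenerate_walk_yields_constant_rewards_per_state(self):
        cfg = SdtConfig(walk_step_sd=0.0)
        log = run_sdt(cfg, hybrid_policy(HybridAgentParams(), 1, cfg), 1)
        per_state = collections.defaultdict(set)
        for t in log.trials:
            per_state[t.terminal_state].add(t.reward)
        for rewards in per_state.values():
            assert len(rewards) == 1

    def test_rewards_stay_within_the_walk_bounds(self):
        cfg = SdtConfig()
        for seed in range(5):
            log = run_sdt(cfg, hybrid_policy(HybridAgentParams(), seed, cfg), seed)
            assert all(cfg.walk_min <= t.reward <= cfg.walk_max for t in log.trials)

    def test_team_presentation_is_balanced(self):
        cfg = SdtConfig()
        log = run_sdt(cfg, hybrid_policy(HybridAgentParams(), 2, cfg), 2)
        counts = collections.Counter(t.team_shown for t in log.test_trials())
        assert sorted(counts.values()) == [62, 63]

    def test_session_length_is_practice_plus_test(self):
        cfg = SdtConfig()
        log = run_sdt(cfg, hybrid_policy(HybridAgentParams(), 3, cfg), 3)
        assert len(log.trials) == 150
        assert len(log.test_trials()) == 125


class TestHybridAgent:
    def test_full_learning_rate_assigns_the_whole_reward(self):
        cfg = SdtConfig()
        agent = hybrid_policy(HybridAgentParams(alpha=1.0), 0, cfg)
        agent.observe("a1", 0, 7)
        assert agent.v_state[0] == 7
        assert agent.q_mf["a1"] == 7

    def test_zero_learning_rate_never_moves_values(self):
        cfg = SdtConfig()
        agent = hybrid_policy(HybridAgentParams(alpha=0.0), 0, cfg)
        agent.observe("a1", 0, 9)
        assert agent.v_state[0] == cfg.walk_midpoint
        assert agent.q_mf["a1"] == cfg.walk_midpoint

    def test_zero_beta_chooses_uniformly(self):
        cfg = SdtConfig()
        agent = hybrid_policy(HybridAgentParams(beta=0.0), 5, cfg)
        picks = [agent.choose("A", ["a1", "a2"]) for _ in range(2000)]
        frac = np.mean([p == "a1" for p in picks])
        assert abs(frac - 0.5) < 0.05

    def test_model_free_agent_values_same_destination_options_independently(self):
        cfg = SdtConfig()
        agent = hybrid_policy(HybridAgentParams(w=0.0, alpha=0.5), 0, cfg)
        agent.observe("a1", 0, 9)  # b1 also leads to state 0
        assert agent.q_mf["a1"] != agent.q_mf["b1"]
        # whereas a fully model-based agent values them identically
        mb = hybrid_policy(HybridAgentParams(w=1.0, alpha=0.5), 0, cfg)
        mb.observe("a1", 0, 9)
        assert mb._net_value("a1") == mb._net_value("b1")


class TestFit:
    def _session(self, w, seed, beta=3.0, alpha=0.5, n_test=200):
        cfg = SdtConfig(n_practice=0, n_test=n_test)
        params = HybridAgentParams(w=w, beta=beta, alpha=alpha)
        return run_sdt(cfg, hybrid_policy(params, seed, cfg), seed)

    def test_too_few_trials_is_an_error(self):
        log = self._session(0.5, 0, n_test=60)
        log.trials = log.trials[:40]
        with pytest.raises(InsufficientDataError):
            fit_hybrid_model(log)

    def test_zero_beta_session_fits_chance_likelihood_and_flags_w(self):
        log = self._session(0.5, 7, beta=0.0)
        fit = fit_hybrid_model(log, n_restarts=8, seed=0)
        n = len(log.test_trials())
        assert fit.log_likelihood <= 0
        assert abs(fit.log_likelihood - n * np.log(0.5)) < 5.0
        assert fit.w_unidentifiable

    def test_fit_is_deterministic_given_log_restarts_and_seed(self):
        log = self._session(0.7, 8)
        a = fit_hybrid_model(log, n_restarts=6, seed=3)
        b = fit_hybrid_model(log, n_restarts=6, seed=3)
        assert (a.w_hat, a.beta_hat, a.alpha_hat) == (b.w_hat, b.beta_hat, b.alpha_hat)

    def test_brute_force_grid_never_beats_the_mle(self):
        log = self._session(0.6, 9)
        fit = fit_hybrid_model(log, n_restarts=8, seed=0)
        grid_best = min(
            hybrid_nll(log, w, beta, alpha)
            for w in np.linspace(0, 1, 9)
            for beta in np.linspace(0, 10, 9)
            for alpha in np.linspace(0, 1, 9)
        )
        assert -fit.log_likelihood <= grid_best + 1e-6

    def test_practice_trials_warm_the_state_but_add_no_likelihood(self):
        cfg = SdtConfig()  # 25 practice + 125 test
        params = HybridAgentParams(w=0.8, beta=3.0, alpha=0.5)
        log = run_sdt(cfg, hybrid_policy(params, 10, cfg), 10)
        fit = fit_hybrid_model(log, n_restarts=6, seed=0)
        assert fit.n_trials == 125
        # chance likelihood on 125 trials bounds the fitted one from below
        assert fit.log_likelihood >= 125 * np.log(0.5) - 1e-9

    def test_model_face_reports_params_and_standard_errors(self):
        log = self._session(0.5, 12)
        res = HybridRLModel(log).fit(n_restarts=6, seed=0)
        assert set(res.params) == {"w", "beta", "alpha"}
        assert "log-likelihood" in res.summary()
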