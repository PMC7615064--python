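"""Experiential discounting engine and hyperbolic k estimation."""
import numpy as np
import pytest

from cogbat import (
    DdtConfig, DiscounterParams, HyperbolicDiscountingModel, estimate_k,
    hyperbolic_policy, indifference_k, run_ddt, score_ddt,
)
from cogbat.agents import hyperbolic_value
from cogbat.errors import ConfigurationError, DegenerateDesignError


def always(choice):
    return lambda ss_a, ss_d, ll_a, ll_d: choice


class TestEngine:
    def test_delays_are_distance_over_speed(self):
        cfg = DdtConfig(n_trials=1, option_pairs=[(5, 2, 9, 10)], travel_speed=1.0)
        log = run_ddt(cfg, always("larger_later"), 0)
        t = log.trials[0]
        assert (t.ss_delay, t.ll_delay) == (2.0, 10.0)
        assert t.coins_earned == 9.0 and t.time_spent == 10.0

    def test_larger_later_choice_earns_the_ll_amount(self):
        log = run_ddt(DdtConfig(), always("larger_later"), 1)
        for t in log.trials:
            assert t.coins_earned == t.ll_amount

    def test_zero_k_agent_always_prefers_larger_later(self):
        agent = hyperbolic_policy(DiscounterParams(true_k=0.0,
                                                   choice_temperature=np.inf))
        log = run_ddt(DdtConfig(), agent, 2)
        assert all(t.choice == "larger_later" for t in log.trials)

    def test_session_truncates_at_the_time_budget(self):
        cfg = DdtConfig(time_budget=25.0)
        log = run_ddt(cfg, always("larger_later"), 3)
        assert len(log.trials) < cfg.n_trials
        assert sum(t.time_spent for t in log.trials) <= 25.0

    def test_default_sessions_have_sixty_trials(self):
        log = run_ddt(DdtConfig(), always("smaller_sooner"), 4)
        assert len(log.trials) == 60

    def test_nonpositive_speed_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            DdtConfig(travel_speed=0.0)


class TestHyperbolicValue:
    def test_printed_item_indifference_point(self):
        # 52 now vs 80 at delay 50: indifference at k = (80/52 - 1)/50
        k_star = indifference_k(52, 80, 50)
        assert k_star == pytest.approx(0.010769, abs=1e-6)
        assert float(hyperbolic_value(80, 50, k_star)) == pytest.approx(52.0)
        # bisection oracle on V(80, 50, k) = 52
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if 80 / (1 + mid * 50) > 52:
                lo = mid
            else:
                hi = mid
        assert k_star == pytest.approx(lo, abs=1e-10)

    def test_deterministic_chooser_switches_preference_at_indifference(self):
        k_star = indifference_k(52, 80, 50)
        for k, expected in ((k_star * 0.8, "larger_later"),
                            (k_star * 1.2, "smaller_sooner")):
            agent = hyperbolic_policy(
                DiscounterParams(true_k=k, choice_temperature=np.inf))
            assert agent(52, 0.0, 80, 50.0) == expected


class TestEstimateK:
    def _session(self, k, seed, temp=5.0):
        agent = hyperbolic_policy(
            DiscounterParams(true_k=k, choice_temperature=temp), seed)
        return run_ddt(DdtConfig(), agent, seed)

    def test_one_sided_choices_hit_the_boundary_with_a_flag(self):
        trials = [(5, 1.0, 9, 10.0, "larger_later")] * 12
        m = estimate_k(trials)
        assert m.k_hat == 0.0
        assert m.prop_smaller_sooner == 0.0
        assert m.boundary == "all_larger_later"
        ss = [(5, 1.0, 9, 10.0, "smaller_sooner")] * 12
        assert estimate_k(ss).boundary == "all_smaller_sooner"

    def test_identical_options_are_a_degenerate_design(self):
        trials = [(5, 1.0, 5, 1.0, "larger_later")] * 12
        with pytest.raises(DegenerateDesignError):
            estimate_k(trials)

    def test_recovery_within_a_factor_of_1_5(self):
        log = self._session(0.05, 11)
        m = score_ddt(log)
        assert 0.05 / 1.5 <= m.k_hat <= 0.05 * 1.5

    def test_grid_oracle_never_beats_the_returned_mle(self):
        log = self._session(0.08, 21)
        trials = [(t.ss_amount, t.ss_delay, t.ll_amount, t.ll_delay, t.choice)
                  for t in log.trials]
        m = estimate_k(trials)

        # independent brute-force likelihood over a dense (k, tau) grid
        def nll_oracle(k, tau):
            total = 0.0
            for ss_a, ss_d, ll_a, ll_d, choice in trials:
                dv = ll_a / (1 + k * ll_d) - ss_a / (1 + k * ss_d)
                p_ll = 1.0 / (1.0 + np.exp(-tau * dv))
                p = p_ll if choice == "larger_later" else 1 - p_ll
                total -= np.log(max(p, 1e-300))
            return total

        best = min(
            nll_oracle(k, tau)
            for k in np.geomspace(1e-4, 10, 200)
            for tau in np.geomspace(0.01, 100, 100)
        )
        assert -m.log_likelihood <= best + 1e-6

    def test_total_coins_and_proportion_match_the_choices(self):
        trials = [(5, 1.0, 9, 10.0, "smaller_sooner"),
                  (5, 1.0, 9, 10.0, "larger_later")] * 6
        m = estimate_k(trials)
        assert m.total_coins == 6 * 5 + 6 * 9
        assert m.prop_smaller_sooner == 0.5


class TestModelFace:
    def test_results_summary_reports_the_fit(self):
        agent = hyperbolic_policy(
            DiscounterParams(true_k=0.05, choice_temperature=5.0), 31)
        log = run_ddt(DdtConfig(), agent, 31)
        res = HyperbolicDiscountingModel.from_session(log).fit()
        assert res.k == pytest.approx(score_ddt(log).k_hat)
        text = res.summary()
        assert "k (per second)" in text and "log-likelihood" in text
        assert np.isfinite(res.bse["log10_k"])
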