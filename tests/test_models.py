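import math

import numpy as np
import pytest

from conftest import make_log
from gamblearn import models, task
from gamblearn.models import (MODELS, AgentPolicy, evidence, get_model,
                              p_gamble, scale_number, session_loglik,
                              session_loglik_batch, simulate_agent, update_q)

PARAMS6 = dict(bias=0.2, beta_number=1.0, beta_value=2.0,
               eta_pos=0.5, eta_neg=0.3)


def hand_rolled_loglik(params, trials):
    """Straight-line reference likelihood for the adjusted & asymmetric
    model on a list of (deck, N, choice, outcome) tuples; written
    independently of the package's update/evidence helpers."""
    q = {"low": 0.0, "even": 0.0, "high": 0.0}
    total = 0.0
    for deck, n, choice, outcome in trials:
        nsc = (5.0 - n) / 4.0
        ev = params["bias"] + params["beta_number"] * nsc \
            + params["beta_value"] * q[deck]
        p = 1.0 / (1.0 + math.exp(-ev))
        total += math.log(p if choice == 1 else 1.0 - p)
        if choice == 1:
            delta = outcome - q[deck] - nsc
            eta = params["eta_pos"] if outcome == 1 else params["eta_neg"]
            q[deck] += eta * delta
    return total


class TestRegistry:
    def test_parameter_lists(self):
        assert MODELS[1].params == ("bias",)
        assert MODELS[2].params == ("bias", "beta_number")
        assert MODELS[3].params == ("bias", "beta_number", "beta_value",
                                    "eta")
        assert MODELS[5].params == ("bias", "beta_number", "beta_value",
                                    "eta_pos", "eta_neg")
        assert MODELS[8].params == ("bias", "beta_number", "beta_value",
                                    "eta_pos", "eta_neg", "rho_pos",
                                    "rho_neg")
        assert MODELS[4].adjusted_pe and not MODELS[3].adjusted_pe
        assert MODELS[7].asymmetric_sensitivity
        assert not MODELS[7].asymmetric_lr

    def test_lookup_by_name_and_id(self):
        assert get_model("adjusted_asymmetric") is MODELS[6]
        assert get_model(2) is MODELS[2]
        assert get_model(MODELS[3]) is MODELS[3]

    def test_param_validation(self):
        with pytest.raises(ValueError, match="needs parameter"):
            models.validate_params(MODELS[3], {"bias": 0.0})
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            models.validate_params(
                MODELS[3], dict(bias=0, beta_number=1, beta_value=1,
                                eta=1.2))


class TestEvidence:
    def test_scaled_number_endpoints(self):
        assert scale_number(1) == 1.0
        assert scale_number(9) == -1.0
        assert scale_number(5) == 0.0

    def test_bias_only_model(self):
        q = np.zeros(3)
        assert evidence(MODELS[1], {"bias": 0.0}, q, "even", 7) == 0.0

    def test_number_model_endpoint(self):
        q = np.zeros(3)
        e = evidence(MODELS[2], {"bias": 0.0, "beta_number": 1.0}, q,
                     "even", 1)
        assert e == 1.0

    def test_full_model_arithmetic(self):
        q = np.zeros(3)
        q[task.DECK_LABELS.index("high")] = 0.25
        e = evidence(MODELS[6], dict(bias=0.2, beta_number=1.0,
                                     beta_value=2.0, eta_pos=0.5,
                                     eta_neg=0.5), q, "high", 5)
        assert e == pytest.approx(0.7)

    def test_unknown_deck_rejected(self):
        with pytest.raises(ValueError, match="unknown deck"):
            evidence(MODELS[1], {"bias": 0.0}, np.zeros(3), "red", 5)

    def test_logistic_choice_rule(self):
        assert p_gamble(0.0) == 0.5
        assert p_gamble(math.log(3)) == pytest.approx(0.75)
        evs = np.linspace(-30, 30, 101)
        ps = p_gamble(evs)
        assert np.all(np.diff(ps) > 0) and np.all((ps > 0) & (ps < 1))


class TestUpdate:
    def test_zero_learning_rate_freezes_q(self):
        q = np.array([0.3, -0.2, 0.5])
        params = dict(bias=0, beta_number=1, beta_value=1, eta=0.0)
        out = update_q(MODELS[3], params, q, "low", 4, 1)
        assert np.array_equal(out, q)

    def test_plain_q_learning_step(self):
        params = dict(bias=0, beta_number=1, beta_value=1, eta=0.5)
        out = update_q(MODELS[3], params, np.zeros(3), "even", 5, 1)
        assert out[task.DECK_LABELS.index("even")] == pytest.approx(0.5)

    def test_adjusted_win_against_easiest_number_teaches_nothing(self):
        params = dict(bias=0, beta_number=1, beta_value=1, eta_pos=0.5,
                      eta_neg=0.5)
        out = update_q(MODELS[6], params, np.zeros(3), "even", 1, 1)
        assert np.all(out == 0.0)

    def test_sensitivity_scales_outcome(self):
        params = dict(bias=0, beta_number=1, beta_value=1, eta=0.5,
                      rho_pos=2.0, rho_neg=1.0)
        out = update_q(MODELS[7], params, np.zeros(3), "even", 5, 1)
        # delta = 2*1 - 0 - 0, eta 0.5
        assert out[task.DECK_LABELS.index("even")] == pytest.approx(1.0)

    def test_invalid_outcome_rejected(self):
        params = dict(bias=0, beta_number=1, beta_value=1, eta=0.5)
        with pytest.raises(ValueError):
            update_q(MODELS[3], params, np.zeros(3), "even", 5, 0)


class TestSessionLoglik:
    def test_unbiased_coin_model(self, model6_log):
        ll = session_loglik(1, {"bias": 0.0}, model6_log)
        assert ll == pytest.approx(180 * math.log(0.5))

    def test_matches_hand_rolled_oracle(self):
        trials = [("even", 5, 1, 1), ("even", 2, 1, -1), ("high", 7, 0, 1),
                  ("high", 3, 1, 1), ("low", 8, 0, -1), ("even", 5, 1, -1)]
        log = make_log(trials)
        assert session_loglik(6, PARAMS6, log) == pytest.approx(
            hand_rolled_loglik(PARAMS6, trials), abs=1e-12)

    def test_finite_and_nonpositive(self, model6_log):
        ll = session_loglik(6, PARAMS6, model6_log)
        assert -np.inf < ll <= 0.0

    def test_miss_trials_excluded(self):
        log = make_log([("even", 5, 1, 1), ("low", 3, task.MISS, -1),
                        ("high", 7, 0, 1)])
        visible = [("even", 5, 1, 1), ("high", 7, 0, 1)]
        assert session_loglik(6, PARAMS6, log) == pytest.approx(
            hand_rolled_loglik(PARAMS6, visible), abs=1e-12)

    def test_malformed_log_rejected(self):
        log = make_log([("even", 5, 1, 1), ("even", 4, 0, 1)])
        object.__setattr__(log.trials[1], "outcome_shown", True)
        with pytest.raises(ValueError, match="declined"):
            session_loglik(6, PARAMS6, log)

    @pytest.mark.parametrize("mid", sorted(MODELS))
    def test_batch_agrees_with_scalar(self, mid, model6_log, rng):
        spec = MODELS[mid]
        S = 7
        samples = {}
        for name in spec.params:
            fam = models.PARAM_FAMILIES[name]
            if fam == "beta":
                samples[name] = rng.uniform(0, 1, S)
            elif fam == "normal":
                samples[name] = rng.normal(0, 1, S)
            else:
                samples[name] = rng.gamma(2, 1, S)
        batch = session_loglik_batch(spec, samples, model6_log)
        for s in range(S):
            single = session_loglik(
                spec, {k: float(v[s]) for k, v in samples.items()},
                model6_log)
            assert batch[s] == pytest.approx(single, abs=1e-9)


class TestNesting:
    """Smaller models are exact special cases of larger ones."""

    def test_asymmetric_collapses_to_symmetric(self, model6_log):
        for sym, asym in [(3, 5), (4, 6)]:
            p_sym = dict(bias=0.3, beta_number=1.5, beta_value=2.0, eta=0.4)
            p_asym = {**{k: v for k, v in p_sym.items() if k != "eta"},
                      "eta_pos": 0.4, "eta_neg": 0.4}
            assert session_loglik(sym, p_sym, model6_log) == pytest.approx(
                session_loglik(asym, p_asym, model6_log), abs=1e-12)

    def test_number_weight_zero_collapses_to_bias(self, model6_log):
        a = session_loglik(2, {"bias": 0.4, "beta_number": 0.0}, model6_log)
        b = session_loglik(1, {"bias": 0.4}, model6_log)
        assert a == pytest.approx(b, abs=1e-12)

    def test_unit_sensitivity_collapses_to_plain_asymmetric(self,
                                                            model6_log):
        p6 = dict(bias=0.1, beta_number=1.0, beta_value=2.0, eta_pos=0.6,
                  eta_neg=0.2)
        p8 = {**p6, "rho_pos": 1.0, "rho_neg": 1.0}
        assert session_loglik(6, p6, model6_log) == pytest.approx(
            session_loglik(8, p8, model6_log), abs=1e-12)


class TestSimulation:
    def test_q_bounds(self, decks):
        r = np.random.default_rng(7)
        for mid, bound in [(3, 1.0), (5, 1.0), (4, 2.0), (6, 2.0)]:
            spec = MODELS[mid]
            params = dict(bias=0.0, beta_number=1.0, beta_value=2.0)
            if spec.asymmetric_lr:
                params.update(eta_pos=0.95, eta_neg=0.9)
            else:
                params["eta"] = 0.95
            pol = AgentPolicy(spec, params, record_q=True)
            task.generate_session(decks, pol, r)
            qs = np.array(pol.q_trace)
            assert np.all(np.abs(qs) <= bound + 1e-12)

    def test_declined_trials_never_update_q(self, decks):
        r = np.random.default_rng(11)
        pol = AgentPolicy(6, PARAMS6, record_q=True)
        log = task.generate_session(decks, pol, r)
        n_gambles = sum(t.choice == 1 for t in log.trials)
        assert len(pol.q_trace) == n_gambles

    def test_loglik_self_consistency_roundtrip(self, decks):
        # replaying the simulated choices through the likelihood reproduces
        # the per-trial probabilities the agent actually used
        r = np.random.default_rng(13)
        log = simulate_agent(6, PARAMS6, decks=decks, rng=r)
        replay = AgentPolicy(6, PARAMS6)
        total = 0.0
        for t in log.trials:
            p = replay.p_gamble(t.deck, t.computer_number)
            total += math.log(p if t.choice == 1 else 1.0 - p)
            if t.choice == 1:
                replay.observe(t.deck, t.computer_number, t.outcome)
        assert session_loglik(6, PARAMS6, log) == pytest.approx(total,
                                                                abs=1e-9)

    def test_number_weight_controls_hard_gambles(self, decks):
        r = np.random.default_rng(17)
        params = dict(bias=0.0, beta_number=8.0)
        log = simulate_agent(2, params, decks=decks, rng=r)
        hard = [t.choice for t in log.trials if t.computer_number == 9]
        assert np.mean(hard) < 0.05

    def test_learning_separates_decks(self, decks):
        # adjusted & asymmetric agents come to gamble more with the high
        # deck than the low deck by the final block
        r = np.random.default_rng(19)
        by_deck = {"low": [], "high": []}
        for _ in range(12):
            log = simulate_agent(6, dict(bias=0.0, beta_number=2.0,
                                         beta_value=3.0, eta_pos=0.35,
                                         eta_neg=0.35), decks=decks, rng=r)
            for t in log.trials:
                if t.block == 3 and t.deck in by_deck:
                    by_deck[t.deck].append(t.choice)
        assert np.mean(by_deck["high"]) > np.mean(by_deck["low"]) + 0.15
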