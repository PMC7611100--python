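"""Rescorla-Wagner family: updates, biased softmax, likelihoods."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import selearn as sl
from selearn.errors import ParameterError


def make_params(**kw):
    base = dict(variant="general_1l", lambdas={"lam": 0.5}, tau=1.0, rho=0.0, q0_pos=0.0)
    base.update(kw)
    return sl.AssocParams(**base)


PERSONA_SELF = sl.default_personas()[0]
PERSONA_OTHER = sl.default_personas()[3]


def trial(choice="positive", outcome="positive", persona=0, pid="p"):
    return sl.TrialRecord(pid, persona, 0, choice, outcome, int(choice == outcome))


class TestSelectLambda:
    def test_asymmetric_3l_other_shared(self):
        p = sl.AssocParams(
            variant="selfother_asym_3l",
            lambdas={"lam_self_pos": 0.1, "lam_self_neg": 0.2, "lam_other": 0.3},
            tau=1.0,
        )
        assert sl.select_lambda(p, "other", "positive") == 0.3
        assert sl.select_lambda(p, "other", "negative") == 0.3
        assert sl.select_lambda(p, "self", "positive") == 0.1
        assert sl.select_lambda(p, "self", "negative") == 0.2

    def test_general_single_rate(self):
        p = make_params()
        for ref in ("self", "other"):
            for val in ("positive", "negative"):
                assert sl.select_lambda(p, ref, val) == 0.5

    def test_4l_distinct_slots(self):
        p = sl.AssocParams(
            variant="selfother_4l",
            lambdas={
                "lam_self_pos": 0.1, "lam_self_neg": 0.2,
                "lam_other_pos": 0.3, "lam_other_neg": 0.4,
            },
            tau=1.0,
        )
        got = {
            (r, v): sl.select_lambda(p, r, v)
            for r in ("self", "other") for v in ("positive", "negative")
        }
        assert len(set(got.values())) == 4

    def test_wrong_lambda_keys_rejected(self):
        with pytest.raises(ParameterError):
            sl.AssocParams(variant="valence_2l", lambdas={"lam": 0.5}, tau=1.0)


class TestUpdate:
    def test_prediction_error_arithmetic(self):
        p = make_params()
        state = sl.AssocState.initial(p)
        new, trace = sl.assoc_update(state, trial(), p, PERSONA_SELF)
        assert trace.pe == 1.0
        assert trace.q_after == 0.5
        assert new.q[0, 1] == 0.5

    @pytest.mark.parametrize("lam,expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_learning_rate_limits(self, lam, expected):
        p = make_params(lambdas={"lam": lam})
        state = sl.AssocState.initial(p)
        new, _ = sl.assoc_update(state, trial(), p, PERSONA_SELF)
        assert new.q[0, 1] == expected  # r=1: full replacement / no learning

    def test_only_chosen_action_and_context_change(self):
        p = make_params(q0_pos=0.3)
        state = sl.AssocState.initial(p)
        new, _ = sl.assoc_update(state, trial(choice="negative", outcome="negative"), p, PERSONA_SELF)
        changed = new.q != state.q
        assert changed.sum() == 1 and changed[0, 0]

    def test_trace_consistency(self):
        p = make_params(lambdas={"lam": 0.37}, q0_pos=0.4)
        state = sl.AssocState.initial(p)
        _, tr = sl.assoc_update(state, trial(outcome="negative", choice="positive"), p, PERSONA_SELF)
        assert tr.q_after - tr.q_before == pytest.approx(tr.lambda_used * tr.pe)


class TestChoiceProbability:
    def test_symmetric_values_give_half(self):
        p = make_params()
        state = sl.AssocState.initial(p)
        assert sl.assoc_choice_probability(state, p, PERSONA_SELF).p_positive == pytest.approx(0.5)

    def test_two_term_softmax_value(self):
        # Q(+)=1, Q(-)=0, rho=0, tau=1: p = 1/(1+e^-1)
        p = make_params(q0_pos=1.0)
        state = sl.AssocState.initial(p)
        dist = sl.assoc_choice_probability(state, p, PERSONA_SELF)
        assert dist.p_positive == pytest.approx(0.7310586, abs=1e-5)
        assert dist.p_positive == pytest.approx(0.73106, abs=1e-5)

    def test_rho_additive_with_q(self):
        a = make_params(q0_pos=0.0, rho=0.5)
        b = make_params(q0_pos=0.5, rho=0.0)
        da = sl.assoc_choice_probability(sl.AssocState.initial(a), a, PERSONA_SELF)
        db = sl.assoc_choice_probability(sl.AssocState.initial(b), b, PERSONA_SELF)
        assert da.p_positive == pytest.approx(db.p_positive, abs=1e-12)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ParameterError):
            make_params(tau=0.0)

    @given(
        q=st.floats(-5, 5), shift=st.floats(-10, 10),
        rho=st.floats(-2, 2), tau=st.floats(0.05, 10),
    )
    @settings(max_examples=60, deadline=None)
    def test_policy_invariant_to_common_shift(self, q, shift, rho, tau):
        p = make_params(rho=rho, tau=tau)
        s1 = sl.AssocState.initial(p)
        s1.q[0] = [0.0, q]
        s2 = sl.AssocState.initial(p)
        s2.q[0] = [shift, q + shift]
        d1 = sl.assoc_choice_probability(s1, p, PERSONA_SELF)
        d2 = sl.assoc_choice_probability(s2, p, PERSONA_SELF)
        assert d1.p_positive == pytest.approx(d2.p_positive, rel=1e-9)
        assert d1.p_positive + d1.p_negative == pytest.approx(1.0)


class TestLogLikelihood:
    def test_uninformative_policy_limit(self, assoc_sessions):
        p = make_params(tau=1e6)
        tot, vec = sl.assoc_log_likelihood(p, assoc_sessions[0])
        assert tot == pytest.approx(192 * math.log(0.5), rel=1e-6)
        assert len(vec) == 192

    def test_hand_rolled_five_trial_sequence(self):
        # independent brute-force recursion of the update and softmax rules
        lam, tau, rho, q0 = 0.4, 0.5, 0.2, 0.3
        p = make_params(lambdas={"lam": lam}, tau=tau, rho=rho, q0_pos=q0)
        choices = ["positive", "negative", "positive", "positive", "negative"]
        outcomes = ["positive", "positive", "negative", "positive", "negative"]
        trials = [
            sl.TrialRecord("p", 0, t, c, o, int(c == o))
            for t, (c, o) in enumerate(zip(choices, outcomes))
        ]
        session = sl.SessionData("p", 30.0, [trials])

        qp, qn = q0, 0.0
        expected = 0.0
        for c, o in zip(choices, outcomes):
            ppos = 1.0 / (1.0 + math.exp(-((qp + rho) - qn) / tau))
            expected += math.log(ppos if c == "positive" else 1 - ppos)
            r = 1 if c == o else 0
            if c == "positive":
                qp += lam * (r - qp)
            else:
                qn += lam * (r - qn)
        tot, vec = sl.assoc_log_likelihood(p, session)
        assert tot == pytest.approx(expected, abs=1e-10)
        assert vec.sum() == pytest.approx(tot, abs=1e-10)

    def test_beats_coin_flip_on_own_data(self, assoc_params, schedule_cfg):
        rng = np.random.default_rng(5)
        wins = 0
        n = 50
        for i in range(n):
            sess = sl.simulate_session(sl.AssocAgent(assoc_params), schedule_cfg, rng, f"p{i}", 30.0)
            tot, _ = sl.assoc_log_likelihood(assoc_params, sess)
            coin = 192 * math.log(0.5)
            wins += tot > coin
        assert wins > n / 2

    @given(
        lam=st.floats(0.0, 1.0), q0=st.floats(-1.0, 2.0),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=30, deadline=None)
    def test_q_values_bounded(self, lam, q0, seed):
        # each update is a convex combination of Q and r in {0, 1}
        p = make_params(lambdas={"lam": lam}, q0_pos=q0)
        rng = np.random.default_rng(seed)
        agent = sl.AssocAgent(p)
        sess = sl.simulate_session(agent, sl.ScheduleConfig(trials_per_block=16), rng)
        lo, hi = min(0.0, q0), max(1.0, q0)
        assert np.all(agent.state.q >= lo - 1e-12)
        assert np.all(agent.state.q <= hi + 1e-12)
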