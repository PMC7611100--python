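"""Belief-update family: trait/state evidence, decay, mean-belief policy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import selearn as sl
from selearn.errors import DegenerateBeliefError, ParameterError

PERSONA_SELF = sl.default_personas()[0]


def shared(alpha=1.0, beta=1.0, eta=1.0, tau=0.5, ai=0.0, bi=0.0):
    return sl.BeliefParams.shared(alpha, beta, eta, tau, alpha_init=ai, beta_init=bi)


def trial(outcome, persona=0, choice="positive"):
    return sl.TrialRecord("p", persona, 0, choice, outcome, int(choice == outcome))


class TestUpdate:
    def test_no_decay_counts_outcomes(self):
        p = shared(eta=1.0)
        state = sl.BeliefState.initial(p)
        for o in ("positive", "positive", "negative"):
            state = sl.belief_update(state, trial(o), p, PERSONA_SELF)
        assert state.alpha_state[0] == 2.0
        assert state.beta_state[0] == 1.0

    def test_decay_then_increment(self):
        p = shared(eta=0.5)
        state = sl.BeliefState.initial(p)
        state.alpha_state[0], state.beta_state[0] = 2.0, 1.0
        state = sl.belief_update(state, trial("positive"), p, PERSONA_SELF)
        assert state.alpha_state[0] == pytest.approx(2.0)
        assert state.beta_state[0] == pytest.approx(0.5)

    def test_geometric_fixed_point(self):
        # constant stream: total state evidence converges to 1 / (1 - eta)
        p = shared(eta=0.9)
        state = sl.BeliefState.initial(p)
        for _ in range(300):
            state = sl.belief_update(state, trial("positive"), p, PERSONA_SELF)
        assert state.alpha_state[0] + state.beta_state[0] == pytest.approx(10.0, rel=1e-6)

    def test_state_evidence_bounded_by_capacity(self):
        p = shared(eta=0.7)
        state = sl.BeliefState.initial(p)
        rng = np.random.default_rng(0)
        bound = 1.0 / (1.0 - 0.7)
        for _ in range(200):
            o = "positive" if rng.random() < 0.5 else "negative"
            state = sl.belief_update(state, trial(o), p, PERSONA_SELF)
            assert state.alpha_state[0] + state.beta_state[0] <= bound + 1e-9

    def test_other_contexts_untouched(self):
        p = shared(eta=0.5, ai=1.0, bi=1.0)
        state = sl.BeliefState.initial(p)
        new = sl.belief_update(state, trial("positive", persona=2), p, PERSONA_SELF)
        for s in (0, 1, 3, 4, 5):
            assert new.alpha_state[s] == state.alpha_state[s]
            assert new.beta_state[s] == state.beta_state[s]


class TestSummaryAndChoice:
    def test_trait_only_mean(self):
        p = shared(alpha=8.0, beta=2.0)
        state = sl.BeliefState.initial(p)
        s = sl.belief_summary(p, state, PERSONA_SELF)
        assert s.mean_approval == pytest.approx(0.8)
        assert s.total_evidence == pytest.approx(10.0)

    def test_symmetric_belief_is_half(self):
        p = shared(alpha=1.0, beta=1.0, ai=1.0, bi=1.0)
        state = sl.BeliefState.initial(p)
        assert sl.belief_choice_probability(p, state, PERSONA_SELF).p_positive == pytest.approx(0.5)

    def test_mean_softmax_closed_form(self):
        # p=0.8, tau=0.1: gap (0.8-0.2)/0.1 = 6 -> 1/(1+e^-6)
        p = shared(alpha=8.0, beta=2.0, tau=0.1)
        state = sl.BeliefState.initial(p)
        dist = sl.belief_choice_probability(p, state, PERSONA_SELF)
        assert dist.p_positive == pytest.approx(1.0 / (1.0 + math.exp(-6.0)), abs=1e-7)
        assert dist.p_positive == pytest.approx(0.99753, abs=1e-5)

    def test_noise_dominated_limit(self):
        p = shared(alpha=9.0, beta=1.0, tau=1e6)
        state = sl.BeliefState.initial(p)
        assert sl.belief_choice_probability(p, state, PERSONA_SELF).p_positive == pytest.approx(0.5, abs=1e-6)

    def test_mean_tracks_outcome_frequency_with_full_memory(self):
        # with eta=1 the state accumulates exact counts; trait washes out
        p = shared(alpha=5.0, beta=5.0, eta=1.0)
        state = sl.BeliefState.initial(p)
        rng = np.random.default_rng(3)
        freq = 0.8
        n = 4000
        for _ in range(n):
            o = "positive" if rng.random() < freq else "negative"
            state = sl.belief_update(state, trial(o), p, PERSONA_SELF)
        s = sl.belief_summary(p, state, PERSONA_SELF)
        assert s.mean_approval == pytest.approx(freq, abs=0.03)

    def test_degenerate_belief(self):
        p = shared(alpha=0.0, beta=0.0)
        state = sl.BeliefState.initial(p)
        with pytest.raises(DegenerateBeliefError):
            sl.belief_summary(p, state, PERSONA_SELF).mean_approval
        # simulation path warns and uses 0.5; fitting path raises
        with pytest.warns(RuntimeWarning):
            d = sl.belief_choice_probability(p, state, PERSONA_SELF)
        assert d.p_positive == 0.5
        with pytest.raises(DegenerateBeliefError):
            sl.belief_choice_probability(p, state, PERSONA_SELF, strict=True)

    def test_invalid_tau(self):
        with pytest.raises(ParameterError):
            shared(tau=-1.0)

    def test_uncertainty_scaled_link_hook(self):
        # non-canonical alternative: thin evidence pushes choice toward 0.5
        import dataclasses

        p_mean = shared(alpha=1.6, beta=0.4, tau=0.2)
        p_unc = dataclasses.replace(p_mean, link="uncertainty_scaled")
        d_mean = sl.belief_choice_probability(p_mean, sl.BeliefState.initial(p_mean), PERSONA_SELF)
        d_unc = sl.belief_choice_probability(p_unc, sl.BeliefState.initial(p_unc), PERSONA_SELF)
        assert 0.5 < d_unc.p_positive < d_mean.p_positive
        # gap scaled by N/(N+1) with N=2
        expected = 1 / (1 + math.exp(-(2 * 0.8 - 1) * (2 / 3) / 0.2))
        assert d_unc.p_positive == pytest.approx(expected, abs=1e-12)
        with pytest.raises(ParameterError):
            dataclasses.replace(p_mean, link="nonsense")

    @given(c=st.floats(0.1, 50.0), a=st.floats(0.2, 20.0), b=st.floats(0.2, 20.0))
    @settings(max_examples=50, deadline=None)
    def test_choice_invariant_to_evidence_scaling(self, c, a, b):
        # policy depends on the mean only
        p1 = shared(alpha=a, beta=b, tau=0.3)
        p2 = shared(alpha=c * a, beta=c * b, tau=0.3)
        d1 = sl.belief_choice_probability(p1, sl.BeliefState.initial(p1), PERSONA_SELF)
        d2 = sl.belief_choice_probability(p2, sl.BeliefState.initial(p2), PERSONA_SELF)
        assert d1.p_positive == pytest.approx(d2.p_positive, rel=1e-9)


class TestConjugateOracle:
    def test_eta_one_matches_beta_bernoulli_posterior(self):
        # with eta=1 and zero initial state the totals equal the pseudo-counts
        # of a conjugate Beta(alpha_trait, beta_trait) posterior
        rng = np.random.default_rng(42)
        p = shared(alpha=3.0, beta=2.0, eta=1.0)
        for _ in range(1000):
            n = rng.integers(1, 30)
            outcomes = rng.random(n) < rng.random()
            state = sl.BeliefState.initial(p)
            for o in outcomes:
                state = sl.belief_update(
                    state, trial("positive" if o else "negative"), p, PERSONA_SELF
                )
            s = sl.belief_summary(p, state, PERSONA_SELF)
            assert s.alpha_total == 3.0 + outcomes.sum()
            assert s.beta_total == 2.0 + (~outcomes).sum()


class TestLogLikelihood:
    def test_uninformative_limit(self, belief_sessions):
        p = shared(alpha=2.0, beta=2.0, eta=1.0, tau=1e6)
        tot, vec = sl.belief_log_likelihood(p, belief_sessions[0])
        assert tot == pytest.approx(192 * math.log(0.5), rel=1e-6)

    def test_hand_rolled_five_trial_sequence(self):
        at, bt, eta, tau, ai, bi = 4.0, 2.0, 0.8, 0.3, 0.5, 0.25
        p = shared(alpha=at, beta=bt, eta=eta, tau=tau, ai=ai, bi=bi)
        choices = ["positive", "negative", "positive", "positive", "negative"]
        outcomes = ["positive", "positive", "negative", "positive", "negative"]
        trials = [
            sl.TrialRecord("p", 0, t, c, o, int(c == o))
            for t, (c, o) in enumerate(zip(choices, outcomes))
        ]
        session = sl.SessionData("p", 30.0, [trials])

        a_s, b_s = ai, bi
        expected = 0.0
        for c, o in zip(choices, outcomes):
            m = (at + a_s) / (at + a_s + bt + b_s)
            ppos = 1.0 / (1.0 + math.exp(-(2.0 * m - 1.0) / tau))
            expected += math.log(ppos if c == "positive" else 1.0 - ppos)
            a_s = eta * a_s + (1.0 if o == "positive" else 0.0)
            b_s = eta * b_s + (0.0 if o == "positive" else 1.0)
        tot, vec = sl.belief_log_likelihood(p, session)
        assert tot == pytest.approx(expected, abs=1e-10)
        assert vec.sum() == pytest.approx(tot, abs=1e-10)

    def test_trait_immutable_across_session(self, belief_params, schedule_cfg):
        rng = np.random.default_rng(4)
        agent = sl.BeliefAgent(belief_params)
        before = (dict(belief_params.alpha_trait), dict(belief_params.beta_trait))
        sl.simulate_session(agent, schedule_cfg, rng)
        assert (agent.params.alpha_trait, agent.params.beta_trait) == before


class TestEffectiveLearningRate:
    def test_delta_rule_correspondence(self):
        # one positive outcome moves the mean by (1 - p) / (N + 1)
        s = sl.BeliefSummary(alpha_total=8.0, beta_total=2.0)
        rate = sl.effective_learning_rate(s)
        assert rate == pytest.approx(1.0 / 11.0)
        delta = (8.0 + 1.0) / 11.0 - 0.8
        assert delta == pytest.approx((1.0 - 0.8) * rate)
        assert delta == pytest.approx(0.0181818, abs=1e-6)

    def test_rate_vanishes_with_entrenchment(self):
        rates = [sl.effective_learning_rate(sl.BeliefSummary(n * 0.8, n * 0.2)) for n in (10, 100, 1000)]
        assert rates == sorted(rates, reverse=True)
        assert rates[-1] < 1e-2

    def test_more_positive_trait_means_smaller_negative_update(self):
        # the mechanism behind the positive-self-evidence / negative-learning-rate link
        deltas = []
        for alpha in (2.0, 4.0, 8.0, 16.0):
            beta = 2.0
            p0 = alpha / (alpha + beta)
            p1 = alpha / (alpha + beta + 1.0)  # after one negative outcome
            deltas.append(abs(p1 - p0))
        assert deltas == sorted(deltas, reverse=True)

    def test_degenerate(self):
        with pytest.raises(DegenerateBeliefError):
            sl.effective_learning_rate(sl.BeliefSummary(0.0, 0.0))
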