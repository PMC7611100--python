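"""Associative (Rescorla-Wagner) models of social-evaluation learning.

Participants learn action values Q(action, context) for choosing the positive
or negative word in each persona context. After each trial the chosen action's
value moves toward the feedback by a learning rate times the prediction error:

    PE_t = r_t - Q_{t-1}(a_t, s_t)
    Q_t(a_t, s_t) = Q_{t-1}(a_t, s_t) + lambda_c * PE_t

with feedback r in {0, 1} (correct / incorrect). The learning rate may depend
on the referent (self/other) and on the valence of the trial's correct word,
giving the variants below. Choice follows a softmax over propensities in which
the positive word receives a constant additive "positivity bias" rho:

    P(+) ∝ exp((Q(+, s) + rho) / tau),   P(-) ∝ exp(Q(-, s) / tau)

An initial-bias parameter q0_pos sets the starting value of Q(+, s) in every
context; Q(-, s) starts at 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .task import Persona, SessionData, TrialRecord, N_PERSONAS

#: learning-rate structure of each variant: number of free lambdas
VARIANTS = ("general_1l", "valence_2l", "selfother_asym_3l", "selfother_4l")

#: free lambda names per variant, in canonical order
VARIANT_LAMBDAS = {
    "general_1l": ("lam",),
    "valence_2l": ("lam_pos", "lam_neg"),
    "selfother_asym_3l": ("lam_self_pos", "lam_self_neg", "lam_other"),
    "selfother_4l": (
        "lam_self_pos",
        "lam_self_neg",
        "lam_other_pos",
        "lam_other_neg",
    ),
}

# (referent, valence) -> free-lambda name; referent in {self, other},
# valence is the OUTCOME word's valence.
_LAMBDA_KEY = {
    "general_1l": {
        ("self", "positive"): "lam",
        ("self", "negative"): "lam",
        ("other", "positive"): "lam",
        ("other", "negative"): "lam",
    },
    "valence_2l": {
        ("self", "positive"): "lam_pos",
        ("self", "negative"): "lam_neg",
        ("other", "positive"): "lam_pos",
        ("other", "negative"): "lam_neg",
    },
    "selfother_asym_3l": {
        ("self", "positive"): "lam_self_pos",
        ("self", "negative"): "lam_self_neg",
        ("other", "positive"): "lam_other",
        ("other", "negative"): "lam_other",
    },
    "selfother_4l": {
        ("self", "positive"): "lam_self_pos",
        ("self", "negative"): "lam_self_neg",
        ("other", "positive"): "lam_other_pos",
        ("other", "negative"): "lam_other_neg",
    },
}


@dataclass(frozen=True)
class AssocParams:
    """Per-subject parameters of one associative-model variant.

    ``lambdas`` maps the variant's free learning-rate names to values in [0, 1].
    ``rho`` and ``q0_pos`` are the optional positivity-bias and initial-bias
    parameters; set them to 0.0 to disable.
    """

    variant: str
    lambdas: dict[str, float]
    tau: float
    rho: float = 0.0
    q0_pos: float = 0.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ParameterError(f"unknown associative variant {self.variant!r}")
        expected = set(VARIANT_LAMBDAS[self.variant])
        if set(self.lambdas) != expected:
            raise ParameterError(
                f"variant {self.variant} needs lambdas {sorted(expected)}, "
                f"got {sorted(self.lambdas)}"
            )
        for k, v in self.lambdas.items():
            if not 0.0 <= v <= 1.0 or not math.isfinite(v):
                raise ParameterError(f"learning rate {k}={v} outside [0, 1]")
        if not (self.tau > 0.0) or not math.isfinite(self.tau):
            raise ParameterError(f"decision noise tau must be > 0, got {self.tau}")
        if not (math.isfinite(self.rho) and math.isfinite(self.q0_pos)):
            raise ParameterError("rho and q0_pos must be finite")


@dataclass(frozen=True)
class ChoiceDistribution:
    """Two-point choice distribution over {positive, negative} words."""

    p_positive: float
    p_negative: float
    z: float  # softmax normalisation constant (of max-shifted propensities)

    def __post_init__(self) -> None:
        if abs(self.p_positive + self.p_negative - 1.0) > 1e-9:
            raise ParameterError("choice probabilities must sum to 1")


@dataclass
class AssocState:
    """Q-values per (action, persona context)."""

    q: np.ndarray  # (N_PERSONAS, 2); column 0 = negative action, 1 = positive

    @classmethod
    def initial(cls, params: AssocParams) -> "AssocState":
        q = np.zeros((N_PERSONAS, 2))
        q[:, 1] = params.q0_pos
        return cls(q=q)

    def reset_persona(self, persona_index: int, params: AssocParams) -> None:
        self.q[persona_index, 0] = 0.0
        self.q[persona_index, 1] = params.q0_pos


@dataclass(frozen=True)
class UpdateTrace:
    """Bookkeeping of one prediction-error update."""

    pe: float
    lambda_used: float
    q_before: float
    q_after: float


def select_lambda(params: AssocParams, referent: str, outcome_valence: str) -> float:
    """Learning rate for a (referent, outcome-valence) trial under the variant."""
    return params.lambdas[_LAMBDA_KEY[params.variant][(referent, outcome_valence)]]


def assoc_update(
    state: AssocState,
    trial: TrialRecord,
    params: AssocParams,
    persona: Persona,
) -> tuple[AssocState, UpdateTrace]:
    """Apply one prediction-error update to the chosen action's value.

    Only Q(a_t, s_t) changes; the unchosen action and other contexts are left
    untouched. Returns a new state plus a trace of the update.
    """
    a = 1 if trial.choice == "positive" else 0
    s = trial.persona_index
    lam = select_lambda(params, persona.referent, trial.outcome_valence)
    q_before = float(state.q[s, a])
    pe = trial.feedback - q_before
    q_after = q_before + lam * pe
    q = state.q.copy()
    q[s, a] = q_after
    return AssocState(q=q), UpdateTrace(
        pe=pe, lambda_used=lam, q_before=q_before, q_after=q_after
    )


def _softmax2(u_pos: float, u_neg: float) -> ChoiceDistribution:
    m = max(u_pos, u_neg)
    ep, en = math.exp(u_pos - m), math.exp(u_neg - m)
    z = ep + en
    return ChoiceDistribution(p_positive=ep / z, p_negative=en / z, z=z)


def assoc_choice_probability(
    state: AssocState, params: AssocParams, persona: Persona
) -> ChoiceDistribution:
    """Positivity-biased softmax over the persona's two action values."""
    if not params.tau > 0:
        raise ParameterError("tau must be positive")
    s = persona.index
    return _softmax2(
        (state.q[s, 1] + params.rho) / params.tau, state.q[s, 0] / params.tau
    )


def assoc_log_likelihood(
    params: AssocParams, session: SessionData
) -> tuple[float, np.ndarray]:
    """Log-likelihood of a session's choices under sequential Q-updates.

    Returns the total and the per-trial log-likelihood vector (block by block,
    trial order), as needed for pointwise model comparison. The state is reset
    at each block start.
    """
    state = AssocState.initial(params)
    lls = []
    for block in session.blocks:
        persona = session.personas[block[0].persona_index]
        state.reset_persona(persona.index, params)
        for trial in block:
            dist = assoc_choice_probability(state, params, persona)
            p = dist.p_positive if trial.choice == "positive" else dist.p_negative
            lls.append(math.log(max(p, 1e-300)))
            state, _ = assoc_update(state, trial, params, persona)
    vec = np.asarray(lls)
    return float(vec.sum()), vec


class AssocAgent:
    """Stateful agent wrapper usable with :func:`selearn.task.simulate_session`."""

    def __init__(self, params: AssocParams):
        self.params = params
        self.state = AssocState.initial(params)

    def reset_block(self, persona: Persona) -> None:
        self.state.reset_persona(persona.index, self.params)

    def choice_probability(self, persona: Persona) -> ChoiceDistribution:
        return assoc_choice_probability(self.state, self.params, persona)

    def update(self, trial: TrialRecord) -> None:
        referent = "self" if trial.persona_index < 3 else "other"
        lam = select_lambda(self.params, referent, trial.outcome_valence)
        a = 1 if trial.choice == "positive" else 0
        s = trial.persona_index
        self.state.q[s, a] += lam * (trial.feedback - self.state.q[s, a])
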