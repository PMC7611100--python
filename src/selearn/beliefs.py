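"""Belief-update models: beta-evidence beliefs about each persona's approval.

A participant's belief that a persona approves of the evaluated person is a
beta distribution summarised by positive evidence alpha and negative evidence
beta. The belief has two components: a fixed *trait* part (the self- or
other-schema activated by the context) and a decaying *state* part accumulated
from task feedback:

    alpha_t = alpha_trait + alpha_state_t
    beta_t  = beta_trait  + beta_state_t

Each trial, the state evidence in the active context decays by the memory
parameter eta and the component matching the outcome valence gains one count
(decay-then-increment). The mean approval p = alpha / (alpha + beta) drives a
softmax choice:

    P(+) ∝ exp(p / tau),   P(-) ∝ exp((1 - p) / tau)

so the positive-word propensity is the mean belief and the negative-word
propensity its complement. With eta < 1 the total state evidence is bounded by
1 / (1 - eta), a working-memory capacity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateBeliefError, ParameterError
from .associative import ChoiceDistribution, _softmax2
from .task import Persona, SessionData, TrialRecord, N_PERSONAS

VARIANTS = ("shared", "selfother", "selfother_full")


@dataclass(frozen=True)
class BeliefParams:
    """Per-subject parameters of one belief-update variant.

    ``shared`` uses one (alpha_trait, beta_trait, eta) for both referents;
    ``selfother`` separates trait evidence by referent with a shared eta;
    ``selfother_full`` also separates eta. ``alpha_init``/``beta_init`` seed
    the state evidence at every block start (0 disables the initial bias).
    """

    variant: str
    alpha_trait: dict[str, float]  # referent -> evidence
    beta_trait: dict[str, float]
    eta: dict[str, float]  # referent -> decay in (0, 1]
    tau: float
    alpha_init: float = 0.0
    beta_init: float = 0.0
    #: belief-to-choice link. "mean" is the canonical mean-only softmax; the
    #: "uncertainty_scaled" alternative (NON-CANONICAL, simulation/scalar
    #: likelihood only) shrinks the propensity gap by N/(N+1) so that thin
    #: evidence increases decision variability.
    link: str = "mean"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ParameterError(f"unknown belief variant {self.variant!r}")
        if self.link not in ("mean", "uncertainty_scaled"):
            raise ParameterError(f"unknown belief-to-choice link {self.link!r}")
        for name, d in (("alpha_trait", self.alpha_trait),
                        ("beta_trait", self.beta_trait)):
            for ref in ("self", "other"):
                v = d.get(ref)
                if v is None or v < 0 or not math.isfinite(v):
                    raise ParameterError(f"{name}[{ref!r}] must be >= 0, got {v}")
        for ref in ("self", "other"):
            e = self.eta.get(ref)
            if e is None or not (0.0 < e <= 1.0):
                raise ParameterError(f"eta[{ref!r}] must be in (0, 1], got {e}")
        if self.variant in ("shared", "selfother"):
            if self.eta["self"] != self.eta["other"]:
                raise ParameterError(f"variant {self.variant} shares eta")
        if self.variant == "shared":
            if (self.alpha_trait["self"] != self.alpha_trait["other"]
                    or self.beta_trait["self"] != self.beta_trait["other"]):
                raise ParameterError("variant 'shared' shares trait evidence")
        if not (self.tau > 0 and math.isfinite(self.tau)):
            raise ParameterError(f"tau must be > 0, got {self.tau}")
        if self.alpha_init < 0 or self.beta_init < 0:
            raise ParameterError("initial state evidence must be >= 0")

    @classmethod
    def shared(cls, alpha: float, beta: float, eta: float, tau: float,
               alpha_init: float = 0.0, beta_init: float = 0.0) -> "BeliefParams":
        return cls(
            variant="shared",
            alpha_trait={"self": alpha, "other": alpha},
            beta_trait={"self": beta, "other": beta},
            eta={"self": eta, "other": eta},
            tau=tau,
            alpha_init=alpha_init,
            beta_init=beta_init,
        )


@dataclass
class BeliefState:
    """Decaying state evidence per persona context."""

    alpha_state: np.ndarray  # (N_PERSONAS,)
    beta_state: np.ndarray

    @classmethod
    def initial(cls, params: BeliefParams) -> "BeliefState":
        return cls(
            alpha_state=np.full(N_PERSONAS, params.alpha_init, dtype=float),
            beta_state=np.full(N_PERSONAS, params.beta_init, dtype=float),
        )

    def reset_persona(self, persona_index: int, params: BeliefParams) -> None:
        self.alpha_state[persona_index] = params.alpha_init
        self.beta_state[persona_index] = params.beta_init


@dataclass(frozen=True)
class BeliefSummary:
    """Total belief (trait + state) in one context."""

    alpha_total: float
    beta_total: float

    @property
    def total_evidence(self) -> float:
        return self.alpha_total + self.beta_total

    @property
    def mean_approval(self) -> float:
        n = self.total_evidence
        if n <= 0:
            raise DegenerateBeliefError("mean of a zero-evidence belief is undefined")
        return self.alpha_total / n


def belief_update(
    state: BeliefState, trial: TrialRecord, params: BeliefParams, persona: Persona
) -> BeliefState:
    """Decay-then-increment the state evidence in the trial's context.

    Trait evidence never changes; contexts other than the trial's are untouched
    (blocks are contiguous per persona, so decaying only the active context is
    equivalent to within-block decay).
    """
    s = trial.persona_index
    eta = params.eta[persona.referent]
    a = state.alpha_state.copy()
    b = state.beta_state.copy()
    pos = trial.outcome_valence == "positive"
    a[s] = eta * a[s] + (1.0 if pos else 0.0)
    b[s] = eta * b[s] + (0.0 if pos else 1.0)
    return BeliefState(alpha_state=a, beta_state=b)


def belief_summary(
    params: BeliefParams, state: BeliefState, persona: Persona
) -> BeliefSummary:
    """Total belief in a context: trait plus current state evidence."""
    s = persona.index
    summary = BeliefSummary(
        alpha_total=params.alpha_trait[persona.referent] + float(state.alpha_state[s]),
        beta_total=params.beta_trait[persona.referent] + float(state.beta_state[s]),
    )
    return summary


def _mean_or_half(summary: BeliefSummary, strict: bool) -> float:
    if summary.total_evidence <= 0:
        if strict:
            raise DegenerateBeliefError(
                "belief with zero total evidence in likelihood evaluation"
            )
        warnings.warn(
            "zero-evidence belief: using mean approval 0.5", RuntimeWarning
        )
        return 0.5
    return summary.mean_approval


def belief_choice_probability(
    params: BeliefParams,
    state: BeliefState,
    persona: Persona,
    strict: bool = False,
) -> ChoiceDistribution:
    """Mean-belief softmax: propensities p / tau and (1 - p) / tau.

    With ``params.link == "uncertainty_scaled"`` (non-canonical hook) both
    propensities are shrunk by N / (N + 1), so uncertain beliefs choose more
    variably; the canonical mean-only link is the default and the only one the
    fitting kernels implement.
    """
    if not params.tau > 0:
        raise ParameterError("tau must be positive")
    summary = belief_summary(params, state, persona)
    p = _mean_or_half(summary, strict)
    scale = 1.0
    if params.link == "uncertainty_scaled":
        n = summary.total_evidence
        scale = n / (n + 1.0)
    return _softmax2(scale * p / params.tau, scale * (1.0 - p) / params.tau)


def belief_log_likelihood(
    params: BeliefParams, session: SessionData
) -> tuple[float, np.ndarray]:
    """Log-likelihood of a session's choices under belief dynamics.

    Returns the total and the per-trial vector; state evidence resets to the
    initial bias at each block start. Zero-evidence beliefs are an error here
    (the fitted parameter region excludes them via the priors/transforms).
    """
    state = BeliefState.initial(params)
    lls = []
    for block in session.blocks:
        persona = session.personas[block[0].persona_index]
        state.reset_persona(persona.index, params)
        for trial in block:
            dist = belief_choice_probability(params, state, persona, strict=True)
            p = dist.p_positive if trial.choice == "positive" else dist.p_negative
            lls.append(math.log(max(p, 1e-300)))
            state = belief_update(state, trial, params, persona)
    vec = np.asarray(lls)
    return float(vec.sum()), vec


def effective_learning_rate(summary: BeliefSummary) -> float:
    """Local learning-rate equivalent of a belief with total evidence N.

    With no decay (eta = 1), one positive outcome moves the mean approval by
    (1 - p) / (N + 1): a delta rule toward 1 with rate 1 / (N + 1). Entrenched
    beliefs (large N) therefore update slowly — the mechanism linking large
    positive self-schemas to small self-negative learning rates.
    """
    n = summary.total_evidence
    if n <= 0:
        raise DegenerateBeliefError("effective learning rate undefined at N = 0")
    return 1.0 / (n + 1.0)


class BeliefAgent:
    """Stateful agent wrapper usable with :func:`selearn.task.simulate_session`."""

    def __init__(self, params: BeliefParams, strict: bool = False):
        self.params = params
        self.state = BeliefState.initial(params)
        self.strict = strict

    def reset_block(self, persona: Persona) -> None:
        self.state.reset_persona(persona.index, self.params)

    def choice_probability(self, persona: Persona) -> ChoiceDistribution:
        return belief_choice_probability(
            self.params, self.state, persona, strict=self.strict
        )

    def update(self, trial: TrialRecord) -> None:
        referent = "self" if trial.persona_index < 3 else "other"
        s = trial.persona_index
        eta = self.params.eta[referent]
        pos = trial.outcome_valence == "positive"
        self.state.alpha_state[s] = eta * self.state.alpha_state[s] + (1.0 if pos else 0.0)
        self.state.beta_state[s] = eta * self.state.beta_state[s] + (0.0 if pos else 1.0)
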