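"""Social-evaluation learning task: domain types, schedules, session simulation, I/O.

The task presents six evaluative contexts ("personas"): a referent (whether the
evaluation concerns the participant herself or an unknown other) crossed with an
approval rule (like / neutral / dislike). On each trial the participant chooses
between a positive and a negative word and receives binary feedback; the
probability that the positive word is the correct one is fixed per rule
(0.8 / 0.5 / 0.2 by default). Each persona is played as one contiguous block of
32 trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ModelError, ValidationError

REFERENTS = ("self", "other")
RULES = ("like", "neutral", "dislike")
VALENCES = ("positive", "negative")
DEFAULT_P_MAP = {"like": 0.8, "neutral": 0.5, "dislike": 0.2}

#: number of evaluative contexts (referent x rule)
N_PERSONAS = 6


@dataclass(frozen=True)
class Persona:
    """One evaluative context: a referent crossed with an approval rule."""

    referent: str
    rule: str
    p_positive: float
    index: int

    def __post_init__(self) -> None:
        if self.referent not in REFERENTS:
            raise ConfigurationError(f"unknown referent {self.referent!r}")
        if self.rule not in RULES:
            raise ConfigurationError(f"unknown rule {self.rule!r}")
        if not 0.0 <= self.p_positive <= 1.0:
            raise ConfigurationError(
                f"p_positive must be in [0, 1], got {self.p_positive}"
            )
        if not 0 <= self.index < N_PERSONAS:
            raise ConfigurationError(f"persona index must be 0..5, got {self.index}")


def default_personas(p_map: dict[str, float] | None = None) -> tuple[Persona, ...]:
    """The six personas in canonical index order (self personas first).

    Index layout: 0 self-like, 1 self-neutral, 2 self-dislike,
    3 other-like, 4 other-neutral, 5 other-dislike.
    """
    p_map = dict(DEFAULT_P_MAP if p_map is None else p_map)
    out = []
    for i, (ref, rule) in enumerate(
        (r, c) for r in REFERENTS for c in RULES
    ):
        out.append(Persona(ref, rule, float(p_map[rule]), i))
    return tuple(out)


@dataclass(frozen=True)
class TrialRecord:
    """One binary word choice plus its feedback within a persona block."""

    participant_id: str
    persona_index: int
    trial_index: int
    choice: str
    outcome_valence: str
    feedback: int

    def __post_init__(self) -> None:
        if self.choice not in VALENCES or self.outcome_valence not in VALENCES:
            raise ValidationError(
                f"choice/outcome must be 'positive' or 'negative', got "
                f"{self.choice!r}/{self.outcome_valence!r}"
            )
        expected = int(self.choice == self.outcome_valence)
        if self.feedback != expected:
            raise ValidationError(
                "feedback must equal 1 exactly when choice matches outcome "
                f"(choice={self.choice}, outcome={self.outcome_valence}, "
                f"feedback={self.feedback})"
            )


@dataclass
class SessionData:
    """One participant's full task run: six persona blocks of trials."""

    participant_id: str
    bfne: float
    blocks: list[list[TrialRecord]]
    personas: tuple[Persona, ...] = field(default_factory=default_personas)

    def all_trials(self) -> list[TrialRecord]:
        return [t for block in self.blocks for t in block]

    def persona_of_block(self, b: int) -> Persona:
        return self.personas[self.blocks[b][0].persona_index]


@dataclass
class ScheduleConfig:
    """How outcome schedules and sessions are constructed.

    ``iid_bernoulli`` draws each trial's correct valence independently;
    ``fixed_ratio`` forces the positive-outcome count to
    ``round(p * trials_per_block)`` and shuffles the order.
    """

    trials_per_block: int = 32
    p_map: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_P_MAP))
    schedule_mode: str = "iid_bernoulli"
    block_order: Sequence[int] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.trials_per_block <= 0:
            raise ConfigurationError("trials_per_block must be positive")
        if self.schedule_mode not in ("iid_bernoulli", "fixed_ratio"):
            raise ConfigurationError(f"unknown schedule_mode {self.schedule_mode!r}")
        for rule, p in self.p_map.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"p_map[{rule!r}]={p} outside [0, 1]")
        if self.block_order is not None:
            order = list(self.block_order)
            if not all(0 <= i < N_PERSONAS for i in order):
                raise ConfigurationError("block_order entries must be persona indices")

    def personas(self) -> tuple[Persona, ...]:
        return default_personas(self.p_map)


class Agent(Protocol):
    """Choice policy with trial-by-trial learning (duck-typed)."""

    def choice_probability(self, persona: Persona):  # -> ChoiceDistribution
        ...

    def update(self, trial: TrialRecord) -> None:
        ...


def make_schedule(
    persona: Persona, cfg: ScheduleConfig, rng: np.random.Generator
) -> list[str]:
    """Sequence of correct-word valences for one block of ``cfg.trials_per_block``."""
    n = cfg.trials_per_block
    p = persona.p_positive
    if cfg.schedule_mode == "iid_bernoulli":
        pos = rng.random(n) < p
    else:  # fixed_ratio
        k = int(round(p * n))
        pos = np.zeros(n, dtype=bool)
        pos[:k] = True
        rng.shuffle(pos)
    return ["positive" if x else "negative" for x in pos]


def simulate_session(
    agent: Agent,
    cfg: ScheduleConfig,
    rng: np.random.Generator,
    participant_id: str = "sim",
    bfne: float = math.nan,
) -> SessionData:
    """Simulate one full session of an agent playing the task.

    Learned quantities are reset at the start of each block (each persona is a
    separate context); trait-like and initial-bias parameters of the agent apply
    to every block. Blocks follow ``cfg.block_order`` or a seeded random
    permutation of all six personas.
    """
    personas = cfg.personas()
    if cfg.block_order is not None:
        order = list(cfg.block_order)
    else:
        order = list(rng.permutation(N_PERSONAS))
    blocks: list[list[TrialRecord]] = []
    for b in order:
        persona = personas[b]
        reset = getattr(agent, "reset_block", None)
        if reset is not None:
            reset(persona)
        schedule = make_schedule(persona, cfg, rng)
        block: list[TrialRecord] = []
        for t, outcome in enumerate(schedule):
            p_pos = agent.choice_probability(persona).p_positive
            if not (0.0 <= p_pos <= 1.0) or not np.isfinite(p_pos):
                raise ModelError(
                    f"agent produced invalid choice probability {p_pos!r}"
                )
            choice = "positive" if rng.random() < p_pos else "negative"
            trial = TrialRecord(
                participant_id=participant_id,
                persona_index=persona.index,
                trial_index=t,
                choice=choice,
                outcome_valence=outcome,
                feedback=int(choice == outcome),
            )
            agent.update(trial)
            block.append(trial)
        blocks.append(block)
    return SessionData(participant_id=participant_id, bfne=bfne, blocks=blocks)


def percent_positive(block: Iterable[TrialRecord]) -> float:
    """Percentage of positive word choices in a block (0-100)."""
    trials = list(block)
    if not trials:
        raise ValueError("percent_positive of an empty block is undefined")
    k = sum(t.choice == "positive" for t in trials)
    return 100.0 * k / len(trials)


# ---------------------------------------------------------------------------
# CSV I/O

_COLUMNS = [
    "participant_id",
    "bfne",
    "persona_referent",
    "persona_rule",
    "trial_index",
    "choice",
    "outcome_valence",
    "feedback",
]

_PERSONA_INDEX = {
    (ref, rule): i
    for i, (ref, rule) in enumerate((r, c) for r in REFERENTS for c in RULES)
}


def write_sessions(sessions: Sequence[SessionData], path) -> None:
    """Write sessions to a trial-level CSV (UTF-8, one row per trial)."""
    rows = []
    for s in sessions:
        for block in s.blocks:
            for t in block:
                persona = s.personas[t.persona_index]
                rows.append(
                    (
                        s.participant_id,
                        s.bfne,
                        persona.referent,
                        persona.rule,
                        t.trial_index,
                        t.choice,
                        t.outcome_valence,
                        t.feedback,
                    )
                )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_sessions(path, p_map: dict[str, float] | None = None) -> list[SessionData]:
    """Read sessions from CSV, validating the feedback-consistency invariant."""
    try:
        df = pd.read_csv(path, dtype={"participant_id": str})
    except pd.errors.EmptyDataError as e:
        raise FormatError(f"{path}: empty file") from e
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise FormatError(f"{path}: no trial rows")
    bad = df.index[
        (df["choice"] == df["outcome_valence"]).astype(int) != df["feedback"]
    ]
    if len(bad):
        raise ValidationError(
            f"{path}: feedback inconsistent with choice/outcome on rows "
            f"{list(bad[:20])}{'...' if len(bad) > 20 else ''}"
        )
    personas = default_personas(p_map)
    sessions = []
    for pid, g in df.groupby("participant_id", sort=False):
        bfne = float(g["bfne"].iloc[0])
        blocks = []
        pis = [
            _PERSONA_INDEX[k]
            for k in zip(g["persona_referent"], g["persona_rule"])
        ]
        # blocks in order of first appearance
        seen: dict[int, list[TrialRecord]] = {}
        for pi, ti, ch, ov, fb in zip(
            pis, g["trial_index"], g["choice"], g["outcome_valence"], g["feedback"]
        ):
            if pi not in seen:
                seen[pi] = []
                blocks.append(seen[pi])
            seen[pi].append(
                TrialRecord(
                    participant_id=str(pid),
                    persona_index=pi,
                    trial_index=int(ti),
                    choice=str(ch),
                    outcome_valence=str(ov),
                    feedback=int(fb),
                )
            )
        sessions.append(
            SessionData(
                participant_id=str(pid), bfne=bfne, blocks=blocks, personas=personas
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# Array view used by the vectorised likelihood kernels

@dataclass
class SessionArrays:
    """Stacked integer view of equally shaped sessions (subject x trial).

    Codes: referent 0=self 1=other; outcome/choice 1=positive 0=negative.
    Trials are concatenated block by block; block boundaries fall at multiples
    of ``trials_per_block``.
    """

    persona: np.ndarray  # (S, T) int, persona index 0..5
    referent: np.ndarray  # (S, T) int
    outcome: np.ndarray  # (S, T) int
    choice: np.ndarray  # (S, T) int
    feedback: np.ndarray  # (S, T) int
    trials_per_block: int
    participant_ids: list[str]
    bfne: np.ndarray  # (S,)

    @property
    def n_subjects(self) -> int:
        return self.persona.shape[0]

    @property
    def n_trials(self) -> int:
        return self.persona.shape[1]


def sessions_to_arrays(sessions: Sequence[SessionData]) -> SessionArrays:
    """Stack sessions with identical block structure into array form."""
    if not sessions:
        raise ValueError("no sessions")
    tpb = len(sessions[0].blocks[0])
    nb = len(sessions[0].blocks)
    S, T = len(sessions), nb * tpb
    persona = np.empty((S, T), dtype=np.int64)
    referent = np.empty((S, T), dtype=np.int64)
    outcome = np.empty((S, T), dtype=np.int64)
    choice = np.empty((S, T), dtype=np.int64)
    feedback = np.empty((S, T), dtype=np.int64)
    bfne = np.empty(S)
    ids = []
    for i, s in enumerate(sessions):
        if len(s.blocks) != nb or any(len(b) != tpb for b in s.blocks):
            raise ValueError("sessions_to_arrays requires identical block structure")
        trials = s.all_trials()
        persona[i] = [t.persona_index for t in trials]
        referent[i] = [
            0 if s.personas[t.persona_index].referent == "self" else 1 for t in trials
        ]
        outcome[i] = [t.outcome_valence == "positive" for t in trials]
        choice[i] = [t.choice == "positive" for t in trials]
        feedback[i] = [t.feedback for t in trials]
        bfne[i] = s.bfne
        ids.append(s.participant_id)
    return SessionArrays(
        persona=persona,
        referent=referent,
        outcome=outcome,
        choice=choice,
        feedback=feedback,
        trials_per_block=tpb,
        participant_ids=ids,
        bfne=bfne,
    )
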