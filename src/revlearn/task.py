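"""Generative engine for the two-choice serial probabilistic reversal-learning task.

The task presents two images, one of which is currently "correct": choosing it
wins points with probability ``p_win_correct`` (0.8 by default) and loses
points otherwise; the incorrect image has the inverse contingency. Outcomes
are pseudo-randomised so the nominal probabilities are exact over blocks of
``block_len`` consecutive selections of each *role* (correct/incorrect), with
no more than ``max_run`` identical outcomes in a row within a role's stream.

Once the subject has chosen the correct image on ``criterion_hits`` of the
last ``criterion_window`` trials, the task enters a stability phase: on every
trial for which criterion is still held the contingencies reverse with
probability k / ``stability_divisor``, where k counts consecutive trials of
maintained criterion. A reversal swaps the two images' roles and starts a new
learning event.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np
import pandas as pd

IMAGES = ("A", "B")
MISS = None  # sentinel choice: no response on this trial

WIN = "WIN"
LOSS = "LOSS"
NONE = "NONE"

CORRECT = "CORRECT"
INCORRECT = "INCORRECT"


class TaskConfigError(ValueError):
    """Raised when a task configuration is internally inconsistent."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the serial reversal-learning task.

    Defaults reproduce the published task: 360 trials, 0.8 reward
    probability balanced over 20-selection blocks, at most 6 identical
    consecutive outcomes per role, a 5-of-6 learning criterion, reversal
    probability k/10 during the stability phase, and +/-50 points.
    """

    n_trials: int = 360
    p_win_correct: float = 0.8
    block_len: int = 20
    max_run: int = 6
    criterion_hits: int = 5
    criterion_window: int = 6
    stability_divisor: float = 10.0
    win_points: int = 50
    loss_points: int = -50
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_win_correct < 1.0:
            raise TaskConfigError("p_win_correct must lie strictly in (0, 1)")
        n_win = self.p_win_correct * self.block_len
        if abs(n_win - round(n_win)) > 1e-9:
            raise TaskConfigError(
                "p_win_correct * block_len must be an integer "
                f"(got {n_win!r})"
            )
        if self.criterion_hits > self.criterion_window:
            raise TaskConfigError("criterion_hits must be <= criterion_window")
        if self.max_run >= self.block_len:
            raise TaskConfigError("max_run must be < block_len")
        if self.stability_divisor <= 0:
            raise TaskConfigError("stability_divisor must be positive")
        if self.n_trials < 1:
            raise TaskConfigError("n_trials must be >= 1")
        # the majority outcome must be packable without an over-long run
        n_major = max(round(n_win), self.block_len - round(n_win))
        n_minor = self.block_len - n_major
        if n_major > self.max_run * (n_minor + 1):
            raise TaskConfigError(
                "max_run too small to arrange the block's outcome split"
            )


@dataclass(frozen=True)
class TrialRecord:
    """One trial of a session, after feedback and the reversal draw."""

    trial_index: int  # 1-based
    correct_image: str
    choice: Optional[str]  # image id or None for a miss
    outcome: str  # WIN | LOSS | NONE
    points_delta: int
    cumulative_points: int
    criterion_met: bool
    maintained_count: int  # k, trials of maintained criterion incl. this one
    reversed_after: bool  # contingencies swap before the next trial
    learning_event: int  # 1-based id of the event this trial belongs to


@dataclass
class Session:
    subject: str
    config: TaskConfig
    trials: list[TrialRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": [t.trial_index for t in self.trials],
                "correct_image": [t.correct_image for t in self.trials],
                "choice": ["" if t.choice is None else t.choice for t in self.trials],
                "outcome": [t.outcome for t in self.trials],
                "points_delta": [t.points_delta for t in self.trials],
                "cumulative": [t.cumulative_points for t in self.trials],
                "criterion_met": [t.criterion_met for t in self.trials],
                "maintained_k": [t.maintained_count for t in self.trials],
                "reversed_after": [t.reversed_after for t in self.trials],
                "learning_event": [t.learning_event for t in self.trials],
            }
        )


def build_outcome_block(
    role: str,
    config: TaskConfig,
    rng: np.random.Generator,
    prev_tail: Sequence[bool] = (),
) -> list[bool]:
    """Draw one pseudo-randomised outcome block for a role.

    Returns ``block_len`` booleans (True = WIN). The block contains exactly
    ``p * block_len`` wins, where p is ``p_win_correct`` for the CORRECT role
    and ``1 - p_win_correct`` otherwise, and no run of identical outcomes
    longer than ``max_run`` — counting also the tail of the role's previous
    block, so the constraint holds across block boundaries.
    """
    if role not in (CORRECT, INCORRECT):
        raise ValueError(f"unknown role {role!r}")
    p = config.p_win_correct if role == CORRECT else 1.0 - config.p_win_correct
    n_win = round(p * config.block_len)
    base = np.array([True] * n_win + [False] * (config.block_len - n_win))
    tail = list(prev_tail)[-config.max_run:]
    for _ in range(10_000):
        perm = rng.permutation(base)
        if _max_run(tail + perm.tolist()) <= config.max_run:
            return perm.tolist()
    raise TaskConfigError(
        "could not satisfy the run-length constraint; check max_run"
    )


def _max_run(seq: Sequence[bool]) -> int:
    best = run = 0
    prev: Optional[bool] = None
    for x in seq:
        run = run + 1 if x == prev else 1
        prev = x
        best = max(best, run)
    return best


def check_criterion(correct_flags: Sequence[bool], config: TaskConfig) -> bool:
    """Learning-criterion test: ``criterion_hits`` correct of the last
    ``criterion_window`` trials (a miss counts as not-correct).

    Evaluable as soon as ``criterion_hits`` trials have elapsed; before that
    the criterion cannot be met.
    """
    t = len(correct_flags)
    if t < config.criterion_hits:
        return False
    window = list(correct_flags)[-config.criterion_window:]
    return sum(window) >= config.criterion_hits


def reversal_probability(k: int, config: TaskConfig) -> float:
    """Probability of reversal after k trials of maintained criterion.

    k/stability_divisor, clamped to [0, 1]; 0 when criterion is not held.
    """
    if k <= 0:
        return 0.0
    return min(k / config.stability_divisor, 1.0)


class _RoleQueue:
    """Outcome buffer for one role; refilled block-by-block, lazily.

    The buffer is attached to the CORRECT/INCORRECT role, not to an image,
    so block balance stays well defined across reversals, and the run-length
    constraint is enforced across block boundaries via the retained tail.
    """

    def __init__(self, role: str, config: TaskConfig):
        self.role = role
        self.config = config
        self._buf: list[bool] = []
        self._pos = 0
        self._tail: list[bool] = []

    def draw(self, rng: np.random.Generator) -> bool:
        if self._pos >= len(self._buf):
            self._buf = build_outcome_block(self.role, self.config, rng, self._tail)
            self._pos = 0
        win = self._buf[self._pos]
        self._pos += 1
        self._tail = (self._tail + [win])[-self.config.max_run:]
        return win


@dataclass
class TaskState:
    """Mutable per-session state consumed by :func:`step`."""

    config: TaskConfig
    correct_image: str
    queues: dict
    window: deque  # last criterion_window correctness flags
    maintained_count: int = 0
    event: int = 1
    trial_index: int = 0
    cumulative_points: int = 0

    @classmethod
    def new(cls, config: TaskConfig, rng: np.random.Generator) -> "TaskState":
        correct = IMAGES[int(rng.integers(2))]  # initial assignment is random
        return cls(
            config=config,
            correct_image=correct,
            queues={
                CORRECT: _RoleQueue(CORRECT, config),
                INCORRECT: _RoleQueue(INCORRECT, config),
            },
            window=deque(maxlen=config.criterion_window),
        )


def step(
    state: TaskState,
    choice: Optional[str],
    config: TaskConfig,
    rng: np.random.Generator,
) -> TrialRecord:
    """Advance the task by one trial.

    Random draws, in order: (1) any block refill triggered by consuming the
    chosen role's outcome queue, (2) one uniform variate for the reversal
    draw whenever criterion is held. A miss consumes no queue outcome.
    The reversal takes effect from the next trial.
    """
    if choice is not None and choice not in IMAGES:
        raise ValueError(f"invalid choice {choice!r}")
    state.trial_index += 1
    event = state.event

    if choice is None:
        outcome = NONE
        points = 0
        state.window.append(False)
    else:
        role = CORRECT if choice == state.correct_image else INCORRECT
        win = state.queues[role].draw(rng)
        outcome = WIN if win else LOSS
        points = config.win_points if win else config.loss_points
        state.window.append(choice == state.correct_image)
    state.cumulative_points += points

    met = check_criterion(state.window, config)
    reversed_after = False
    if met:
        state.maintained_count += 1
        p_rev = reversal_probability(state.maintained_count, config)
        if rng.random() < p_rev:
            reversed_after = True
    else:
        state.maintained_count = 0

    record = TrialRecord(
        trial_index=state.trial_index,
        correct_image=state.correct_image,
        choice=choice,
        outcome=outcome,
        points_delta=points,
        cumulative_points=state.cumulative_points,
        criterion_met=met,
        maintained_count=state.maintained_count,
        reversed_after=reversed_after,
        learning_event=event,
    )

    if reversed_after:
        state.correct_image = IMAGES[1 - IMAGES.index(state.correct_image)]
        state.maintained_count = 0
        state.window.clear()  # criterion tracking restarts in the new event
        state.event += 1
    return record


class Agent(Protocol):
    """Choice policy driving :func:`run_session`.

    ``choose`` receives the task state for the benefit of diagnostic
    policies (e.g. an oracle that always picks the correct image); learning
    agents must ignore everything except their own history. ``observe`` is
    called with the realised outcome value (+1 win, -1 loss, 0 miss).
    """

    def choose(self, state: TaskState, rng: np.random.Generator) -> Optional[str]: ...

    def observe(self, choice: Optional[str], outcome_value: float) -> None: ...


def outcome_value(outcome: str) -> float:
    """Outcome coding fed to learning agents: WIN -> +1, LOSS -> -1."""
    return {WIN: 1.0, LOSS: -1.0, NONE: 0.0}[outcome]


def run_session(
    agent: Agent,
    config: TaskConfig,
    rng: Optional[np.random.Generator] = None,
    subject: str = "sim",
) -> Session:
    """Simulate a full session of ``config.n_trials`` trials."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = TaskState.new(config, rng)
    session = Session(subject=subject, config=config)
    for _ in range(config.n_trials):
        choice = agent.choose(state, rng)
        record = step(state, choice, config, rng)
        agent.observe(choice, outcome_value(record.outcome))
        session.trials.append(record)
    return session


# -- deterministic diagnostic policies ---------------------------------------


class AlwaysCorrectAgent:
    """Oracle policy: always selects the currently correct image."""

    def choose(self, state: TaskState, rng: np.random.Generator) -> str:
        return state.correct_image

    def observe(self, choice, outcome_value) -> None:
        pass


class AlwaysMissAgent:
    """Never responds."""

    def choose(self, state: TaskState, rng: np.random.Generator) -> None:
        return MISS

    def observe(self, choice, outcome_value) -> None:
        pass


class FixedChoiceAgent:
    """Always chooses the same image, regardless of feedback."""

    def __init__(self, image: str):
        if image not in IMAGES:
            raise ValueError(f"invalid image {image!r}")
        self.image = image

    def choose(self, state: TaskState, rng: np.random.Generator) -> str:
        return self.image

    def observe(self, choice, outcome_value) -> None:
        pass


class ScriptedAgent:
    """Replays a fixed sequence of choices (None entries are misses)."""

    def __init__(self, choices: Sequence[Optional[str]]):
        self.choices = list(choices)
        self._i = 0

    def choose(self, state: TaskState, rng: np.random.Generator) -> Optional[str]:
        c = self.choices[self._i]
        self._i += 1
        return c

    def observe(self, choice, outcome_value) -> None:
        pass
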