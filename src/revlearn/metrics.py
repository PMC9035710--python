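"""Behavioural measures of a reversal-learning session.

A session is segmented into *learning events*: the stretches of trials
between contingency reversals. Within each post-reversal event we count

* perseverative errors: choices of the previously correct image from the
  start of the event up to (not including) the first choice of the newly
  correct image — the subject has not yet "switched" strategy;
* regressive errors: relapses to the previously correct image after that
  first switch and before the next reversal.

Misses carry no choice, so they neither count as errors nor end the
perseverative run. The first event of a session has no previous strategy
and its error counts are reported as absent (None), not zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .task import IMAGES, Session, TrialRecord


@dataclass(frozen=True)
class LearningEvent:
    """One contingency regime: trials between consecutive reversals."""

    event_id: int
    start_trial: int  # 1-based trial index of the first trial
    criterion_trial: Optional[int]  # first trial on which criterion was met
    reversal_trial: Optional[int]  # trial after which contingencies reversed
    correct_image: str
    trials: tuple[TrialRecord, ...]


@dataclass(frozen=True)
class ErrorCounts:
    perseverative: Optional[int]  # None for the first event
    regressive: Optional[int]


@dataclass(frozen=True)
class PerformanceSummary:
    subject: str
    n_trials: int
    correct: int
    incorrect: int
    misses: int
    reversals: int
    mean_trials_to_criterion: float
    mean_perseverative: float  # per post-reversal event; nan if no reversal
    mean_regressive: float
    total_perseverative: int
    total_regressive: int
    final_points: int


def segment_events(session: Session) -> list[LearningEvent]:
    """Split a session into learning events, one per contingency regime.

    The final (possibly incomplete) event is included. Raises on a session
    whose reversal flags appear on trials where criterion did not hold.
    """
    events: list[LearningEvent] = []
    current: list[TrialRecord] = []
    for t in session.trials:
        if t.reversed_after and not t.criterion_met:
            raise ValueError(
                f"malformed session: reversal without criterion at trial "
                f"{t.trial_index}"
            )
        current.append(t)
        if t.reversed_after:
            events.append(_make_event(current))
            current = []
    if current:
        events.append(_make_event(current))
    return events


def _make_event(trials: list[TrialRecord]) -> LearningEvent:
    criterion = next(
        (t.trial_index for t in trials if t.criterion_met), None
    )
    reversal = trials[-1].trial_index if trials[-1].reversed_after else None
    return LearningEvent(
        event_id=trials[0].learning_event,
        start_trial=trials[0].trial_index,
        criterion_trial=criterion,
        reversal_trial=reversal,
        correct_image=trials[0].correct_image,
        trials=tuple(trials),
    )


def count_perseverative(event: LearningEvent, previous_correct_image: str) -> int:
    """Perseverative errors: choices of the previously correct image before
    the first choice of the newly correct image. Misses are skipped and do
    not end the run."""
    new_correct = event.correct_image
    count = 0
    for t in event.trials:
        if t.choice is None:
            continue
        if t.choice == new_correct:
            break
        if t.choice == previous_correct_image:
            count += 1
    return count


def count_regressive(event: LearningEvent, previous_correct_image: str) -> int:
    """Regressive errors: choices of the previously correct image after the
    first choice of the newly correct image, before the event ends."""
    switched = False
    count = 0
    for t in event.trials:
        if t.choice is None:
            continue
        if not switched:
            if t.choice == event.correct_image:
                switched = True
            continue
        if t.choice == previous_correct_image:
            count += 1
    return count


def event_errors(events: list[LearningEvent]) -> list[ErrorCounts]:
    """Per-event error counts; the first event's counts are absent."""
    out: list[ErrorCounts] = []
    for i, ev in enumerate(events):
        if i == 0:
            out.append(ErrorCounts(None, None))
        else:
            prev = events[i - 1].correct_image
            out.append(
                ErrorCounts(
                    perseverative=count_perseverative(ev, prev),
                    regressive=count_regressive(ev, prev),
                )
            )
    return out


def event_table(session: Session) -> pd.DataFrame:
    """Long-format per-event table: trials to criterion and error counts."""
    events = segment_events(session)
    errors = event_errors(events)
    rows = []
    for ev, err in zip(events, errors):
        ttc = (
            ev.criterion_trial - ev.start_trial + 1
            if ev.criterion_trial is not None
            else None
        )
        rows.append(
            {
                "event": ev.event_id,
                "start_trial": ev.start_trial,
                "trials_to_criterion": ttc,
                "perseverative": err.perseverative,
                "regressive": err.regressive,
                "reversed": ev.reversal_trial is not None,
            }
        )
    return pd.DataFrame(rows)


def summarize(session: Session) -> PerformanceSummary:
    """Session-level performance summary.

    Trials-to-criterion counts trials from event start to the criterion
    trial inclusive, averaged over events that reached criterion; error
    means are over post-reversal events only.
    """
    events = segment_events(session)
    errors = event_errors(events)
    correct = sum(
        1 for t in session.trials if t.choice is not None and t.choice == t.correct_image
    )
    misses = sum(1 for t in session.trials if t.choice is None)
    incorrect = len(session.trials) - correct - misses
    reversals = sum(1 for t in session.trials if t.reversed_after)
    ttcs = [
        ev.criterion_trial - ev.start_trial + 1
        for ev in events
        if ev.criterion_trial is not None
    ]
    pers = [e.perseverative for e in errors if e.perseverative is not None]
    regs = [e.regressive for e in errors if e.regressive is not None]
    return PerformanceSummary(
        subject=session.subject,
        n_trials=len(session.trials),
        correct=correct,
        incorrect=incorrect,
        misses=misses,
        reversals=reversals,
        mean_trials_to_criterion=float(pd.Series(ttcs, dtype=float).mean()),
        mean_perseverative=float(pd.Series(pers, dtype=float).mean()),
        mean_regressive=float(pd.Series(regs, dtype=float).mean()),
        total_perseverative=int(sum(pers)) if pers else 0,
        total_regressive=int(sum(regs)) if regs else 0,
        final_points=session.trials[-1].cumulative_points if session.trials else 0,
    )


def summary_frame(summaries: list[PerformanceSummary]) -> pd.DataFrame:
    """One row per subject with the PerformanceSummary fields."""
    return pd.DataFrame([s.__dict__ for s in summaries])
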