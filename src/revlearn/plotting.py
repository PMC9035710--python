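"""Basic summary plots: a session trace and per-event behaviour."""

from __future__ import annotations

from .metrics import event_table
from .task import Session


def plot_session(session: Session, ax=None):
    """Cumulative points over trials with criterion (C) and reversal (R)
    markers — one learning event per shaded span."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    trials = session.trials
    ax.plot(
        [t.trial_index for t in trials],
        [t.cumulative_points for t in trials],
        lw=1.0,
        color="tab:blue",
    )
    first_criterion: set[int] = set()
    for t in trials:
        if t.criterion_met and t.learning_event not in first_criterion:
            first_criterion.add(t.learning_event)
            ax.axvline(t.trial_index, color="tab:orange", ls="--", lw=0.6)
        if t.reversed_after:
            ax.axvline(t.trial_index, color="k", lw=0.6)
    ax.set_xlabel("trial")
    ax.set_ylabel("cumulative points")
    ax.set_title(f"{session.subject}: dashed = criterion, solid = reversal")
    return ax


def plot_event_errors(session: Session, ax=None):
    """Perseverative and regressive error counts per learning event."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    table = event_table(session).dropna(subset=["perseverative"])
    ax.bar(table["event"] - 0.2, table["perseverative"], width=0.4,
           label="perseverative", color="tab:orange")
    ax.bar(table["event"] + 0.2, table["regressive"], width=0.4,
           label="regressive", color="tab:blue")
    ax.set_xlabel("learning event")
    ax.set_ylabel("errors")
    ax.legend(frameon=False)
    return ax
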