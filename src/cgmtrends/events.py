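"""Therapy events (carbohydrate intake, insulin boluses) and event windows.

Trend arrows cannot foresee carbohydrate intake or insulin delivery, so
prediction quality is expected to degrade when the 30-min observation window
overlaps such an event.  A diary record at time ``t`` is "inside" the event
window of an event at time ``e`` when ``e - pre < t < e + post`` with the
default ``pre = 30`` and ``post = 120`` minutes; the boundaries themselves
are excluded (strict inequalities), which is measure-zero in practice but
documented for reproducibility.  Events are treated as instantaneous points;
continuous basal insulin delivery does not open windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["TherapyEvent", "EVENT_KINDS", "in_event_window", "stratified_summary"]

EVENT_KINDS = ("CHO", "insulin_bolus")

DEFAULT_PRE_MIN = 30.0
DEFAULT_POST_MIN = 120.0


@dataclass(frozen=True)
class TherapyEvent:
    """A timed discrete therapy intervention for one participant.

    ``amount`` is grams for CHO and units for insulin boluses; it is carried
    for bookkeeping only and does not affect the window logic.
    """

    participant_id: str
    time: float
    kind: str
    amount: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"kind must be one of {EVENT_KINDS}, got {self.kind!r}")
        if not np.isfinite(self.time):
            raise ValueError("event time must be finite")


def in_event_window(
    t: float,
    events: Iterable[TherapyEvent],
    pre: float = DEFAULT_PRE_MIN,
    post: float = DEFAULT_POST_MIN,
) -> bool:
    """True iff ``t`` falls strictly inside ``(e.time - pre, e.time + post)``
    for some event ``e``.  ``events`` must all belong to the participant
    whose diary time ``t`` is."""
    if pre < 0 or post < 0:
        raise ValueError(f"pre and post must be non-negative, got pre={pre}, post={post}")
    return any(e.time - pre < t < e.time + post for e in events)


def event_window_flags(
    times: Sequence[float],
    events: Sequence[TherapyEvent],
    pre: float = DEFAULT_PRE_MIN,
    post: float = DEFAULT_POST_MIN,
) -> np.ndarray:
    """Vectorized :func:`in_event_window` over many diary times."""
    if pre < 0 or post < 0:
        raise ValueError(f"pre and post must be non-negative, got pre={pre}, post={post}")
    t = np.asarray(times, dtype=float)
    if not events:
        return np.zeros(t.shape, dtype=bool)
    e = np.array([ev.time for ev in events], dtype=float)
    # Broadcast the exact scalar comparisons so the vectorized path agrees
    # with in_event_window bit-for-bit, including float boundary cases.
    tt = t[:, None]
    return ((e[None, :] - pre < tt) & (tt < e[None, :] + post)).any(axis=1)


def stratified_summary(records):
    """Split concordance records by the event-window flag.

    Returns ``(inside_summary, outside_summary, pct_inside)`` where
    ``pct_inside`` is the fraction of records inside any event window, as a
    percentage rounded to one decimal (``None`` when there are no records).
    """
    from .concordance import summarize, _round1  # local import avoids a cycle

    inside = [r for r in records if r.in_window]
    outside = [r for r in records if not r.in_window]
    n = len(inside) + len(outside)
    pct_inside = _round1(100.0 * len(inside) / n) if n else None
    return summarize(inside), summarize(outside), pct_inside
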