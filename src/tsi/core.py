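"""Core index computations for the Toothbrushing Systematics Index (TSI).

The TSI scores one observed brushing session against an area scheme with
``n`` reachable areas.  From the timed-event record four behavioural
measures are derived:

``b``
    number of changes of the brush between areas (transitions between
    consecutive brushing events whose areas differ),
``x``
    total effective brushing duration in seconds (sum of event durations;
    pauses are excluded),
``i``
    number of distinct areas reached,
``d_a``
    brushing duration within each area ``a`` (zero for unreached areas).

Two component values are computed from these:

* consistency/completeness ``C = max(0, 1 - b/x) * i/n``
* isochronicity ``I = max(0, 1 - n/(2(n-1)) * sum_a |d_a/x - 1/n|)``

where the sum runs over *all* ``n`` reachable areas.  The scaling factor in
``I`` normalises the mean absolute deviation of the relative per-area
durations by its maximum ``2(n-1)/n**2``, attained when all brushing time
is spent in a single area.  Both components lie in [0, 1] after clamping;
their sum, the TSI, lies in [0, 2], with 2 describing perfectly systematic
brushing (every area reached, equal time per area, few changes relative to
duration) and 0 describing unsystematic brushing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .schemes import Area, AreaScheme, SchemeError, SURFACES

__all__ = [
    "BrushingEvent",
    "BrushingSession",
    "SessionSummary",
    "IndexResult",
    "TsiError",
    "EmptySessionError",
    "UndefinedIndexError",
    "SessionValidationError",
    "summarize_session",
    "c_value",
    "i_value",
    "tsi",
    "restrict_to_surfaces",
]


class TsiError(Exception):
    """Base class for scoring errors."""


class EmptySessionError(TsiError):
    """No brushing recorded; C and I are undefined."""


class UndefinedIndexError(TsiError):
    """Inputs for which the index formulas are undefined (x <= 0, n < 2)."""


class SessionValidationError(TsiError, ValueError):
    """An event sequence violating the session invariants."""


@dataclass(frozen=True, order=True)
class BrushingEvent:
    """One coded interval during which the brush acts on one area.

    Onset/offset are session-relative seconds; sub-second (video-frame)
    resolution is accepted.
    """

    onset: float
    offset: float
    area: Area

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise SessionValidationError(
                f"event onset must be >= 0, got {self.onset}"
            )
        if not self.offset > self.onset:
            raise SessionValidationError(
                f"event must have positive duration "
                f"(onset={self.onset}, offset={self.offset})"
            )
        sextant, surface = self.area
        if surface not in SURFACES:
            raise SessionValidationError(f"unknown surface {surface!r}")
        object.__setattr__(self, "area", (int(sextant), surface))

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class BrushingSession:
    """A chronologically ordered, non-overlapping sequence of events.

    Events are sorted by onset on construction.  Gaps between events are
    permitted (non-brushing intervals have already been excluded from the
    record); overlaps are rejected.
    """

    events: tuple[BrushingEvent, ...]

    def __init__(self, events: Iterable[BrushingEvent]):
        ordered = tuple(sorted(events, key=lambda e: (e.onset, e.offset)))
        for prev, nxt in zip(ordered, ordered[1:]):
            if nxt.onset < prev.offset:
                raise SessionValidationError(
                    f"overlapping events: [{prev.onset}, {prev.offset}) in "
                    f"{prev.area} and [{nxt.onset}, {nxt.offset}) in {nxt.area}"
                )
        object.__setattr__(self, "events", ordered)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


@dataclass(frozen=True)
class SessionSummary:
    """The behavioural measures b, x, i and the per-area durations."""

    b: int
    x: float
    i: int
    d: Mapping[Area, float]


@dataclass(frozen=True)
class IndexResult:
    """C-value, I-value and their sum (the TSI) for one session."""

    c_value: float
    i_value: float
    summary: SessionSummary | None = field(default=None, compare=False)

    @property
    def tsi(self) -> float:
        return self.c_value + self.i_value


def summarize_session(
    session: BrushingSession, scheme: AreaScheme
) -> SessionSummary:
    """Derive the behavioural measures from a session.

    A change is counted whenever the area of an event differs from the area
    of the immediately preceding event; a pause between two events in the
    same area contributes no change.

    Raises
    ------
    EmptySessionError
        If the session contains no events.
    SessionValidationError
        If an event's area is not part of the scheme.
    """
    if len(session) == 0:
        raise EmptySessionError("no brushing recorded (empty session)")
    durations: dict[Area, float] = {}
    b = 0
    prev_area: Area | None = None
    for idx, event in enumerate(session):
        if event.area not in scheme:
            raise SessionValidationError(
                f"event {idx} (onset {event.onset} s) is coded in area "
                f"{event.area}, which is not in scheme {scheme.name!r}"
            )
        durations[event.area] = durations.get(event.area, 0.0) + event.duration
        if prev_area is not None and event.area != prev_area:
            b += 1
        prev_area = event.area
    x = sum(durations.values())
    return SessionSummary(b=b, x=x, i=len(durations), d=durations)


def c_value(summary: SessionSummary, scheme: AreaScheme) -> float:
    """Consistency/completeness value C = max(0, 1 - b/x) * i/n.

    The quotient b/x penalises frequent alternation of the brush between
    areas relative to the effective brushing duration; i/n rewards
    completeness.  When the number of changes exceeds the duration in
    seconds the raw value is negative and is clamped to zero.
    """
    if summary.x <= 0:
        raise UndefinedIndexError(
            f"C is undefined for total brushing duration x={summary.x}"
        )
    n = scheme.n
    if not 0 <= summary.i <= n:
        raise UndefinedIndexError(
            f"reached areas i={summary.i} outside [0, n={n}]"
        )
    raw = (1.0 - summary.b / summary.x) * (summary.i / n)
    return max(0.0, raw)


def i_value(summary: SessionSummary, scheme: AreaScheme) -> float:
    """Isochronicity value.

    I = 1 - n/(2(n-1)) * sum over all n reachable areas of |d_a/x - 1/n|,
    with d_a = 0 for unreached areas, clamped below at zero.  Equals 1
    exactly when every reachable area received x/n seconds, and 0 when all
    time was spent in a single area.
    """
    if summary.x <= 0:
        raise UndefinedIndexError(
            f"I is undefined for total brushing duration x={summary.x}"
        )
    n = scheme.n
    if n < 2:
        raise UndefinedIndexError(
            "I is undefined for a single-area scheme (n must be >= 2)"
        )
    x = summary.x
    target = 1.0 / n
    mad_sum = 0.0
    for area in scheme:
        share = summary.d.get(area, 0.0) / x
        mad_sum += abs(share - target)
    raw = 1.0 - n / (2.0 * (n - 1)) * mad_sum
    return max(0.0, raw)


def tsi(session: BrushingSession, scheme: AreaScheme) -> IndexResult:
    """Score a session: C, I and TSI = C + I under the given scheme."""
    summary = summarize_session(session, scheme)
    return IndexResult(
        c_value=c_value(summary, scheme),
        i_value=i_value(summary, scheme),
        summary=summary,
    )


def restrict_to_surfaces(
    session: BrushingSession,
    scheme: AreaScheme,
    surfaces: Iterable[str],
) -> tuple[BrushingSession, AreaScheme]:
    """Drop events on excluded surfaces and shrink the scheme accordingly.

    Used for the vestibular/oral analysis condition, in which occlusal
    events are removed and n drops from 16 to 12.  All measures are
    recomputed on the filtered stream: two events that become adjacent
    after filtering count a change only if their areas differ.

    Raises
    ------
    EmptySessionError
        If no event survives the filter.
    """
    keep = set(surfaces)
    sub_scheme = scheme.restrict(keep)
    retained = [e for e in session if e.area[1] in keep]
    if not retained:
        raise EmptySessionError("no brushing on selected surfaces")
    return BrushingSession(retained), sub_scheme
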