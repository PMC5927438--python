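"""Theoretical brushing-sequence grid for index validation.

The index behaviour is explored on a full-factorial sweep of hypothetical
brushing parameter combinations: the number of reached areas (1..16 of 16),
a repetition factor (each area approached 1..5 times, which fixes the
change count at 16*k - 1, i.e. 15..79), the total brushing duration
(eight values spanning 30-480 s) and the allocation condition (isochronal:
equal time per reached area; non-isochronal: time allocated by an uneven
master weight vector).  The defaults yield 16 * 5 * 8 * 2 = 1280 scored
rows.

Grid rows are parameter tuples plugged into the index formulas, so change
count and area count vary independently; :func:`realize_session` emits
physically consistent event sequences (i areas visited k times each,
hence b = i*k - 1) for any single parameter combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import core
from .core import BrushingEvent, BrushingSession, SessionSummary
from .schemes import AreaScheme

__all__ = [
    "GridSpec",
    "GridRow",
    "NonIsoWeights",
    "ISOCHRONAL",
    "NON_ISOCHRONAL",
    "default_master_weights",
    "score_grid",
    "realize_session",
    "summarize_grid",
    "grid_to_frame",
]

ISOCHRONAL = "isochronal"
NON_ISOCHRONAL = "non_isochronal"
CONDITIONS = (ISOCHRONAL, NON_ISOCHRONAL)

DEFAULT_DURATIONS = (30.0, 60.0, 90.0, 120.0, 180.0, 240.0, 360.0, 480.0)


@dataclass(frozen=True)
class NonIsoWeights:
    """Master allocation of brushing time over areas, as shares of x.

    For a row reaching i areas, the leading i weights are renormalised to
    sum to one and give each reached area's share of the total duration.
    At least two weights must differ, otherwise the allocation is
    isochronal.
    """

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = tuple(float(v) for v in self.weights)
        if len(w) < 2:
            raise ValueError("need at least two weights")
        if any(v < 0 for v in w):
            raise ValueError("weights must be nonnegative")
        total = sum(w)
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"weights must sum to 1, got {total}")
        if len(set(np.round(w, 12))) < 2:
            raise ValueError("weights must not all be equal (isochronal)")
        object.__setattr__(self, "weights", w)

    def shares(self, i: int) -> np.ndarray:
        """Renormalised leading-i shares of the total duration."""
        if not 1 <= i <= len(self.weights):
            raise ValueError(f"i={i} outside 1..{len(self.weights)}")
        lead = np.asarray(self.weights[:i], dtype=float)
        total = lead.sum()
        if total <= 0:
            raise ValueError(f"leading {i} weights sum to zero")
        return lead / total


def default_master_weights(n: int = 16) -> NonIsoWeights:
    """A documented uneven master allocation over the default area order.

    Vestibular surfaces receive disproportionally long and oral surfaces
    disproportionally short brushing times, with occlusal surfaces in
    between — the pattern habitual (uninstructed) brushing tends to show.
    Raw weights per surface: vestibular 2.0, oral 0.75, occlusal 1.25,
    incisal 0.75, normalised to sum to one over the first n areas.
    """
    raw_per_surface = {
        "vestibular": 2.0,
        "oral": 0.75,
        "occlusal": 1.25,
        "incisal": 0.75,
    }
    universe = AreaScheme.all_areas(include_incisal=True)
    if not 2 <= n <= universe.n:
        raise ValueError(f"n must be in 2..{universe.n}, got {n}")
    raw = [raw_per_surface[surface] for _, surface in list(universe)[:n]]
    total = sum(raw)
    return NonIsoWeights(tuple(v / total for v in raw))


@dataclass(frozen=True)
class GridSpec:
    """Parameters of the theoretical sweep.

    Defaults reproduce the 1280-row validation grid: 16 area counts x
    5 repetition factors x 8 durations x 2 conditions.
    """

    area_counts: tuple[int, ...] = tuple(range(1, 17))
    repetition_factors: tuple[int, ...] = (1, 2, 3, 4, 5)
    durations_s: tuple[float, ...] = DEFAULT_DURATIONS
    conditions: tuple[str, ...] = CONDITIONS
    n: int = 16

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("scheme size n must be >= 2")
        if not self.area_counts or any(
            not 1 <= i <= self.n for i in self.area_counts
        ):
            raise ValueError(f"area counts must lie in 1..{self.n}")
        if not self.repetition_factors or any(
            k < 1 for k in self.repetition_factors
        ):
            raise ValueError("repetition factors must be >= 1")
        if not self.durations_s or any(x <= 0 for x in self.durations_s):
            raise ValueError("durations must be positive")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown or not self.conditions:
            raise ValueError(
                f"conditions must be a non-empty subset of {CONDITIONS}"
            )

    @property
    def n_rows(self) -> int:
        return (
            len(self.area_counts)
            * len(self.repetition_factors)
            * len(self.durations_s)
            * len(self.conditions)
        )


@dataclass(frozen=True)
class GridRow:
    """One scored parameter combination (a cell of the validation matrix)."""

    condition: str
    i: int
    k: int
    b: int
    x: float
    c_value: float
    i_value: float
    tsi: float


def _scheme_for(n: int) -> AreaScheme:
    universe = AreaScheme.all_areas(include_incisal=True)
    if n == 16:
        return AreaScheme.all_areas()
    if not 2 <= n <= universe.n:
        raise ValueError(f"scheme size n must be in 2..{universe.n}")
    return AreaScheme(tuple(list(universe)[:n]), name=f"first_{n}")


def _allocate(
    i: int, x: float, condition: str, weights: NonIsoWeights | None, n: int
) -> np.ndarray:
    if condition == ISOCHRONAL:
        return np.full(i, x / i)
    if condition == NON_ISOCHRONAL:
        if weights is None:
            weights = default_master_weights(n)
        return weights.shares(i) * x
    raise ValueError(f"unknown condition {condition!r}")


def score_grid(
    spec: GridSpec = GridSpec(), weights: NonIsoWeights | None = None
) -> list[GridRow]:
    """Score every parameter combination of the sweep.

    The change count of a row is tied to the repetition factor alone,
    b = n*k - 1 (15, 31, 47, 63 or 79 for n=16), independent of the area
    count, so that the sweep probes change counts and completeness
    independently.  C and I are evaluated by the core index formulas,
    including their clamps at zero.
    """
    scheme = _scheme_for(spec.n)
    areas = list(scheme)
    rows: list[GridRow] = []
    for condition in spec.conditions:
        for i in spec.area_counts:
            for k in spec.repetition_factors:
                b = spec.n * k - 1
                for x in spec.durations_s:
                    alloc = _allocate(i, x, condition, weights, spec.n)
                    summary = SessionSummary(
                        b=b,
                        x=float(x),
                        i=i,
                        d=dict(zip(areas, alloc.tolist())),
                    )
                    c = core.c_value(summary, scheme)
                    iv = core.i_value(summary, scheme)
                    rows.append(
                        GridRow(
                            condition=condition,
                            i=i,
                            k=k,
                            b=b,
                            x=float(x),
                            c_value=c,
                            i_value=iv,
                            tsi=c + iv,
                        )
                    )
    return rows


def realize_session(
    i: int,
    k: int,
    x: float,
    condition: str = ISOCHRONAL,
    weights: NonIsoWeights | None = None,
    seed: int | None = None,
    scheme: AreaScheme | None = None,
    min_event_s: float = 0.05,
) -> BrushingSession:
    """Emit a concrete event sequence for one parameter combination.

    The session visits i areas k times each in a repeating round, giving
    i*k events and i*k - 1 changes, with each visit lasting the area's
    share of x divided by k.  Events are contiguous starting at 0 s.  The
    seed shuffles which areas are chosen and their order; scores are
    unaffected by that order.

    Raises
    ------
    ValueError
        If some visit would be shorter than ``min_event_s`` (x too small
        for the requested number of events).
    """
    if i < 1 or k < 1 or x <= 0:
        raise ValueError("need i >= 1, k >= 1, x > 0")
    if scheme is None:
        scheme = _scheme_for(16)
    if i > scheme.n:
        raise ValueError(f"cannot reach {i} areas in a scheme of {scheme.n}")
    areas = list(scheme)
    order = np.arange(len(areas))
    if seed is not None:
        np.random.default_rng(seed).shuffle(order)
    chosen = [areas[j] for j in order[:i]]
    alloc = _allocate(i, x, condition, weights, scheme.n)
    dwell = alloc / k
    if np.any(dwell < min_event_s):
        raise ValueError(
            f"infeasible parameters: a visit of {dwell.min():.4g} s is "
            f"shorter than the minimum event duration {min_event_s} s"
        )
    events = []
    t = 0.0
    for _ in range(k):
        for area, dur in zip(chosen, dwell):
            events.append(BrushingEvent(onset=t, offset=t + dur, area=area))
            t += dur
    return BrushingSession(events)


def summarize_grid(
    rows: Sequence[GridRow], condition: str | None = None, digits: int = 2
) -> dict[str, dict[str, float]]:
    """Min/max/mean/sample-SD of C, I and TSI over the grid rows.

    With ``condition`` given, only rows of that condition enter; the
    summary is reported at two decimals by default, matching the printed
    precision of the index.
    """
    if condition is not None:
        rows = [r for r in rows if r.condition == condition]
    if not rows:
        raise ValueError("no grid rows to summarise")
    frame = grid_to_frame(rows)
    out: dict[str, dict[str, float]] = {}
    for col in ("c_value", "i_value", "tsi"):
        v = frame[col].to_numpy()
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        out[col] = {
            "min": round(float(v.min()), digits),
            "max": round(float(v.max()), digits),
            "mean": round(float(v.mean()), digits),
            "sd": round(sd, digits),
        }
    return out


def grid_to_frame(rows: Iterable[GridRow]) -> pd.DataFrame:
    """Long-format table of the scored grid."""
    return pd.DataFrame(
        [
            {
                "condition": r.condition,
                "i": r.i,
                "k": r.k,
                "b": r.b,
                "x": r.x,
                "c_value": r.c_value,
                "i_value": r.i_value,
                "tsi": r.tsi,
            }
            for r in rows
        ]
    )


def matrix_frame(rows: Sequence[GridRow], value: str = "tsi") -> pd.DataFrame:
    """Pivot one condition's rows into an areas x (duration, changes)
    matrix mirroring the validation-figure layout."""
    frame = grid_to_frame(rows)
    conditions = frame["condition"].unique()
    if len(conditions) != 1:
        raise ValueError("pivot one condition at a time")
    return frame.pivot_table(
        index="i", columns=["x", "b"], values=value, aggfunc="first"
    )
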