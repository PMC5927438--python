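"""Reading timed-event logs and writing scored results.

The on-disk dialect is a plain CSV (RFC-4180) with a header row and the
columns ``onset_s``, ``offset_s``, ``sextant``, ``surface``; extra columns
are ignored.  Surfaces are coded ``V`` (vestibular), ``O`` (oral), ``OCC``
(occlusal) or ``INC`` (incisal); full lower-case names are also accepted.
An optional ``session_id`` column keys multi-session batch files, and an
optional ``non_brushing`` column (truthy values: 1/true/yes) marks rows to
drop before scoring, e.g. spitting out.  Rows need not be pre-sorted; the
reader sorts by onset and then enforces non-overlap.

Proprietary exports from video-coding software can be mapped onto this
dialect by renaming columns; the index is defined on the behavioural
measures, not on any particular file format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .core import BrushingEvent, BrushingSession, SessionValidationError
from .schemes import SURFACE_CODES, SURFACES

__all__ = [
    "ResultRecord",
    "read_event_log",
    "read_sessions",
    "write_results",
    "read_results",
    "round_half_up",
    "load_config",
]

REQUIRED_COLUMNS = ("onset_s", "offset_s", "sextant", "surface")

_TRUTHY = {"1", "true", "yes", "y"}


@dataclass(frozen=True)
class ResultRecord:
    """One scored session in the results table."""

    session_id: str
    scheme: str
    b: int
    x: float
    i: int
    c_value: float
    i_value: float
    tsi: float


def round_half_up(value: float, digits: int = 2) -> float:
    """Round with ties away from zero, matching printed index values
    (banker's rounding would report 0.125 as 0.12 rather than 0.13)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def _parse_surface(code: object, row: int) -> str:
    text = str(code).strip()
    if text.upper() in SURFACE_CODES:
        return SURFACE_CODES[text.upper()]
    if text.lower() in SURFACES:
        return text.lower()
    raise SessionValidationError(
        f"row {row}: unknown surface code {code!r} "
        f"(expected one of {sorted(SURFACE_CODES)})"
    )


def _frame_to_session(frame: pd.DataFrame) -> BrushingSession:
    events = []
    for row_label, row in frame.iterrows():
        try:
            events.append(
                BrushingEvent(
                    onset=float(row["onset_s"]),
                    offset=float(row["offset_s"]),
                    area=(int(row["sextant"]), _parse_surface(row["surface"], row_label)),
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, SessionValidationError):
                raise
            raise SessionValidationError(f"row {row_label}: {exc}") from exc
    return BrushingSession(events)


def _load_frame(path: str | Path, delimiter: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError:
        raise SessionValidationError(f"{path}: empty event log") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SessionValidationError(
            f"{path}: missing required column(s) {missing}"
        )
    if frame.empty:
        raise SessionValidationError(f"{path}: event log has no rows")
    if "non_brushing" in frame.columns:
        flag = frame["non_brushing"].astype(str).str.strip().str.lower()
        frame = frame[~flag.isin(_TRUTHY)]
        if frame.empty:
            raise SessionValidationError(
                f"{path}: all rows are flagged non-brushing"
            )
    return frame


def read_event_log(path: str | Path, delimiter: str = ",") -> BrushingSession:
    """Read a single-session event log into a validated session.

    Raises :class:`~tsi.core.SessionValidationError` on missing columns,
    unknown surface codes, non-positive durations or overlapping intervals
    (the overlap message names both offending intervals).
    """
    return _frame_to_session(_load_frame(path, delimiter))


def read_sessions(
    path: str | Path, delimiter: str = ","
) -> dict[str, BrushingSession]:
    """Read a batch file; sessions are keyed by the ``session_id`` column.

    A file without a ``session_id`` column yields one session keyed by the
    file stem.
    """
    frame = _load_frame(path, delimiter)
    if "session_id" not in frame.columns:
        return {Path(path).stem: _frame_to_session(frame)}
    out: dict[str, BrushingSession] = {}
    for sid, group in frame.groupby("session_id", sort=False):
        out[str(sid)] = _frame_to_session(group)
    return out


def write_results(
    records: Sequence[ResultRecord],
    path: str | Path,
    digits: int = 2,
    delimiter: str = ",",
) -> None:
    """Write scored sessions as a delimited table with header.

    Index values (c_value, i_value, tsi) and x are written at the given
    precision (default two decimals, half-up); counts are exact.
    """
    if not records:
        raise ValueError("no result records to write")
    rows = []
    for r in records:
        rows.append(
            {
                "session_id": r.session_id,
                "scheme": r.scheme,
                "b": r.b,
                "x": round_half_up(r.x, digits),
                "i": r.i,
                "c_value": round_half_up(r.c_value, digits),
                "i_value": round_half_up(r.i_value, digits),
                "tsi": round_half_up(r.tsi, digits),
            }
        )
    frame = pd.DataFrame(rows)
    fmt = f"%.{digits}f"
    frame.to_csv(path, sep=delimiter, index=False, float_format=fmt)


def read_results(path: str | Path, delimiter: str = ",") -> list[ResultRecord]:
    """Read back a results table written by :func:`write_results`."""
    frame = pd.read_csv(path, sep=delimiter)
    names = [f.name for f in fields(ResultRecord)]
    return [
        ResultRecord(**{k: row[k] for k in names})
        for _, row in frame.iterrows()
    ]


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration.

    Recognised keys: ``scheme`` ('all' | 'vo' | 'all_incisal' or an explicit
    list of [sextant, surface] pairs), ``delimiter``, ``digits``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data
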