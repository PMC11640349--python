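"""Event logs, time normalization, and TDS / temporal-liking curves.

Temporal dominance of sensations (TDS) tasks record which single sensory
attribute a panelist perceives as dominant at each moment of a tasting
trial; temporal-liking tasks record a 1-9 hedonic score that is re-entered
whenever preference changes.  Both are captured here as timed button-press
event logs.  Trial time is normalized to [0, 1] (start button = 0, stop
button = 1) so trials of different durations can be averaged, and curves
are evaluated on a shared evenly spaced grid:

* a TDS curve set gives, per attribute and grid point, the fraction of
  trials in which that attribute was the dominant selection (dominance
  proportion);
* a liking curve carries the last-entered score forward in time, with 0
  before the first rating, averaged across trials.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_ATTRIBUTES",
    "AttributeSet",
    "PressEvent",
    "Trial",
    "PanelEventLog",
    "TimeGrid",
    "TDSCurveSet",
    "LikingCurve",
    "CurvePair",
    "EventLogError",
    "parse_event_log",
    "write_event_log",
    "normalize_trial",
    "dominant_attribute_at",
    "tds_curves",
    "liking_curve",
    "write_curve_pair",
    "read_tds_csv",
    "read_liking_csv",
]

#: The eight strawberry attributes, in task-interface order.
DEFAULT_ATTRIBUTES = (
    "aromatic", "juicy", "sweet", "fruity", "light", "watery", "green", "sour",
)

EVENT_KINDS = ("start", "tds_select", "liking_score", "stop")

#: Canonical float format for curve CSVs; lossless for doubles that round-trip
#: at 12 significant digits.
FLOAT_FMT = "%.12g"


class EventLogError(ValueError):
    """Raised for malformed event-log rows or inconsistent trials."""


@dataclass(frozen=True)
class AttributeSet:
    """Ordered set of TDS attribute labels."""

    names: tuple[str, ...] = DEFAULT_ATTRIBUTES

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ValueError("attribute set must be non-empty")
        if any(not n for n in self.names):
            raise ValueError("attribute labels must be non-empty strings")
        if len(set(self.names)) != len(self.names):
            raise ValueError("attribute labels must be unique")

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError:
            raise KeyError(f"unknown attribute label {label!r}") from None

    def __contains__(self, label: object) -> bool:
        return label in self.names

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class PressEvent:
    """A single timed button press.

    ``value`` is an attribute label for ``tds_select`` events, an integer
    score in 1..9 for ``liking_score`` events, and ``None`` for
    ``start``/``stop``.
    """

    time_s: float
    kind: str
    value: str | int | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.time_s < 0:
            raise ValueError("event time must be non-negative")
        if self.kind == "liking_score":
            if not isinstance(self.value, (int, np.integer)) or not 1 <= int(self.value) <= 9:
                raise ValueError("liking score out of 1-9")
        elif self.kind == "tds_select":
            if not isinstance(self.value, str) or not self.value:
                raise ValueError("tds_select needs an attribute label")
        elif self.value is not None:
            raise ValueError(f"{self.kind} events carry no value")


@dataclass
class Trial:
    """One task run by one participant: a time-ordered event sequence.

    Events are stored in seconds; :func:`normalize_trial` produces a copy
    on normalized time (stop at exactly 1.0).
    """

    participant_id: str
    trial_index: int
    events: list[PressEvent]
    duration_s: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise EventLogError(
                f"trial ({self.participant_id}, {self.trial_index}): "
                "duration must be positive"
            )
        starts = [e for e in self.events if e.kind == "start"]
        stops = [e for e in self.events if e.kind == "stop"]
        ident = f"trial ({self.participant_id}, {self.trial_index})"
        if len(starts) != 1 or starts[0].time_s != 0.0:
            raise EventLogError(f"{ident}: needs exactly one start event at t=0")
        if len(stops) != 1 or stops[0].time_s != self.duration_s:
            raise EventLogError(f"{ident}: needs exactly one stop event at the trial duration")
        times = [e.time_s for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise EventLogError(f"{ident}: event times are not sorted")
        # a selection may coincide with start (press at t=0) but two events
        # of the same kind cannot share a timestamp
        stamps = [(e.time_s, e.kind) for e in self.events]
        if len(set(stamps)) != len(stamps):
            raise EventLogError(f"{ident}: two events of the same kind share a timestamp")
        if any(not 0 <= t <= self.duration_s for t in times):
            raise EventLogError(f"{ident}: event outside [0, duration]")

    @property
    def tds_events(self) -> list[PressEvent]:
        return [e for e in self.events if e.kind == "tds_select"]

    @property
    def liking_events(self) -> list[PressEvent]:
        return [e for e in self.events if e.kind == "liking_score"]

    @property
    def task(self) -> str:
        """'tds', 'liking', or 'empty' (no selection/rating events)."""
        if self.tds_events:
            return "tds"
        if self.liking_events:
            return "liking"
        return "empty"


@dataclass
class PanelEventLog:
    """All trials of a panel, with diagnostics for rejected trials."""

    trials: list[Trial]
    rejected: list[str] = field(default_factory=list)

    @property
    def tds_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.task == "tds"]

    @property
    def liking_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.task == "liking"]

    def by_participant(self, task: str | None = None) -> dict[str, list[Trial]]:
        out: dict[str, list[Trial]] = {}
        for t in self.trials:
            if task is not None and t.task != task:
                continue
            out.setdefault(t.participant_id, []).append(t)
        return out

    def __len__(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class TimeGrid:
    """m points evenly spaced on normalized time [0, 1], endpoints included."""

    m: int = 101

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("grid needs at least 2 points")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.m)


@dataclass
class TDSCurveSet:
    """Dominance proportions on a grid: proportions[i, a] is the fraction of
    trials whose dominant attribute at times[i] is attribute a."""

    grid: TimeGrid
    attributes: AttributeSet
    proportions: np.ndarray  # (m, n)

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape != (self.grid.m, self.attributes.n):
            raise ValueError("proportions shape must be (m, n)")
        if np.any(self.proportions < -1e-12) or np.any(self.proportions > 1 + 1e-12):
            raise ValueError("dominance proportions must lie in [0, 1]")
        if np.any(self.proportions.sum(axis=1) > 1 + 1e-9):
            raise ValueError("dominance proportions sum to more than 1 at some time")


@dataclass
class LikingCurve:
    """Temporal liking scores on a grid; 0 before the first rating."""

    grid: TimeGrid
    values: np.ndarray  # (m,)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.m,):
            raise ValueError("values shape must be (m,)")
        if np.any(self.values < -1e-12) or np.any(self.values > 9 + 1e-12):
            raise ValueError("liking values must lie in [0, 9]")


@dataclass
class CurvePair:
    """A TDS curve set and the matching liking curve on one shared grid."""

    tds: TDSCurveSet
    liking: LikingCurve

    def __post_init__(self) -> None:
        if self.tds.grid != self.liking.grid:
            raise ValueError("TDS and liking curves must share the grid")

    @property
    def grid(self) -> TimeGrid:
        return self.tds.grid


# ---------------------------------------------------------------------------
# event-log CSV round trip
# ---------------------------------------------------------------------------

def parse_event_log(
    path: str | Path,
    attributes: AttributeSet | None = None,
) -> PanelEventLog:
    """Read an event-log CSV into trials.

    The dialect is ``participant_id,trial_index,time_s,kind,value`` with a
    header row.  Row-level problems (unknown kind or attribute, liking score
    outside 1-9, unparsable numbers, non-monotone times within a trial)
    raise :class:`EventLogError` naming the offending line.  Trials missing
    their start or stop event are rejected with a diagnostic in
    ``log.rejected`` rather than aborting the whole file.
    """
    attributes = attributes or AttributeSet()
    rows: dict[tuple[str, int], list[tuple[int, PressEvent]]] = {}
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["participant_id", "trial_index", "time_s", "kind", "value"]:
            raise EventLogError(f"{path}: unexpected header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c for c in row):
                continue
            if len(row) != 5:
                raise EventLogError(f"{path}:{lineno}: expected 5 columns, got {len(row)}")
            pid, idx_s, time_s, kind, value = (c.strip() for c in row)
            try:
                idx = int(idx_s)
                t = float(time_s)
            except ValueError as exc:
                raise EventLogError(f"{path}:{lineno}: {exc}") from None
            if kind not in EVENT_KINDS:
                raise EventLogError(f"{path}:{lineno}: unknown event kind {kind!r}")
            val: str | int | None = None
            if kind == "tds_select":
                if value not in attributes:
                    raise EventLogError(
                        f"{path}:{lineno}: unknown attribute label {value!r}"
                    )
                val = value
            elif kind == "liking_score":
                try:
                    val = int(value)
                except ValueError:
                    raise EventLogError(
                        f"{path}:{lineno}: liking score {value!r} is not an integer"
                    ) from None
                if not 1 <= val <= 9:
                    raise EventLogError(f"{path}:{lineno}: liking score out of 1-9")
            elif value:
                raise EventLogError(f"{path}:{lineno}: {kind} rows must have empty value")
            try:
                ev = PressEvent(t, kind, val)
            except ValueError as exc:
                raise EventLogError(f"{path}:{lineno}: {exc}") from None
            rows.setdefault((pid, idx), []).append((lineno, ev))

    trials: list[Trial] = []
    rejected: list[str] = []
    for (pid, idx), recs in rows.items():
        times = [ev.time_s for _, ev in recs]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            bad = next(ln for (ln, _), t1, t2 in zip(recs[1:], times, times[1:]) if t2 < t1)
            raise EventLogError(
                f"{path}:{bad}: non-monotone event times in trial ({pid}, {idx})"
            )
        events = [ev for _, ev in recs]
        stops = [ev for ev in events if ev.kind == "stop"]
        starts = [ev for ev in events if ev.kind == "start"]
        if len(starts) != 1 or len(stops) != 1:
            rejected.append(
                f"trial ({pid}, {idx}): needs exactly one start and one stop "
                f"(found {len(starts)} start, {len(stops)} stop)"
            )
            continue
        try:
            trials.append(Trial(pid, idx, events, duration_s=stops[0].time_s))
        except EventLogError as exc:
            rejected.append(str(exc))
    trials.sort(key=lambda tr: (tr.participant_id, tr.trial_index))
    return PanelEventLog(trials, rejected)


def write_event_log(log: PanelEventLog | Iterable[Trial], path: str | Path) -> None:
    """Write trials back to the event-log CSV dialect (canonical floats)."""
    trials = log.trials if isinstance(log, PanelEventLog) else list(log)
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "trial_index", "time_s", "kind", "value"])
        for tr in trials:
            for ev in tr.events:
                writer.writerow([
                    tr.participant_id,
                    tr.trial_index,
                    FLOAT_FMT % ev.time_s,
                    ev.kind,
                    "" if ev.value is None else ev.value,
                ])


# ---------------------------------------------------------------------------
# normalization and curves
# ---------------------------------------------------------------------------

def normalize_trial(trial: Trial) -> Trial:
    """Return a copy of the trial with times divided by its duration.

    The stop event maps to exactly 1.0.  Idempotent on already-normalized
    trials (their duration is 1.0).
    """
    if trial.duration_s <= 0:
        raise EventLogError("cannot normalize a trial with non-positive duration")
    d = trial.duration_s
    events = [
        PressEvent(1.0 if ev.kind == "stop" else ev.time_s / d, ev.kind, ev.value)
        for ev in trial.events
    ]
    return Trial(trial.participant_id, trial.trial_index, events,
                 duration_s=1.0, normalized=True)


def _require_normalized(trials: Sequence[Trial]) -> None:
    for tr in trials:
        if not tr.normalized:
            raise ValueError("trials must be normalized first (normalize_trial)")


def dominant_attribute_at(trial: Trial, t: float) -> str | None:
    """Dominant attribute of a normalized trial at time t (carry-forward).

    A press takes effect at its own timestamp: the latest ``tds_select``
    with press time <= t wins.  Returns ``None`` before the first press.
    """
    if not trial.normalized:
        raise ValueError("trial must be normalized")
    if not 0 <= t <= 1:
        raise ValueError("t must lie in [0, 1]")
    current: str | None = None
    for ev in trial.tds_events:
        if ev.time_s <= t:
            current = ev.value  # type: ignore[assignment]
        else:
            break
    return current


def _carry_forward_indices(press_times: np.ndarray, grid_times: np.ndarray) -> np.ndarray:
    """Index of the latest press at or before each grid time (-1 if none)."""
    return np.searchsorted(press_times, grid_times, side="right") - 1


def tds_curves(
    trials: Sequence[Trial],
    grid: TimeGrid | None = None,
    attributes: AttributeSet | None = None,
) -> TDSCurveSet:
    """Dominance-proportion curves over a set of normalized trials.

    At each grid point the proportion for attribute a is the fraction of
    trials whose dominant (carried-forward) selection is a.  Trials that
    have not yet made a first selection contribute to no attribute, so row
    sums are below 1 early in the task and reach 1 once every trial has
    selected something.
    """
    trials = [t for t in trials if t.task != "liking"]
    if not trials:
        raise ValueError("need at least one TDS trial")
    _require_normalized(trials)
    grid = grid or TimeGrid()
    attributes = attributes or AttributeSet()
    counts = np.zeros((grid.m, attributes.n))
    gt = grid.times
    for tr in trials:
        presses = tr.tds_events
        if not presses:
            continue
        times = np.array([ev.time_s for ev in presses])
        labels = np.array([attributes.index(ev.value) for ev in presses])
        idx = _carry_forward_indices(times, gt)
        active = idx >= 0
        np.add.at(counts, (np.nonzero(active)[0], labels[idx[active]]), 1.0)
    return TDSCurveSet(grid, attributes, counts / len(trials))


def liking_curve(trials: Sequence[Trial], grid: TimeGrid | None = None) -> LikingCurve:
    """Mean carried-forward liking over normalized trials.

    Per trial the curve is a step function: 0 before the first rating, then
    the last-entered score.  The returned curve is the pointwise arithmetic
    mean across trials (fractional values are expected).
    """
    trials = [t for t in trials if t.task != "tds"]
    if not trials:
        raise ValueError("need at least one liking trial")
    _require_normalized(trials)
    grid = grid or TimeGrid()
    total = np.zeros(grid.m)
    gt = grid.times
    for tr in trials:
        presses = tr.liking_events
        if not presses:
            continue  # never rated: contributes 0 everywhere
        times = np.array([ev.time_s for ev in presses])
        scores = np.array([float(ev.value) for ev in presses])
        idx = _carry_forward_indices(times, gt)
        vals = np.where(idx >= 0, scores[np.clip(idx, 0, None)], 0.0)
        total += vals
    return LikingCurve(grid, total / len(trials))


# ---------------------------------------------------------------------------
# curve CSV round trip
# ---------------------------------------------------------------------------

def _write_table(path: Path, header: list[str], columns: list[np.ndarray]) -> None:
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for row in zip(*columns):
            writer.writerow([FLOAT_FMT % v for v in row])


def write_curve_pair(pair: CurvePair, tds_path: str | Path, liking_path: str | Path) -> None:
    """Write a curve pair as two CSVs: ``t`` plus attribute columns, and
    ``t,liking``.  Floats use a canonical 12-significant-digit format so a
    write -> read -> write cycle is bit-identical."""
    grid = pair.grid
    _write_table(
        Path(tds_path),
        ["t", *pair.tds.attributes.names],
        [grid.times, *[pair.tds.proportions[:, j] for j in range(pair.tds.attributes.n)]],
    )
    _write_table(Path(liking_path), ["t", "liking"], [grid.times, pair.liking.values])


def _read_table(path: Path) -> tuple[list[str], np.ndarray]:
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        data = np.array([[float(c) for c in row] for row in reader if row])
    return header, data


def read_tds_csv(path: str | Path) -> TDSCurveSet:
    header, data = _read_table(Path(path))
    if header[0] != "t":
        raise ValueError(f"{path}: first column must be 't'")
    grid = TimeGrid(data.shape[0])
    if not np.allclose(data[:, 0], grid.times, atol=1e-9):
        raise ValueError(f"{path}: time column is not an even [0,1] grid")
    return TDSCurveSet(grid, AttributeSet(tuple(header[1:])), data[:, 1:])


def read_liking_csv(path: str | Path) -> LikingCurve:
    header, data = _read_table(Path(path))
    if header != ["t", "liking"]:
        raise ValueError(f"{path}: expected columns t,liking")
    grid = TimeGrid(data.shape[0])
    if not np.allclose(data[:, 0], grid.times, atol=1e-9):
        raise ValueError(f"{path}: time column is not an even [0,1] grid")
    return LikingCurve(grid, data[:, 1])
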