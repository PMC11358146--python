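"""Stimulus schedule, continuous rating traces and the TR-grid condition labels.

The music-listening run is a fixed sequence of 13 classical pieces (3 happy,
3 sad, 7 neutral) separated by 2 s of silence; participants continuously rate
how the music makes them feel on a -6 (very sad) .. +6 (very happy) scale while
BOLD volumes are acquired every ``tr_s`` seconds.  This module parses and
validates the schedule, maps each acquired volume to a song condition
(including the sequence-derived ``neutral_following_sad`` /
``neutral_following_happy`` categories) and resamples a rating trace onto the
volume grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "VALENCE_LABELS",
    "DERIVED_LABELS",
    "StimulusEvent",
    "StimulusSchedule",
    "RatingTrace",
    "SubjectMeta",
    "ConditionLabels",
    "ScheduleValidationError",
    "parse_schedule",
    "load_schedule",
    "write_schedule",
    "table1_schedule",
    "label_timepoints",
    "resample_ratings",
]

logger = logging.getLogger(__name__)

VALENCE_LABELS = ("happy", "sad", "neutral")
DERIVED_LABELS = ("neutral_following_sad", "neutral_following_happy", "none")
SILENCE = "silence"


class ScheduleValidationError(ValueError):
    """Raised when a stimulus schedule violates its structural invariants."""


@dataclass(frozen=True)
class StimulusEvent:
    """One timed musical piece with a valence label."""

    index: int
    start_s: float
    end_s: float
    label: str
    title: str = ""
    composer: str = ""

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ScheduleValidationError(
                f"event {self.index}: end_s ({self.end_s}) must exceed start_s ({self.start_s})"
            )
        if self.label not in VALENCE_LABELS:
            raise ScheduleValidationError(
                f"event {self.index}: unknown label {self.label!r}; expected one of {VALENCE_LABELS}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered, non-overlapping musical events with a constant inter-piece gap.

    ``silence_s`` is ``None`` (flagged, not an error) when the schedule has a
    single event, so no consecutive gap exists.
    """

    events: tuple[StimulusEvent, ...]
    silence_s: float | None

    def __post_init__(self) -> None:
        starts = [e.start_s for e in self.events]
        if sorted(starts) != starts:
            raise ScheduleValidationError("events are not sorted by start_s")

    @property
    def end_s(self) -> float:
        return self.events[-1].end_s

    def labels(self) -> list[str]:
        return [e.label for e in self.events]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [e.index for e in self.events],
                "start_s": [e.start_s for e in self.events],
                "end_s": [e.end_s for e in self.events],
                "label": [e.label for e in self.events],
                "title": [e.title for e in self.events],
                "composer": [e.composer for e in self.events],
            }
        )


@dataclass(frozen=True)
class RatingTrace:
    """One subject's continuous emotion ratings on a uniform time grid."""

    subject_id: str
    values: np.ndarray
    dt_s: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("rating trace needs at least 2 samples")
        if not self.dt_s > 0:
            raise ValueError("dt_s must be positive")
        if np.any(np.isnan(self.values)):
            raise ValueError(f"{self.subject_id}: rating trace contains missing samples")
        if self.values.min() < -6 or self.values.max() > 6:
            raise ValueError(f"{self.subject_id}: ratings outside the [-6, +6] scale")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject questionnaire and demographic metadata.

    ``masq_ad`` is the 14-item anhedonic-depression subscale total (each item
    1-5, hence 14..70); ``music_background`` is the 1-5 classical-music
    knowledge item used as a nuisance covariate.
    """

    subject_id: str
    masq_ad: int
    age: float
    gender: str
    music_background: int

    def __post_init__(self) -> None:
        if not 14 <= self.masq_ad <= 70:
            raise ValueError(f"{self.subject_id}: MASQ-AD {self.masq_ad} outside [14, 70]")
        if not 1 <= self.music_background <= 5:
            raise ValueError(
                f"{self.subject_id}: music_background {self.music_background} outside [1, 5]"
            )


@dataclass(frozen=True)
class ConditionLabels:
    """Per-volume condition labels on the scanner TR grid.

    ``labels[v]`` is the valence of the event containing volume ``v``'s
    temporal midpoint (``silence`` if none), ``derived[v]`` marks volumes of
    neutral events immediately preceded by a sad/happy event, and
    ``event_index[v]`` is the 1-based schedule index of that event (0 during
    silence).
    """

    labels: np.ndarray
    derived: np.ndarray
    event_index: np.ndarray
    tr_s: float
    dummy_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.derived) == len(self.event_index)):
            raise ValueError("labels, derived and event_index must have equal length")
        bad = (np.asarray(self.derived) != "none") & (np.asarray(self.labels) != "neutral")
        if bad.any():
            raise ValueError("derived labels may only mark neutral volumes")

    @property
    def n_volumes(self) -> int:
        return int(len(self.labels))

    def midpoints_s(self) -> np.ndarray:
        """Clock time of each volume's temporal midpoint."""
        return self.dummy_offset_s + (np.arange(self.n_volumes) + 0.5) * self.tr_s

    def mask(self, condition: str) -> np.ndarray:
        """Boolean volume mask for a base or derived condition."""
        if condition in DERIVED_LABELS[:2]:
            return np.asarray(self.derived) == condition
        return np.asarray(self.labels) == condition


def parse_schedule(rows: Iterable[Mapping] | pd.DataFrame) -> StimulusSchedule:
    """Validate tabular records into a :class:`StimulusSchedule`.

    The inter-piece silence is inferred as the unique gap between consecutive
    events; a non-constant gap, overlapping or non-monotone events, or an
    unknown label raise :class:`ScheduleValidationError` naming the offending
    row.
    """
    if isinstance(rows, pd.DataFrame):
        rows = rows.to_dict("records")
    events = []
    for row in rows:
        events.append(
            StimulusEvent(
                index=int(row["index"]),
                start_s=float(row["start_s"] if "start_s" in row else row["start"]),
                end_s=float(row["end_s"] if "end_s" in row else row["end"]),
                label=str(row["label"]).strip().lower(),
                title=str(row.get("title", "")),
                composer=str(row.get("composer", "")),
            )
        )
    if not events:
        raise ScheduleValidationError("schedule has no events")
    events.sort(key=lambda e: e.start_s)
    gaps = []
    for prev, nxt in zip(events, events[1:]):
        if nxt.start_s < prev.end_s:
            raise ScheduleValidationError(
                f"event {nxt.index} (start {nxt.start_s}) overlaps event "
                f"{prev.index} (end {prev.end_s})"
            )
        gaps.append(nxt.start_s - prev.end_s)
    silence_s: float | None
    if not gaps:
        silence_s = None
        logger.warning("single-event schedule: silence_s undefined")
    else:
        if np.ptp(gaps) > 1e-9:
            i = int(np.argmax(np.abs(np.asarray(gaps) - gaps[0])))
            raise ScheduleValidationError(
                f"non-constant inter-piece gap: event {events[i + 1].index} follows "
                f"after {gaps[i]} s but the first gap is {gaps[0]} s"
            )
        silence_s = float(gaps[0])
    return StimulusSchedule(events=tuple(events), silence_s=silence_s)


def load_schedule(path) -> StimulusSchedule:
    """Read a delimited schedule (columns index,start_s,end_s,label,title,composer)."""
    return parse_schedule(pd.read_csv(path, sep="\t", comment="#"))


def write_schedule(schedule: StimulusSchedule, path) -> None:
    schedule.to_frame().to_csv(path, sep="\t", index=False)


def table1_schedule() -> StimulusSchedule:
    """The packaged 13-piece run schedule (verbatim stimulus timing table)."""
    ref = resources.files("musicstates.data").joinpath("stimulus_schedule.tsv")
    with resources.as_file(ref) as path:
        return load_schedule(path)


def label_timepoints(
    schedule: StimulusSchedule,
    tr_s: float,
    n_volumes: int,
    dummy_offset_s: float = 0.0,
) -> ConditionLabels:
    """Assign each acquired volume a condition from the schedule.

    Volume ``v`` covers clock time ``[dummy_offset_s + v*tr_s,
    dummy_offset_s + (v+1)*tr_s)`` and takes the label of the event whose
    half-open window ``[start_s, end_s)`` contains the volume midpoint, else
    ``silence``.  A neutral event immediately preceded (in schedule order) by a
    sad (happy) event contributes ``neutral_following_sad``
    (``neutral_following_happy``) derived labels for all of its volumes.
    Volumes past the schedule end are silence, never an error.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    if not tr_s > 0:
        raise ValueError("tr_s must be positive")
    events = schedule.events
    derived_of_event = {}
    for prev, nxt in zip(events, events[1:]):
        if nxt.label == "neutral" and prev.label in ("sad", "happy"):
            derived_of_event[nxt.index] = f"neutral_following_{prev.label}"

    mids = dummy_offset_s + (np.arange(n_volumes) + 0.5) * tr_s
    starts = np.array([e.start_s for e in events])
    ends = np.array([e.end_s for e in events])
    # half-open [start, end): index of the last event starting at or before mid
    pos = np.searchsorted(starts, mids, side="right") - 1
    labels = np.full(n_volumes, SILENCE, dtype=object)
    derived = np.full(n_volumes, "none", dtype=object)
    event_index = np.zeros(n_volumes, dtype=int)
    inside = (pos >= 0) & (mids < ends[np.clip(pos, 0, len(events) - 1)])
    for v in np.nonzero(inside)[0]:
        ev = events[pos[v]]
        labels[v] = ev.label
        event_index[v] = ev.index
        derived[v] = derived_of_event.get(ev.index, "none")
    return ConditionLabels(
        labels=labels,
        derived=derived,
        event_index=event_index,
        tr_s=float(tr_s),
        dummy_offset_s=float(dummy_offset_s),
    )


def resample_ratings(trace: RatingTrace, labels: ConditionLabels) -> np.ndarray:
    """Resample a rating trace onto the TR grid (one value per volume).

    The rating of volume ``v`` is the trace sample nearest the volume midpoint,
    ties broken toward the earlier sample.  Raises if the trace does not cover
    the labelled span.
    """
    mids = labels.midpoints_s()
    q = (mids - trace.t0_s) / trace.dt_s
    idx = np.ceil(q - 0.5).astype(int)  # nearest, ties to the earlier sample
    if idx.min() < 0 or idx.max() >= trace.n_samples:
        raise ValueError(
            f"{trace.subject_id}: rating trace ({trace.n_samples} samples, dt "
            f"{trace.dt_s}s from t0 {trace.t0_s}s) does not cover the labelled span "
            f"(midpoints {mids[0]:g}..{mids[-1]:g}s)"
        )
    return trace.values[idx]
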