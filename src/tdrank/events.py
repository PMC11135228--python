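"""Patient event timelines and the treatment-discontinuation (TD) labeling rule.

A patient discontinues treatment when they miss a scheduled clinical
appointment and then fail to visit the clinic within a patient-specific
threshold: three times their mean recent inter-visit interval, capped at
60 days.  Patients with no confirmed discontinuation are treatment
continuers (TC) and are right-censored at their most recent recorded
visit.

All dates are integer day indices.  ISO-8601 dates in input files are
converted to day ordinals on load; no calendar or timezone logic exists
beyond that conversion.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

log = logging.getLogger(__name__)

#: Hard cap on the no-return threshold, in days.
TD_THRESHOLD_CAP = 60.0

#: Event streams the pipeline understands.
KNOWN_STREAMS = frozenset(
    {
        "visit",
        "appointment",
        "diagnosis",
        "prescription",
        "lab",
        "attribute",
        "consultation",
        "surgery",
        "guidance",
    }
)

#: Attribute code marking patients excluded from TD labeling
#: (death or documented change of care setting).
EXCLUSION_CODE = "td_exclusion"


class NoVisitHistoryError(ValueError):
    """Raised when an operation requires at least one recorded visit."""


@dataclass(frozen=True)
class Event:
    """One row of an EHR-style event log.

    ``aux`` carries stream-specific fields; appointment events use
    ``scheduled_date`` (the day the appointment falls on), ``made_date``
    (the day it was booked) and ``status`` in {kept, missed, pending}.
    """

    patient_id: str
    date: int
    stream: str
    code: str
    value: float | None = None
    unit: str | None = None
    aux: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stream == "appointment":
            sched = self.aux.get("scheduled_date")
            made = self.aux.get("made_date")
            if sched is not None and made is not None and sched < made:
                raise ValueError(
                    f"appointment scheduled_date {sched} precedes made_date {made}"
                )


@dataclass
class PatientTimeline:
    """Ordered event log for a single patient up to a data cutoff."""

    patient_id: str
    events: list[Event]
    data_cutoff: int

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.date)
        for e in self.events:
            if e.date > self.data_cutoff:
                raise ValueError(
                    f"event at day {e.date} beyond data cutoff {self.data_cutoff}"
                )

    def visit_days(self) -> list[int]:
        """Sorted distinct days on which the patient attended the clinic.

        A kept appointment counts as a visit even without a same-day
        visit record.
        """
        days = set()
        for e in self.events:
            if e.stream == "visit":
                days.add(e.date)
            elif e.stream == "appointment" and e.aux.get("status") == "kept":
                days.add(int(e.aux.get("scheduled_date", e.date)))
        return sorted(days)

    def missed_appointment_days(self) -> list[int]:
        return sorted(
            int(e.aux.get("scheduled_date", e.date))
            for e in self.events
            if e.stream == "appointment" and e.aux.get("status") == "missed"
        )

    @property
    def excluded(self) -> bool:
        """Physician-style exclusion flag (death / care-setting change)."""
        return any(
            e.stream == "attribute" and e.code == EXCLUSION_CODE for e in self.events
        )


@dataclass(frozen=True)
class TDLabel:
    """Outcome of the labeling rule for one patient.

    For TD the anchor is the missed appointment that established the
    discontinuation; for TC it is the most recent recorded visit.
    """

    status: str  # "TD" or "TC"
    anchor_date: int
    threshold_days: float


@dataclass(frozen=True)
class IndexedObservation:
    """A (patient, index date) observation with its time-to-event length.

    ``length_days`` is the number of days from the index date to the
    anchor: the TD-establishing missed appointment when ``is_td`` is
    true, otherwise the censoring time at the last recorded visit.
    """

    patient_id: str
    index_date: int
    length_days: int
    is_td: bool


def mean_recent_interval(timeline: PatientTimeline, at: int) -> float | None:
    """Mean of the intervals between the last 3 visit days at or before ``at``.

    With exactly two visits the single interval is returned; with one
    visit the interval is undefined (``None``) and callers fall back to
    the 60-day cap alone.
    """
    visits = [d for d in timeline.visit_days() if d <= at]
    if not visits:
        raise NoVisitHistoryError(f"no visit history for {timeline.patient_id} at day {at}")
    recent = visits[-3:]
    if len(recent) == 1:
        return None
    gaps = [b - a for a, b in zip(recent, recent[1:])]
    return sum(gaps) / len(gaps)


def td_threshold(mean_interval: float | None) -> float:
    """No-return threshold: min(3 x mean recent interval, 60) days."""
    if mean_interval is None:
        return TD_THRESHOLD_CAP
    if mean_interval <= 0:
        raise ValueError(f"mean interval must be positive, got {mean_interval}")
    return min(3.0 * mean_interval, TD_THRESHOLD_CAP)


def label_patient(timeline: PatientTimeline) -> TDLabel:
    """Apply the TD rule to one patient.

    Missed appointments are scanned in date order; the first one with no
    subsequent visit within the threshold — and whose threshold window
    closes on or before the data cutoff, so the absence is confirmable —
    yields TD.  Otherwise the patient is TC, anchored at the last visit.
    Patients carrying the exclusion flag are never labeled TD.
    """
    visits = timeline.visit_days()
    if not visits:
        raise NoVisitHistoryError(f"no visit history for {timeline.patient_id}")
    last_visit = visits[-1]

    if not timeline.excluded:
        for miss_day in timeline.missed_appointment_days():
            try:
                mi = mean_recent_interval(timeline, at=miss_day)
            except NoVisitHistoryError:
                mi = None  # miss precedes any visit: cap alone applies
            thr = td_threshold(mi)
            window_end = miss_day + thr
            if window_end > timeline.data_cutoff:
                continue  # censored: cannot confirm no-return
            if not any(miss_day < v <= window_end for v in visits):
                return TDLabel(status="TD", anchor_date=miss_day, threshold_days=thr)

    mi = mean_recent_interval(timeline, at=last_visit)
    return TDLabel(status="TC", anchor_date=last_visit, threshold_days=td_threshold(mi))


def length_until_event(timeline: PatientTimeline, index_date: int) -> IndexedObservation:
    """Days from a visit (the index date) to the patient's anchor event.

    For a TD patient this is the time to the discontinuation-defining
    missed appointment; for a TC patient the time to the last recorded
    visit (the censoring time).
    """
    if index_date not in timeline.visit_days():
        raise ValueError(
            f"index date {index_date} is not a recorded visit day of {timeline.patient_id}"
        )
    lab = label_patient(timeline)
    length = lab.anchor_date - index_date
    if length < 0:
        raise ValueError(
            f"index date {index_date} lies after anchor {lab.anchor_date} "
            f"for {timeline.patient_id}"
        )
    return IndexedObservation(
        patient_id=timeline.patient_id,
        index_date=index_date,
        length_days=int(length),
        is_td=lab.status == "TD",
    )


# ---------------------------------------------------------------------------
# File round-tripping

_EVENT_COLUMNS = [
    "patient_id",
    "date",
    "stream",
    "code",
    "value",
    "unit",
    "scheduled_date",
    "made_date",
    "status",
]


def _coerce_day(raw: object) -> int:
    """Accept integer day indices or ISO-8601 dates (converted to ordinals)."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        raise ValueError("missing date")
    try:
        return int(raw)
    except (TypeError, ValueError):
        return _dt.date.fromisoformat(str(raw).strip()).toordinal()


def events_to_frame(events: Iterable[Event]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(
            {
                "patient_id": e.patient_id,
                "date": e.date,
                "stream": e.stream,
                "code": e.code,
                "value": e.value,
                "unit": e.unit,
                "scheduled_date": e.aux.get("scheduled_date"),
                "made_date": e.aux.get("made_date"),
                "status": e.aux.get("status"),
            }
        )
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def frame_to_timelines(
    frame: pd.DataFrame, data_cutoff: int | None = None
) -> dict[str, PatientTimeline]:
    """Group an event-log table into per-patient timelines.

    The cutoff defaults to the latest date observed anywhere in the log
    (appointment scheduled dates included: a pending appointment proves
    observability up to its day was intended, but confirmation windows
    still respect the realised cutoff).
    """
    events: dict[str, list[Event]] = {}
    max_day = 0
    for row in frame.itertuples(index=False):
        day = _coerce_day(row.date)
        max_day = max(max_day, day)
        aux: dict[str, object] = {}
        for key in ("scheduled_date", "made_date"):
            raw = getattr(row, key, None)
            if raw is not None and not pd.isna(raw):
                aux[key] = _coerce_day(raw)
        status = getattr(row, "status", None)
        if status is not None and not pd.isna(status):
            aux["status"] = str(status)
        value = getattr(row, "value", None)
        if value is not None and pd.isna(value):
            value = None
        unit = getattr(row, "unit", None)
        if unit is not None and pd.isna(unit):
            unit = None
        events.setdefault(str(row.patient_id), []).append(
            Event(
                patient_id=str(row.patient_id),
                date=day,
                stream=str(row.stream),
                code=str(row.code),
                value=None if value is None else float(value),
                unit=None if unit is None else str(unit),
                aux=aux,
            )
        )
    cutoff = data_cutoff if data_cutoff is not None else max_day
    return {
        pid: PatientTimeline(patient_id=pid, events=evs, data_cutoff=cutoff)
        for pid, evs in sorted(events.items())
    }


def read_event_log(path: str | Path, data_cutoff: int | None = None) -> dict[str, PatientTimeline]:
    """Read a CSV or JSONL event log into per-patient timelines."""
    path = Path(path)
    if path.suffix.lower() in {".jsonl", ".ndjson"}:
        rows = [json.loads(line) for line in path.read_text().splitlines() if line.strip()]
        frame = pd.DataFrame(rows)
    else:
        frame = pd.read_csv(path)
    if frame.empty:
        raise NoVisitHistoryError(f"no visit history: event log {path} is empty")
    missing = {"patient_id", "date", "stream", "code"} - set(frame.columns)
    if missing:
        raise ValueError(f"event log {path} lacks columns {sorted(missing)}")
    for col in _EVENT_COLUMNS:
        if col not in frame.columns:
            frame[col] = None
    sample = frame["date"].iloc[0]
    log.info(
        "read %d events from %s (dates detected as %s)",
        len(frame),
        path,
        "integer day index" if str(sample).lstrip("-").isdigit() else "ISO-8601",
    )
    return frame_to_timelines(frame, data_cutoff=data_cutoff)


def write_event_log(events: Iterable[Event], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def observations_to_frame(
    observations: Iterable[IndexedObservation],
    timelines: Mapping[str, PatientTimeline] | None = None,
) -> pd.DataFrame:
    """Tabulate observations as the label CSV schema.

    Anchor and threshold columns are filled when timelines are supplied.
    """
    rows = []
    for obs in observations:
        row = {
            "patient_id": obs.patient_id,
            "index_date": obs.index_date,
            "status": "TD" if obs.is_td else "TC",
            "length_days": obs.length_days,
            "threshold_days": None,
            "anchor_date": obs.index_date + obs.length_days,
        }
        if timelines is not None:
            lab = label_patient(timelines[obs.patient_id])
            row["threshold_days"] = lab.threshold_days
            row["anchor_date"] = lab.anchor_date
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["patient_id", "index_date", "status", "length_days", "threshold_days", "anchor_date"],
    )


def frame_to_observations(frame: pd.DataFrame) -> list[IndexedObservation]:
    return [
        IndexedObservation(
            patient_id=str(r.patient_id),
            index_date=int(r.index_date),
            length_days=int(r.length_days),
            is_td=str(r.status) == "TD",
        )
        for r in frame.itertuples(index=False)
    ]
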