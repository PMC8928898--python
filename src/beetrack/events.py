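"""From movement paths to behavioral records.

The path endpoints define the events: a path that starts at a cavity mouth is
a **leave**, one that ends at a cavity mouth is an **enter**.  The event
stream is then error-corrected (unidentified bees removed; missing events
inside enter-leave-enter sequences invalidate their neighbours) and condensed
into the four behavioral outputs:

* **address book** — which cavity each bee is nesting in, decided by the
  double time rule: the bee stayed inside at least ``min_inside_duration_s``
  (long enough to unload pollen) and did not enter another cavity within
  ``min_outside_duration_s`` of leaving (long enough to be a genuine
  collection trip).  Both default to 40 s.
* **nest recognition** — per homecoming, how many wrong cavities the bee
  entered before finding its own nest.
* **flight list** — durations from leaving the nest cavity to the next
  return to it; probing visits in between belong to the flight.
* **flight activity** — the fraction of the known-alive roster with at least
  one recorded flight.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

from .core import AnalysisConfig, BeeID, CavityID, EventType, Timestamp
from .detector import CavityGrid
from .tracker import Track

__all__ = [
    "RawEvent",
    "CorrectedEvent",
    "NestAssignment",
    "NestRecognitionRecord",
    "FlightRecord",
    "extract_events",
    "correct_events",
    "assign_nests",
    "nest_recognition",
    "flight_list",
    "flight_activity",
]


@dataclasses.dataclass(frozen=True)
class RawEvent:
    """One detected enter/leave of one cavity by one (possibly unknown) bee."""

    timestamp: Timestamp
    bee: BeeID
    cavity: CavityID
    kind: EventType


@dataclasses.dataclass
class CorrectedEvent:
    """A raw event after error correction, with per-output usage flags.

    ``usable`` is False for events flanking a detected missing event; such
    events are excluded from every derived output.  The three ``used_for_*``
    flags record whether the event actually participated in an emitted
    address-book / nest-recognition / flight-list record.
    """

    timestamp: Timestamp
    bee: BeeID
    cavity: CavityID
    kind: EventType
    usable: bool = True
    used_for_address_book: bool = False
    used_for_nest_recognition: bool = False
    used_for_flight_list: bool = False

    def __post_init__(self) -> None:
        if self.bee.is_unknown:
            raise ValueError("corrected events must carry an identified bee")

    @property
    def t(self) -> float:
        return self.timestamp.seconds

    @property
    def used_any(self) -> bool:
        """True iff the event participated in at least one emitted record."""
        return (
            self.used_for_address_book
            or self.used_for_nest_recognition
            or self.used_for_flight_list
        )


@dataclasses.dataclass(frozen=True)
class NestAssignment:
    """A bee linked to a cavity it is nesting in."""

    bee: BeeID
    cavity: CavityID
    established_at: Timestamp


@dataclasses.dataclass(frozen=True)
class NestRecognitionRecord:
    """Wrong cavities entered before the bee found its nest on one return."""

    bee: BeeID
    n_probed: int
    timestamp: Timestamp


@dataclasses.dataclass(frozen=True)
class FlightRecord:
    """One flight: from leaving the nest cavity until returning to it."""

    bee: BeeID
    duration_s: float
    timestamp: Timestamp  # moment of leaving


def _sort_key(ev) -> tuple:
    return (ev.timestamp.seconds, str(ev.bee), ev.kind.value)


def extract_events(
    tracks: Sequence[Track], grid: CavityGrid, cfg: AnalysisConfig
) -> list[RawEvent]:
    """Read enter/leave events off the endpoints of closed movement paths.

    A path whose first detection lies within the cavity association radius of
    a cavity center starts with a leave of that cavity; one whose last
    detection does ends with an enter.  Paths touching no cavity at either
    end contribute nothing.
    """
    radius = cfg.cavity_assoc_radius_px
    if radius is None:
        radius = grid.median_spacing / 2.0
    events: list[RawEvent] = []
    for track in tracks:
        if not track.detections:
            continue
        first, last = track.detections[0], track.detections[-1]
        cav, dist = grid.nearest(first.centroid)
        if dist <= radius:
            events.append(
                RawEvent(
                    Timestamp.from_frame(first.frame_index, cfg.fps),
                    track.resolved_id,
                    cav,
                    EventType.LEAVE,
                )
            )
        cav, dist = grid.nearest(last.centroid)
        if dist <= radius:
            events.append(
                RawEvent(
                    Timestamp.from_frame(last.frame_index, cfg.fps),
                    track.resolved_id,
                    cav,
                    EventType.ENTER,
                )
            )
    events.sort(key=_sort_key)
    return events


def _by_bee(events: Iterable) -> dict[BeeID, list]:
    grouped: dict[BeeID, list] = {}
    for ev in events:
        grouped.setdefault(ev.bee, []).append(ev)
    return grouped


def correct_events(raw: Sequence[RawEvent]) -> list[CorrectedEvent]:
    """Apply the event error correction.

    Events with unidentified bee IDs are removed.  Then, per bee, two
    consecutive events of the same kind imply a missing complementary event
    between them; exactly the two flanking events are marked unusable (runs
    of same-kind events flag every member).  Within any run of consecutive
    usable events the kinds then strictly alternate; an unusable stretch acts
    as a gap that downstream windows refuse to span.
    """
    corrected = [
        CorrectedEvent(ev.timestamp, ev.bee, ev.cavity, ev.kind)
        for ev in raw
        if not ev.bee.is_unknown
    ]
    for bee_events in _by_bee(corrected).values():
        for prev, nxt in zip(bee_events, bee_events[1:]):
            if prev.kind == nxt.kind:
                prev.usable = nxt.usable = False
    corrected.sort(key=_sort_key)
    return corrected


def assign_nests(
    events: Sequence[CorrectedEvent],
    cfg: AnalysisConfig,
    video_end: Timestamp | None = None,
) -> list[NestAssignment]:
    """Derive the address book by the double time rule.

    For each usable enter with a matching next usable leave of the same
    cavity: the pair qualifies iff the stay lasted at least
    ``min_inside_duration_s`` and the bee's next usable enter of a *different*
    cavity came at least ``min_outside_duration_s`` after the leave (or never
    before the video end, with at least that much video remaining — an
    undecidable tail withholds the assignment).  Repeated qualification of an
    existing (bee, cavity) pair is not re-added.
    """
    if video_end is None:
        end_s = max((ev.t for ev in events), default=0.0)
    else:
        end_s = video_end.seconds
    assignments: list[NestAssignment] = []
    seen: set[tuple[BeeID, CavityID]] = set()
    for bee, bee_events in _by_bee(events).items():
        usable = [ev for ev in bee_events if ev.usable]
        for i, enter in enumerate(usable[:-1]):
            if enter.kind is not EventType.ENTER:
                continue
            leave = usable[i + 1]
            if leave.kind is not EventType.LEAVE or leave.cavity != enter.cavity:
                continue
            if any(
                not ev.usable and enter.t < ev.t < leave.t for ev in bee_events
            ):
                continue  # the stay spans a gap with missing events
            if leave.t - enter.t < cfg.min_inside_duration_s:
                continue
            other = next(
                (
                    ev
                    for ev in usable[i + 2 :]
                    if ev.kind is EventType.ENTER and ev.cavity != enter.cavity
                ),
                None,
            )
            if other is not None:
                undisturbed = other.t - leave.t >= cfg.min_outside_duration_s
            else:
                undisturbed = end_s - leave.t >= cfg.min_outside_duration_s
            if not undisturbed:
                continue
            key = (bee, enter.cavity)
            if key in seen:
                continue
            seen.add(key)
            assignments.append(NestAssignment(bee, enter.cavity, enter.timestamp))
            enter.used_for_address_book = True
            leave.used_for_address_book = True
    assignments.sort(key=lambda a: (a.established_at.seconds, str(a.bee)))
    return assignments


def _active_nest(
    assignments: Sequence[NestAssignment], bee: BeeID, t: float
) -> CavityID | None:
    """The bee's nest at time ``t``: latest assignment established by then.

    Assignments are known retrospectively from the whole video, so before the
    first assignment is established the earliest one counts — the bee was
    already nesting there while the evidence accrued.
    """
    own = [a for a in assignments if a.bee == bee]
    if not own:
        return None
    prior = [a for a in own if a.established_at.seconds <= t]
    if prior:
        return max(prior, key=lambda a: a.established_at.seconds).cavity
    return min(own, key=lambda a: a.established_at.seconds).cavity


def nest_recognition(
    events: Sequence[CorrectedEvent], assignments: Sequence[NestAssignment]
) -> list[NestRecognitionRecord]:
    """Count probed wrong cavities per homecoming.

    For each usable enter of a bee's active nest: the window opens at the
    bee's previous usable leave of that nest (or video start) and the count
    is the number of usable enters of other cavities inside it.  Homecomings
    whose window contains any unusable event of the bee are skipped, since an
    undetected event may hide probes.
    """
    records: list[NestRecognitionRecord] = []
    for bee, bee_events in _by_bee(events).items():
        usable = [ev for ev in bee_events if ev.usable]
        for enter in usable:
            if enter.kind is not EventType.ENTER:
                continue
            nest = _active_nest(assignments, bee, enter.t)
            if nest is None or enter.cavity != nest:
                continue
            window_start = max(
                (
                    ev.t
                    for ev in usable
                    if ev.kind is EventType.LEAVE
                    and ev.cavity == nest
                    and ev.t < enter.t
                ),
                default=-1.0,
            )
            if any(
                not ev.usable and window_start < ev.t <= enter.t for ev in bee_events
            ):
                continue
            in_window = [
                ev for ev in usable if window_start <= ev.t <= enter.t
            ]
            probes = [
                ev
                for ev in in_window
                if ev.kind is EventType.ENTER and ev.cavity != nest
            ]
            records.append(NestRecognitionRecord(bee, len(probes), enter.timestamp))
            for ev in in_window:
                ev.used_for_nest_recognition = True
    records.sort(key=lambda r: (r.timestamp.seconds, str(r.bee)))
    return records


def flight_list(
    events: Sequence[CorrectedEvent], assignments: Sequence[NestAssignment]
) -> list[FlightRecord]:
    """Flight durations: usable leave of the active nest to the next usable
    enter of that same nest.  Probing visits in between are part of the
    flight.  Windows containing any unusable event of the bee are skipped.
    """
    records: list[FlightRecord] = []
    for bee, bee_events in _by_bee(events).items():
        usable = [ev for ev in bee_events if ev.usable]
        for leave in usable:
            if leave.kind is not EventType.LEAVE:
                continue
            nest = _active_nest(assignments, bee, leave.t)
            if nest is None or leave.cavity != nest:
                continue
            ret = next(
                (
                    ev
                    for ev in usable
                    if ev.kind is EventType.ENTER
                    and ev.cavity == nest
                    and ev.t > leave.t
                ),
                None,
            )
            if ret is None:
                continue
            if any(
                not ev.usable and leave.t <= ev.t <= ret.t for ev in bee_events
            ):
                continue
            records.append(FlightRecord(bee, ret.t - leave.t, leave.timestamp))
            leave.used_for_flight_list = True
            ret.used_for_flight_list = True
    records.sort(key=lambda r: (r.timestamp.seconds, str(r.bee)))
    return records


def flight_activity(
    flights: Sequence[FlightRecord], roster: set[BeeID]
) -> tuple[set[BeeID], float]:
    """Bees with at least one flight, and their proportion of the alive roster."""
    if not roster:
        raise ValueError("flight activity needs a non-empty roster of alive females")
    active = {f.bee for f in flights} & set(roster)
    return active, len(active) / len(roster)
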