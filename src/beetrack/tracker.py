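"""Centroid tracking: link per-frame detections into movement paths.

The matcher is deliberately a greedy nearest-centroid linker, not an optimal
assignment: candidate (path, detection) pairs are accepted in order of
increasing distance.  Its known failure mode — two bees with crossing paths
exchanging identities — is the documented error class of this style of
tracker, and downstream evaluation expects exactly that behavior rather than
a repaired one.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Iterable, Sequence

from .core import AnalysisConfig, BeeID, UNKNOWN_BEE
from .detector import Detection

__all__ = ["Track", "BuildStats", "update_tracks", "resolve_track_id", "build_paths"]


@dataclasses.dataclass
class Track:
    """A chronological chain of detections of one physical bee."""

    track_id: int
    detections: list[Detection]
    first_frame: int
    last_frame: int
    resolved_id: BeeID = UNKNOWN_BEE
    state: str = "active"  # active | closed

    @property
    def last_centroid(self) -> tuple[float, float]:
        return self.detections[-1].centroid

    def __len__(self) -> int:
        return len(self.detections)


@dataclasses.dataclass
class BuildStats:
    """Accounting for detection conservation across a tracking run."""

    n_detections: int = 0
    n_tracks_closed: int = 0
    n_tracks_discarded: int = 0
    n_detections_discarded: int = 0


def update_tracks(
    active: list[Track],
    frame_dets: Sequence[Detection],
    cfg: AnalysisConfig,
    frame_index: int | None = None,
    id_counter: itertools.count | None = None,
) -> tuple[list[Track], list[Track]]:
    """Advance the tracker by one frame.

    Greedy matching: all (track, detection) pairs are sorted by centroid
    distance and accepted in increasing order while the distance is within
    ``tracker_max_match_dist_px`` and both partners are unclaimed.  Unmatched
    detections open new paths; paths unmatched for more than
    ``tracker_max_missed_frames`` frames are closed.  Returns the updated
    active list and the newly closed paths.
    """
    if frame_index is None:
        if not frame_dets:
            raise ValueError("frame_index is required when the frame has no detections")
        frame_index = frame_dets[0].frame_index
    if id_counter is None:
        start = max((t.track_id for t in active), default=-1) + 1
        id_counter = itertools.count(start)

    pairs = []
    for ti, track in enumerate(active):
        tx, ty = track.last_centroid
        for di, det in enumerate(frame_dets):
            d = math.hypot(det.centroid[0] - tx, det.centroid[1] - ty)
            if d <= cfg.tracker_max_match_dist_px:
                pairs.append((d, ti, di))
    pairs.sort()

    claimed_tracks: set[int] = set()
    claimed_dets: set[int] = set()
    for d, ti, di in pairs:
        if ti in claimed_tracks or di in claimed_dets:
            continue
        claimed_tracks.add(ti)
        claimed_dets.add(di)
        track = active[ti]
        track.detections.append(frame_dets[di])
        track.last_frame = frame_index

    still_active: list[Track] = []
    newly_closed: list[Track] = []
    for ti, track in enumerate(active):
        if ti not in claimed_tracks and (
            frame_index - track.last_frame > cfg.tracker_max_missed_frames
        ):
            track.state = "closed"
            newly_closed.append(track)
        else:
            still_active.append(track)

    for di, det in enumerate(frame_dets):
        if di in claimed_dets:
            continue
        still_active.append(
            Track(
                track_id=next(id_counter),
                detections=[det],
                first_frame=frame_index,
                last_frame=frame_index,
            )
        )
    return still_active, newly_closed


def resolve_track_id(track: Track) -> BeeID:
    """One bee identity per path: confidence-weighted majority over the fully
    readable tag reads; ties broken toward the later-observed read; UNKNOWN
    when nothing was readable."""
    weights: dict[tuple, float] = {}
    last_seen: dict[tuple, int] = {}
    for pos, det in enumerate(track.detections):
        tag = det.tag
        if not tag.fully_readable:
            continue
        key = (tag.color, tag.digit)
        weights[key] = weights.get(key, 0.0) + tag.confidence
        last_seen[key] = pos
    if not weights:
        return UNKNOWN_BEE
    best = max(weights, key=lambda k: (weights[k], last_seen[k]))
    return BeeID(best[0], best[1])


def build_paths(
    all_frames: Iterable[Sequence[Detection]],
    cfg: AnalysisConfig,
    stats: BuildStats | None = None,
) -> list[Track]:
    """Fold :func:`update_tracks` over a whole video.

    Remaining paths are closed at the end, identities resolved, and paths
    shorter than ``min_track_length_frames`` discarded (accounted for in
    ``stats`` when given).  Closed paths are returned in order of first frame.
    """
    active: list[Track] = []
    closed: list[Track] = []
    id_counter = itertools.count(0)
    n_dets = 0
    for frame_index, frame_dets in enumerate(all_frames):
        n_dets += len(frame_dets)
        active, newly_closed = update_tracks(
            active, frame_dets, cfg, frame_index=frame_index, id_counter=id_counter
        )
        closed.extend(newly_closed)
    for track in active:
        track.state = "closed"
        closed.append(track)

    kept: list[Track] = []
    n_discarded = 0
    n_dets_discarded = 0
    for track in closed:
        if len(track) < cfg.min_track_length_frames:
            n_discarded += 1
            n_dets_discarded += len(track)
            continue
        track.resolved_id = resolve_track_id(track)
        kept.append(track)
    kept.sort(key=lambda t: (t.first_frame, t.track_id))

    if stats is not None:
        stats.n_detections = n_dets
        stats.n_tracks_closed = len(closed)
        stats.n_tracks_discarded = n_discarded
        stats.n_detections_discarded = n_dets_discarded
    return kept
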