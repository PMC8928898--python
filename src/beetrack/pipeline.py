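"""End-to-end analysis: detections in, behavioral records out."""

from __future__ import annotations

from typing import Sequence

from .core import AnalysisConfig
from .detector import Detection, index_cavity_grid, stream_detections
from .events import (
    assign_nests,
    correct_events,
    extract_events,
    flight_list,
    nest_recognition,
)
from .io import ResultBundle
from .tracker import BuildStats, build_paths
from .core import Timestamp

__all__ = ["analyze_detections", "analyze_stream"]


def analyze_detections(
    per_frame: Sequence[Sequence[Detection]],
    cavity_centers: Sequence[tuple[float, float]],
    cfg: AnalysisConfig,
    video_name: str = "video",
    stats: BuildStats | None = None,
) -> ResultBundle:
    """Run the full pipeline on per-frame detections.

    Indexes the cavity grid from the raw center positions, links detections
    into movement paths, reads events off path endpoints, error-corrects the
    event stream, and derives the address book, nest recognition, and flight
    list.
    """
    grid = index_cavity_grid(list(cavity_centers))
    tracks = build_paths(per_frame, cfg, stats=stats)
    raw = extract_events(tracks, grid, cfg)
    corrected = correct_events(raw)
    n_frames = len(per_frame)
    video_end = Timestamp.from_frame(max(n_frames - 1, 0), cfg.fps)
    assignments = assign_nests(corrected, cfg, video_end=video_end)
    nr = nest_recognition(corrected, assignments)
    fl = flight_list(corrected, assignments)
    return ResultBundle(
        video_name=video_name,
        raw_events=raw,
        corrected_events=corrected,
        assignments=assignments,
        nest_recognition_records=nr,
        flight_records=fl,
        fps=cfg.fps,
        n_frames=n_frames,
    )


def analyze_stream(
    stream, cfg: AnalysisConfig, video_name: str = "video"
) -> ResultBundle:
    """Analyze a simulator detection stream through the oracle backend."""
    per_frame = stream_detections(stream)
    centers = [(c.x, c.y) for c in stream.cavity_centers]
    return analyze_detections(per_frame, centers, cfg, video_name=video_name)
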