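"""File formats, video handling, visualization, and precision evaluation.

Each analyzed video gets its own subfolder in the result directory holding
the five CSV outputs: ``all_events_unfiltered``, ``error_corrected_events``,
``address_book``, ``nest_recognition``, and ``flight_list``.  All files are
UTF-8, comma-separated, with a header row and ``HH:MM:SS.mmm`` timestamps.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .core import BeeID, CavityID, EventType, Timestamp
from .events import (
    CorrectedEvent,
    FlightRecord,
    NestAssignment,
    NestRecognitionRecord,
    RawEvent,
)

__all__ = [
    "ResultBundle",
    "write_outputs",
    "read_events_csv",
    "read_video",
    "visualize",
    "compute_precision",
    "format_precision",
    "EvalResult",
    "evaluate_against_truth",
]

OUTPUT_FILES = (
    "all_events_unfiltered.csv",
    "error_corrected_events.csv",
    "address_book.csv",
    "nest_recognition.csv",
    "flight_list.csv",
)


@dataclasses.dataclass
class ResultBundle:
    """Everything the analysis produced for one input video."""

    video_name: str
    raw_events: list[RawEvent]
    corrected_events: list[CorrectedEvent]
    assignments: list[NestAssignment]
    nest_recognition_records: list[NestRecognitionRecord]
    flight_records: list[FlightRecord]
    fps: float = 25.0
    n_frames: int = 0


def _yn(flag: bool) -> str:
    return "yes" if flag else "no"


def write_outputs(
    bundle: ResultBundle, result_dir: str | Path, overwrite: bool = False
) -> Path:
    """Write the five CSV outputs into ``result_dir/<video_name>/``.

    Refuses to touch a pre-existing subfolder unless ``overwrite`` is set.
    Returns the subfolder path.
    """
    result_dir = Path(result_dir)
    sub = result_dir / bundle.video_name
    if sub.exists() and not overwrite:
        raise FileExistsError(
            f"result subfolder {sub} already exists (pass overwrite=True to replace)"
        )
    sub.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "timestamp": ev.timestamp.render(),
                "bee_id": str(ev.bee),
                "event_type": ev.kind.value,
                "cavity_id": str(ev.cavity),
            }
            for ev in bundle.raw_events
        ],
        columns=["timestamp", "bee_id", "event_type", "cavity_id"],
    ).to_csv(sub / "all_events_unfiltered.csv", index=False)

    pd.DataFrame(
        [
            {
                "timestamp": ev.timestamp.render(),
                "bee_id": str(ev.bee),
                "cavity_id": str(ev.cavity),
                "event_type": ev.kind.value,
                "used_for_address_book": _yn(ev.used_for_address_book),
                "used_for_nest_recognition": _yn(ev.used_for_nest_recognition),
                "used_for_flight_list": _yn(ev.used_for_flight_list),
            }
            for ev in bundle.corrected_events
        ],
        columns=[
            "timestamp",
            "bee_id",
            "cavity_id",
            "event_type",
            "used_for_address_book",
            "used_for_nest_recognition",
            "used_for_flight_list",
        ],
    ).to_csv(sub / "error_corrected_events.csv", index=False)

    pd.DataFrame(
        [
            {
                "bee_id": str(a.bee),
                "cavity_id": str(a.cavity),
                "established_at": a.established_at.render(),
            }
            for a in bundle.assignments
        ],
        columns=["bee_id", "cavity_id", "established_at"],
    ).to_csv(sub / "address_book.csv", index=False)

    pd.DataFrame(
        [
            {
                "bee_id": str(r.bee),
                "n_probed": r.n_probed,
                "timestamp": r.timestamp.render(),
            }
            for r in bundle.nest_recognition_records
        ],
        columns=["bee_id", "n_probed", "timestamp"],
    ).to_csv(sub / "nest_recognition.csv", index=False)

    pd.DataFrame(
        [
            {
                "bee_id": str(r.bee),
                "flight_duration_s": round(r.duration_s, 3),
                "timestamp": r.timestamp.render(),
            }
            for r in bundle.flight_records
        ],
        columns=["bee_id", "flight_duration_s", "timestamp"],
    ).to_csv(sub / "flight_list.csv", index=False)
    return sub


def _parse_ts(text: str, fps: float) -> Timestamp:
    hh, mm, rest = text.split(":")
    seconds = int(hh) * 3600 + int(mm) * 60 + float(rest)
    return Timestamp(
        seconds=round(seconds * fps) / fps, frame_index=int(round(seconds * fps))
    )


def read_events_csv(path: str | Path, fps: float = 25.0) -> list[RawEvent]:
    """Read an events CSV (unfiltered or corrected) back into RawEvents."""
    df = pd.read_csv(path, dtype=str)
    return [
        RawEvent(
            _parse_ts(row.timestamp, fps),
            BeeID.parse(row.bee_id),
            CavityID.parse(row.cavity_id),
            EventType(row.event_type),
        )
        for row in df.itertuples()
    ]


def read_corrected_csv(path: str | Path, fps: float = 25.0) -> list[CorrectedEvent]:
    df = pd.read_csv(path, dtype=str)
    out = []
    for row in df.itertuples():
        ev = CorrectedEvent(
            _parse_ts(row.timestamp, fps),
            BeeID.parse(row.bee_id),
            CavityID.parse(row.cavity_id),
            EventType(row.event_type),
            used_for_address_book=row.used_for_address_book == "yes",
            used_for_nest_recognition=row.used_for_nest_recognition == "yes",
            used_for_flight_list=row.used_for_flight_list == "yes",
        )
        out.append(ev)
    return out


# ---------------------------------------------------------------------------
# video


def read_video(path: str | Path, fps_fallback: float = 25.0):
    """Read frames and fps from an MP4 file or a directory of PNG frames.

    Non-16:9 input is processed with a warning.  Returns (frames, fps) where
    frames is a list of HxWx3 uint8 arrays.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        frames = [np.asarray(iio.imread(f))[..., :3] for f in files]
        fps = fps_fallback
    else:
        frames = [np.asarray(f)[..., :3] for f in iio.imiter(path)]
        try:
            meta = iio.immeta(path)
            fps = float(meta.get("fps", fps_fallback))
        except Exception:
            fps = fps_fallback
    if frames:
        h, w = frames[0].shape[:2]
        if w * 9 != h * 16:
            warnings.warn(
                f"input is {w}x{h}, not 16:9; processing continues but precision "
                "may be impaired",
                stacklevel=2,
            )
    return frames, fps


def visualize(
    frames: Iterable[np.ndarray],
    tracks,
    events: Sequence[RawEvent],
    out_path: str | Path,
    fps: float = 25.0,
    banner_hold_s: float = 2.0,
) -> int:
    """Overlay analysis results on the frames and write them out.

    Bee boxes carry the resolved ID; a banner announces each event (bee,
    cavity, enter/leave) and is held for ``banner_hold_s``.  ``out_path``
    ending in ``.mp4`` writes a video (requires an ffmpeg-capable imageio
    backend); otherwise it is treated as a directory and PNG frames are
    written.  Returns the number of frames written.
    """
    out_path = Path(out_path)
    hold = max(1, int(round(banner_hold_s * fps)))
    boxes_by_frame: dict[int, list] = {}
    for track in tracks or []:
        for det in track.detections:
            boxes_by_frame.setdefault(det.frame_index, []).append(
                (det.bbox, str(track.resolved_id))
            )

    def _annotated():
        for f_idx, frame in enumerate(frames):
            img = Image.fromarray(np.ascontiguousarray(frame))
            draw = ImageDraw.Draw(img)
            for (x, y, w, h), label in boxes_by_frame.get(f_idx, []):
                draw.rectangle([x, y, x + w, y + h], outline=(255, 0, 0), width=2)
                draw.text((x, max(0.0, y - 12)), label, fill=(255, 0, 0))
            banners = [
                f"{ev.kind.value}: {ev.bee} at {ev.cavity}"
                for ev in events
                if 0 <= f_idx - ev.timestamp.frame_index < hold
            ]
            for i, text in enumerate(banners[:3]):
                draw.text((10, 10 + 14 * i), text, fill=(0, 0, 255))
            yield np.asarray(img)

    n = 0
    if out_path.suffix.lower() == ".mp4":
        try:
            import imageio

            writer = imageio.get_writer(out_path, fps=fps)
        except Exception as exc:  # no ffmpeg backend available
            raise RuntimeError(
                "writing MP4 requires an ffmpeg-capable imageio backend; "
                "pass a directory path to write PNG frames instead"
            ) from exc
        with writer:
            for frame in _annotated():
                writer.append_data(frame)
                n += 1
    else:
        out_path.mkdir(parents=True, exist_ok=True)
        for frame in _annotated():
            iio.imwrite(out_path / f"frame_{n:06d}.png", frame)
            n += 1
    return n


# ---------------------------------------------------------------------------
# precision


def compute_precision(n_checked: int, n_errors: int) -> float:
    """Precision = TP / (TP + FP) over a set of manually checked events."""
    if n_checked <= 0:
        raise ValueError("precision needs at least one checked event")
    if not 0 <= n_errors <= n_checked:
        raise ValueError("n_errors must be between 0 and n_checked")
    return (n_checked - n_errors) / n_checked


def format_precision(precision: float, decimals: int = 1) -> str:
    """Render a precision as a percentage string, e.g. 0.9611 -> '96.1%'."""
    return f"{round(precision * 100.0, decimals):.{decimals}f}%"


@dataclasses.dataclass
class EvalResult:
    """Event-level comparison of produced events against ground truth.

    Precision (TP / (TP + FP)) is the primary figure; recall is reported for
    completeness but is secondary — the pipeline trades recall for precision,
    and missing events only shrink sample sizes without biasing the
    measurements themselves.
    """

    tp: int
    fp: int
    fn: int
    false_positives: list[RawEvent]
    false_negatives: list[RawEvent]

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 1.0


def evaluate_against_truth(
    produced: Sequence[RawEvent], truth, time_tol_s: float = 1.0
) -> EvalResult:
    """Greedy chronological matching of produced events to true events.

    A produced event matches an unclaimed true event iff bee ID, cavity ID,
    and event type are all identical and the timestamps differ by at most
    ``time_tol_s``.  Unmatched produced events are false positives, unmatched
    true events false negatives.
    """
    truth_events = list(truth.events) if hasattr(truth, "events") else list(truth)
    by_key: dict[tuple, list[RawEvent]] = {}
    for ev in truth_events:
        by_key.setdefault((ev.bee, ev.cavity, ev.kind), []).append(ev)
    for lst in by_key.values():
        lst.sort(key=lambda e: e.timestamp.seconds)
    claimed: set[int] = set()
    tp = 0
    fps_list: list[RawEvent] = []
    for ev in sorted(produced, key=lambda e: e.timestamp.seconds):
        candidates = by_key.get((ev.bee, ev.cavity, ev.kind), [])
        match = next(
            (
                c
                for c in candidates
                if id(c) not in claimed
                and abs(c.timestamp.seconds - ev.timestamp.seconds) <= time_tol_s
            ),
            None,
        )
        if match is None:
            fps_list.append(ev)
        else:
            claimed.add(id(match))
            tp += 1
    fns = [ev for ev in truth_events if id(ev) not in claimed]
    return EvalResult(tp=tp, fp=len(fps_list), fn=len(fns), false_positives=fps_list, false_negatives=fns)
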