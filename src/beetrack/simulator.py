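"""Synthetic nesting-unit scenes with ground truth.

The simulator emulates a frontally filmed nesting unit: a board with a grid
of cavities (up to 12 rows x 10 columns) and up to 24 individually tagged
females.  Each bee alternates long stays inside its nest cavity with flights
off screen; on each return it probes a geometrically distributed number of
wrong cavities (brief enter + leave) before entering its own nest.  Outside
bees move along piecewise-linear waypoint paths with a small perpendicular
wobble; a bee is invisible while inside a cavity or off screen.

The output is a :class:`GroundTruth` (authoritative event log, trajectories,
nest map, drawn probe counts) and a :class:`DetectionStream` (per-frame
observations of outside bees after injectable noise: detection misses,
withheld tag reads, green-read-as-yellow confusion, centroid jitter).  With
all noise at zero the stream equals the true trajectories exactly.

By default flights are scheduled so that at most one bee is in visible
transit at a time (``avoid_crossings``), which guarantees crossing-free
paths for ground-truth recovery experiments; a scripted two-bee crossing
scene is provided separately for studying the tracker's ID-swap failure.
"""

from __future__ import annotations

import dataclasses
import heapq
import math
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    COLORS,
    DIGITS,
    BeeID,
    CavityID,
    Color,
    EventType,
    Timestamp,
)
from .events import RawEvent
from .glyphs import glyph_image

__all__ = [
    "NoiseModel",
    "SimScenario",
    "GroundTruth",
    "DetectionStream",
    "StreamRecord",
    "CavityCenter",
    "simulate_session",
    "scripted_crossing_session",
    "render_frames",
    "write_ground_truth",
    "read_ground_truth",
    "write_detections",
    "read_detections",
    "write_cavity_centers",
    "read_cavity_centers",
]

# scene geometry (pixels at the native 1920x1080 scene scale)
CAVITY_SPACING_PX = 80.0
CAVITY_RADIUS_PX = 18.0
TAG_RADIUS_PX = 12.0
BODY_HALF_AXES_PX = (22.0, 13.0)
OFFSCREEN_MARGIN_PX = 60.0
WOBBLE_AMP_PX = 3.0
WOBBLE_FREQ_HZ = 2.0
AIRSPACE_COOLDOWN_S = 1.0

BOARD_RGB = (205, 200, 190)
CAVITY_RGB = (30, 25, 20)
BODY_RGB = (60, 45, 35)
TAG_RGB = {
    Color.WHITE: (250, 250, 250),
    Color.YELLOW: (235, 205, 40),
    Color.GREEN: (45, 165, 60),
}


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Detection-level noise injected into the stream (never into the truth)."""

    miss_rate: float = 0.0
    green_yellow_confusion_rate: float = 0.0
    tag_unreadable_rate: float = 0.0
    centroid_jitter_px: float = 0.0

    def __post_init__(self) -> None:
        for name in ("miss_rate", "green_yellow_confusion_rate", "tag_unreadable_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.centroid_jitter_px < 0:
            raise ValueError("centroid_jitter_px must be >= 0")


@dataclasses.dataclass
class SimScenario:
    """Parameters of one synthetic session.

    Durations are drawn per event: flight and inside-stay durations are
    lognormal (seconds), the number of wrong cavities probed per return is
    geometric on {0, 1, 2, ...}, and probe stays are uniform and must remain
    strictly below ``min_inside_duration_s`` so a probe can never qualify as
    nesting.  ``nest_map`` may be given explicitly; otherwise bees are placed
    on distinct cavities drawn from the seeded generator.
    """

    n_bees: int = 24
    grid_rows: int = 12
    grid_cols: int = 10
    duration_s: float = 1800.0
    fps: float = 25.0
    nest_map: dict[BeeID, CavityID] | None = None
    flight_duration_lognorm: tuple[float, float] = (math.log(240.0), 0.4)
    inside_duration_lognorm: tuple[float, float] = (math.log(300.0), 0.4)
    initial_inside_range_s: tuple[float, float] = (30.0, 300.0)
    n_probes_p: float = 0.5
    probe_duration_range_s: tuple[float, float] = (2.0, 8.0)
    min_inside_duration_s: float = 40.0
    noise: NoiseModel = dataclasses.field(default_factory=NoiseModel)
    rng_seed: int = 0
    avoid_crossings: bool = True
    frame_size: tuple[int, int] = (1920, 1080)
    bee_speed_px_s: float = 400.0

    def __post_init__(self) -> None:
        max_ids = len(COLORS) * len(DIGITS)
        if not 1 <= self.n_bees <= max_ids:
            raise ValueError(f"n_bees must be in [1, {max_ids}]")
        if not 1 <= self.grid_rows <= 12 or not 1 <= self.grid_cols <= 10:
            raise ValueError("grid must be at most 12 rows x 10 columns")
        if self.n_bees > self.grid_rows * self.grid_cols:
            raise ValueError("more bees than cavities")
        if self.probe_duration_range_s[1] >= self.min_inside_duration_s:
            raise ValueError(
                "probe durations must stay strictly below min_inside_duration_s, "
                "otherwise a probe could qualify as nesting"
            )
        if not 0.0 < self.n_probes_p <= 1.0:
            raise ValueError("n_probes_p must be in (0, 1]")
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration_s and fps must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def roster(self) -> list[BeeID]:
        return [BeeID(c, d) for c in COLORS for d in DIGITS][: self.n_bees]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "SimScenario":
        data = dict(mapping)
        if "noise" in data and isinstance(data["noise"], Mapping):
            data["noise"] = NoiseModel(**data["noise"])
        if "nest_map" in data and isinstance(data["nest_map"], Mapping):
            data["nest_map"] = {
                BeeID.parse(k): CavityID.parse(v) for k, v in data["nest_map"].items()
            }
        for key in (
            "flight_duration_lognorm",
            "inside_duration_lognorm",
            "initial_inside_range_s",
            "probe_duration_range_s",
            "frame_size",
        ):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimScenario":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})


@dataclasses.dataclass(frozen=True)
class CavityCenter:
    x: float
    y: float
    cavity: CavityID


@dataclasses.dataclass(frozen=True)
class StreamRecord:
    """One noisy observation of an outside bee in one frame."""

    frame: int
    x: float
    y: float
    color: str
    digit: int
    readable: bool


@dataclasses.dataclass
class _Segment:
    kind: str  # "inside" | "transit"
    f0: int
    f1: int  # inclusive
    cavity: CavityID | None = None
    waypoints: list[tuple[float, float]] | None = None
    phase: float = 0.0  # wobble phase


@dataclasses.dataclass
class GroundTruth:
    """The simulator's authoritative record of what actually happened."""

    events: list[RawEvent]
    nest_map: dict[BeeID, CavityID]
    probe_counts: dict[BeeID, list[int]]
    segments: dict[BeeID, list[_Segment]]
    cavity_centers: list[CavityCenter]
    fps: float
    n_frames: int
    frame_size: tuple[int, int]

    def position(self, bee: BeeID, frame: int):
        """``("inside", CavityID)``, ``(x, y)``, or ``None`` (off screen)."""
        for seg in self.segments.get(bee, []):
            if seg.f0 <= frame <= seg.f1:
                if seg.kind == "inside":
                    return ("inside", seg.cavity)
                return _interp_segment(seg, frame, self.fps)
        return None


@dataclasses.dataclass
class DetectionStream:
    """Per-frame noisy observations plus the true cavity centers."""

    frames: list[list[StreamRecord]]
    cavity_centers: list[CavityCenter]
    fps: float
    frame_size: tuple[int, int]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_records(self) -> int:
        return sum(len(f) for f in self.frames)


def cavity_layout(
    grid_rows: int, grid_cols: int, frame_size: tuple[int, int]
) -> list[CavityCenter]:
    """Centers of the cavity grid, centered on the frame."""
    w, h = frame_size
    x0 = w / 2.0 - (grid_cols - 1) * CAVITY_SPACING_PX / 2.0
    y0 = h / 2.0 - (grid_rows - 1) * CAVITY_SPACING_PX / 2.0
    if x0 < CAVITY_RADIUS_PX or y0 < CAVITY_RADIUS_PX:
        raise ValueError("cavity grid does not fit the frame")
    return [
        CavityCenter(
            x0 + (c - 1) * CAVITY_SPACING_PX,
            y0 + (r - 1) * CAVITY_SPACING_PX,
            CavityID(r, c),
        )
        for r in range(1, grid_rows + 1)
        for c in range(1, grid_cols + 1)
    ]


def _interp_segment(seg: _Segment, frame: int, fps: float) -> tuple[float, float]:
    pts = seg.waypoints
    n = seg.f1 - seg.f0
    frac = 0.0 if n == 0 else (frame - seg.f0) / n
    lengths = [
        math.hypot(b[0] - a[0], b[1] - a[1]) for a, b in zip(pts, pts[1:])
    ]
    total = sum(lengths)
    if total == 0:
        return pts[0]
    target = frac * total
    acc = 0.0
    for (a, b), L in zip(zip(pts, pts[1:]), lengths):
        if target <= acc + L or (a, b) == (pts[-2], pts[-1]):
            u = 0.0 if L == 0 else (target - acc) / L
            x = a[0] + u * (b[0] - a[0])
            y = a[1] + u * (b[1] - a[1])
            if L > 0:
                px, py = -(b[1] - a[1]) / L, (b[0] - a[0]) / L
                wob = (
                    WOBBLE_AMP_PX
                    * math.sin(2 * math.pi * WOBBLE_FREQ_HZ * frame / fps + seg.phase)
                    * math.sin(math.pi * frac)
                )
                x, y = x + px * wob, y + py * wob
            return (x, y)
        acc += L
    return pts[-1]


def _transit_frames(pts: Sequence[tuple[float, float]], speed: float, fps: float) -> int:
    total = sum(math.hypot(b[0] - a[0], b[1] - a[1]) for a, b in zip(pts, pts[1:]))
    return max(3, int(round(total / speed * fps)))


def simulate_session(scenario: SimScenario) -> tuple[GroundTruth, DetectionStream]:
    """Run one synthetic session; identical scenarios reproduce identically."""
    ss = np.random.SeedSequence(scenario.rng_seed)
    rng_behavior, rng_noise = (np.random.default_rng(c) for c in ss.spawn(2))

    fps = scenario.fps
    n_frames = scenario.n_frames
    centers = cavity_layout(scenario.grid_rows, scenario.grid_cols, scenario.frame_size)
    center_of = {c.cavity: (c.x, c.y) for c in centers}
    roster = scenario.roster

    if scenario.nest_map is None:
        cavities = [c.cavity for c in centers]
        picks = rng_behavior.choice(len(cavities), size=len(roster), replace=False)
        nest_map = {bee: cavities[int(i)] for bee, i in zip(roster, picks)}
    else:
        nest_map = dict(scenario.nest_map)
        if set(nest_map) != set(roster):
            raise ValueError("nest_map must cover exactly the scenario roster")
        if len(set(nest_map.values())) != len(roster):
            raise ValueError("bees must nest in distinct cavities")

    w, h = scenario.frame_size
    speed = scenario.bee_speed_px_s
    cooldown = int(round(AIRSPACE_COOLDOWN_S * fps))
    mlog_f, slog_f = scenario.flight_duration_lognorm
    mlog_i, slog_i = scenario.inside_duration_lognorm

    events: list[tuple[int, BeeID, CavityID, EventType]] = []
    segments: dict[BeeID, list[_Segment]] = {bee: [] for bee in roster}
    probe_counts: dict[BeeID, list[int]] = {bee: [] for bee in roster}
    last_enter_frame: dict[BeeID, int] = {bee: -1 for bee in roster}
    phases = {bee: 2 * math.pi * i / len(roster) for i, bee in enumerate(roster)}

    airspace_free = 0
    heap: list[tuple[int, int, int, str, object]] = []
    seq = 0
    for i, bee in enumerate(roster):
        first_leave = int(round(rng_behavior.uniform(*scenario.initial_inside_range_s) * fps))
        heapq.heappush(heap, (first_leave, seq, i, "leave", None))
        seq += 1

    def add_event(frame: int, bee: BeeID, cavity: CavityID, kind: EventType) -> bool:
        if frame >= n_frames:
            return False
        events.append((frame, bee, cavity, kind))
        return True

    while heap:
        desired, _, bee_i, action, payload = heapq.heappop(heap)
        bee = roster[bee_i]
        nest = nest_map[bee]
        nx, ny = center_of[nest]

        if action == "leave":
            exit_pts = [(nx, ny), (nx, h + OFFSCREEN_MARGIN_PX)]
            n_out = _transit_frames(exit_pts, speed, fps)
            start = max(desired, airspace_free) if scenario.avoid_crossings else desired
            if start >= n_frames:
                segments[bee].append(
                    _Segment("inside", last_enter_frame[bee] + 1, n_frames - 1, cavity=nest)
                )
                continue
            segments[bee].append(
                _Segment("inside", last_enter_frame[bee] + 1, start - 1, cavity=nest)
            )
            add_event(start, bee, nest, EventType.LEAVE)
            segments[bee].append(
                _Segment("transit", start, start + n_out, waypoints=exit_pts, phase=phases[bee])
            )
            if scenario.avoid_crossings:
                airspace_free = max(airspace_free, start + n_out + cooldown)

            # plan the return: k wrong cavities probed, then the nest
            flight_s = float(rng_behavior.lognormal(mlog_f, slog_f))
            k = int(rng_behavior.geometric(scenario.n_probes_p)) - 1
            other = [c.cavity for c in centers if c.cavity != nest]
            probe_idx = rng_behavior.choice(len(other), size=k, replace=False) if k else []
            targets = [other[int(j)] for j in probe_idx] + [nest]
            probe_frames = [
                max(1, int(round(rng_behavior.uniform(*scenario.probe_duration_range_s) * fps)))
                for _ in range(k)
            ]
            legs = []
            entry_x = center_of[targets[0]][0]
            prev = (entry_x, h + OFFSCREEN_MARGIN_PX)
            n_ret = 0
            for j, target in enumerate(targets):
                pts = [prev, center_of[target]]
                n_t = _transit_frames(pts, speed, fps)
                legs.append((pts, n_t, probe_frames[j] if j < k else None, target))
                n_ret += n_t + (probe_frames[j] if j < k else 0)
                prev = center_of[target]
            flight_frames = max(
                int(round(flight_s * fps)), n_out + n_ret + 2 * cooldown
            )
            heapq.heappush(
                heap, (start + flight_frames - n_ret, seq, bee_i, "return", (legs, k))
            )
            seq += 1

        else:  # return
            legs, k = payload
            rstart = max(desired, airspace_free) if scenario.avoid_crossings else desired
            cursor = rstart
            completed = True
            for pts, n_t, probe_f, target in legs:
                arrive = cursor + n_t
                if arrive >= n_frames:
                    completed = False
                if cursor <= n_frames - 1:
                    segments[bee].append(
                        _Segment("transit", cursor, arrive, waypoints=list(pts), phase=phases[bee])
                    )
                if not completed:
                    break
                add_event(arrive, bee, target, EventType.ENTER)
                if probe_f is None:  # the nest: stay inside until the next leave
                    last_enter_frame[bee] = arrive
                    probe_counts[bee].append(k)
                    inside_s = float(rng_behavior.lognormal(mlog_i, slog_i))
                    next_leave = arrive + int(round(inside_s * fps))
                    if scenario.avoid_crossings:
                        airspace_free = max(airspace_free, arrive + cooldown)
                    heapq.heappush(heap, (next_leave, seq, bee_i, "leave", None))
                    seq += 1
                else:
                    depart = arrive + probe_f
                    if depart >= n_frames:
                        segments[bee].append(
                            _Segment("inside", arrive + 1, n_frames - 1, cavity=target)
                        )
                        completed = False
                        break
                    segments[bee].append(
                        _Segment("inside", arrive + 1, depart - 1, cavity=target)
                    )
                    add_event(depart, bee, target, EventType.LEAVE)
                    cursor = depart

    events.sort(key=lambda e: (e[0], str(e[1]), e[3].value))
    truth_events = [
        RawEvent(Timestamp.from_frame(f, fps), bee, cav, kind)
        for f, bee, cav, kind in events
    ]
    truth = GroundTruth(
        events=truth_events,
        nest_map=nest_map,
        probe_counts=probe_counts,
        segments=segments,
        cavity_centers=centers,
        fps=fps,
        n_frames=n_frames,
        frame_size=scenario.frame_size,
    )
    stream = _emit_stream(truth, roster, scenario.noise, rng_noise)
    return truth, stream


def _emit_stream(
    truth: GroundTruth,
    roster: Sequence[BeeID],
    noise: NoiseModel,
    rng: np.random.Generator,
) -> DetectionStream:
    """Observe the true trajectories through the noise model.

    The random draws per visible (bee, frame) slot are consumed in a fixed
    order regardless of the noise rates, so streams generated from the same
    seed at different rates are coupled (e.g. raising miss_rate can only
    remove detections).
    """
    w, h = truth.frame_size
    frames: list[list[StreamRecord]] = [[] for _ in range(truth.n_frames)]
    for bee in roster:
        for seg in truth.segments[bee]:
            if seg.kind != "transit":
                continue
            for f in range(seg.f0, min(seg.f1, truth.n_frames - 1) + 1):
                x, y = _interp_segment(seg, f, truth.fps)
                u_miss = rng.random()
                u_unreadable = rng.random()
                u_confuse = rng.random()
                jx, jy = rng.normal(size=2)
                if not (0 <= x < w and 0 <= y < h):
                    continue
                if u_miss < noise.miss_rate:
                    continue
                color = bee.color
                if (
                    color is Color.GREEN
                    and u_confuse < noise.green_yellow_confusion_rate
                ):
                    color = Color.YELLOW
                frames[f].append(
                    StreamRecord(
                        frame=f,
                        x=x + jx * noise.centroid_jitter_px,
                        y=y + jy * noise.centroid_jitter_px,
                        color=color.value,
                        digit=bee.digit,
                        readable=u_unreadable >= noise.tag_unreadable_rate,
                    )
                )
    return DetectionStream(
        frames=frames,
        cavity_centers=list(truth.cavity_centers),
        fps=truth.fps,
        frame_size=truth.frame_size,
    )


def scripted_crossing_session(
    seed: int = 0,
    fps: float = 25.0,
    duration_s: float = 120.0,
    noise: NoiseModel | None = None,
) -> tuple[GroundTruth, DetectionStream]:
    """A deterministic two-bee scene whose paths cross at a shallow angle.

    Both bees fly in from the left edge at the same time and enter their
    nests in column 9; their straight paths share the same x at every frame
    and cross vertically late in the approach.  This is the canonical input
    for studying the greedy tracker's ID-swap failure mode.
    """
    frame_size = (1920, 1080)
    centers = cavity_layout(12, 10, frame_size)
    center_of = {c.cavity: (c.x, c.y) for c in centers}
    bee_a, bee_b = BeeID(Color.GREEN, 1), BeeID(Color.GREEN, 2)
    nest_a, nest_b = CavityID(10, 9), CavityID(8, 9)
    start_f = int(round(2.0 * fps))
    n_transit = 91
    n_frames = int(round(duration_s * fps))

    path_a = [(-80.0, 200.0), center_of[nest_a]]
    path_b = [(-80.0, 900.0), center_of[nest_b]]
    enter_f = start_f + n_transit

    segments = {
        bee_a: [
            _Segment("transit", start_f, enter_f, waypoints=path_a),
            _Segment("inside", enter_f + 1, n_frames - 1, cavity=nest_a),
        ],
        bee_b: [
            _Segment("transit", start_f, enter_f, waypoints=path_b),
            _Segment("inside", enter_f + 1, n_frames - 1, cavity=nest_b),
        ],
    }
    events = [
        RawEvent(Timestamp.from_frame(enter_f, fps), bee_a, nest_a, EventType.ENTER),
        RawEvent(Timestamp.from_frame(enter_f, fps), bee_b, nest_b, EventType.ENTER),
    ]
    truth = GroundTruth(
        events=events,
        nest_map={bee_a: nest_a, bee_b: nest_b},
        probe_counts={bee_a: [], bee_b: []},
        segments=segments,
        cavity_centers=centers,
        fps=fps,
        n_frames=n_frames,
        frame_size=frame_size,
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    stream = _emit_stream(truth, [bee_a, bee_b], noise or NoiseModel(), rng)
    return truth, stream


# ---------------------------------------------------------------------------
# rendering


def render_frames(
    truth: GroundTruth,
    stream: DetectionStream | None = None,
    size: tuple[int, int] = (1920, 1080),
    frame_range: tuple[int, int] | None = None,
) -> Iterator[np.ndarray]:
    """Render the scene: cavity grid as dark circles on a light board, each
    outside bee as a dark body ellipse bearing its colored tag disc with the
    digit glyph.  Deterministic given the truth.  ``size`` must be 16:9.
    """
    w, h = size
    if w * 9 != h * 16:
        raise ValueError(f"frame size must have a 16:9 aspect ratio, got {w}x{h}")
    scale = w / truth.frame_size[0]
    f0, f1 = frame_range if frame_range is not None else (0, truth.n_frames)

    base = np.empty((h, w, 3), dtype=np.uint8)
    base[..., :] = BOARD_RGB
    for c in truth.cavity_centers:
        _fill_disc(base, c.x * scale, c.y * scale, CAVITY_RADIUS_PX * scale, CAVITY_RGB)

    bees = list(truth.segments)
    for f in range(f0, f1):
        frame = base.copy()
        for bee in bees:
            pos = truth.position(bee, f)
            if pos is None or pos[0] == "inside":
                continue
            x, y = pos[0] * scale, pos[1] * scale
            _fill_ellipse(
                frame, x, y, BODY_HALF_AXES_PX[0] * scale, BODY_HALF_AXES_PX[1] * scale, BODY_RGB
            )
            _fill_disc(frame, x, y, TAG_RADIUS_PX * scale, TAG_RGB[bee.color])
            _stamp_glyph(frame, x, y, bee.digit, scale)
        yield frame


def _fill_disc(img: np.ndarray, cx: float, cy: float, r: float, rgb) -> None:
    h, w = img.shape[:2]
    x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
    y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    img[y0:y1, x0:x1][mask] = rgb


def _fill_ellipse(img: np.ndarray, cx: float, cy: float, a: float, b: float, rgb) -> None:
    h, w = img.shape[:2]
    x0, x1 = max(0, int(cx - a) - 1), min(w, int(cx + a) + 2)
    y0, y1 = max(0, int(cy - b) - 1), min(h, int(cy + b) + 2)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    img[y0:y1, x0:x1][mask] = rgb


def _stamp_glyph(img: np.ndarray, cx: float, cy: float, digit: int, scale: float) -> None:
    g = glyph_image(digit, scale=max(1, int(round(2 * scale))))
    gh, gw = g.shape
    y0, x0 = int(round(cy - gh / 2)), int(round(cx - gw / 2))
    h, w = img.shape[:2]
    if y0 < 0 or x0 < 0 or y0 + gh > h or x0 + gw > w:
        return
    region = img[y0 : y0 + gh, x0 : x0 + gw]
    region[g] = (0, 0, 0)


# ---------------------------------------------------------------------------
# CSV round-trips (plain-text interchange for every stream artifact)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Events CSV: timestamp, bee_id, cavity_id, event_type."""
    df = pd.DataFrame(
        [
            {
                "timestamp": ev.timestamp.render(),
                "bee_id": str(ev.bee),
                "cavity_id": str(ev.cavity),
                "event_type": ev.kind.value,
            }
            for ev in truth.events
        ],
        columns=["timestamp", "bee_id", "cavity_id", "event_type"],
    )
    df.to_csv(path, index=False)


def _parse_timestamp(text: str, fps: float) -> Timestamp:
    hh, mm, rest = text.split(":")
    seconds = int(hh) * 3600 + int(mm) * 60 + float(rest)
    return Timestamp(seconds=round(seconds * fps) / fps, frame_index=int(round(seconds * fps)))


def read_ground_truth(path: str | Path, fps: float) -> list[RawEvent]:
    df = pd.read_csv(path, dtype=str)
    return [
        RawEvent(
            _parse_timestamp(row.timestamp, fps),
            BeeID.parse(row.bee_id),
            CavityID.parse(row.cavity_id),
            EventType(row.event_type),
        )
        for row in df.itertuples()
    ]


def write_detections(stream: DetectionStream, path: str | Path) -> None:
    """Oracle-backend interchange: frame, x, y, color, digit, readable."""
    rows = [
        {
            "frame": rec.frame,
            "x": rec.x,
            "y": rec.y,
            "color": rec.color,
            "digit": rec.digit,
            "readable": int(rec.readable),
        }
        for frame in stream.frames
        for rec in frame
    ]
    df = pd.DataFrame(rows, columns=["frame", "x", "y", "color", "digit", "readable"])
    df.to_csv(path, index=False)


def read_detections(
    path: str | Path,
    fps: float = 25.0,
    frame_size: tuple[int, int] = (1920, 1080),
    n_frames: int | None = None,
) -> DetectionStream:
    df = pd.read_csv(path)
    last = int(df["frame"].max()) if len(df) else -1
    n = n_frames if n_frames is not None else last + 1
    frames: list[list[StreamRecord]] = [[] for _ in range(n)]
    for row in df.itertuples():
        frames[int(row.frame)].append(
            StreamRecord(
                frame=int(row.frame),
                x=float(row.x),
                y=float(row.y),
                color=str(row.color),
                digit=int(row.digit),
                readable=bool(int(row.readable)),
            )
        )
    return DetectionStream(frames=frames, cavity_centers=[], fps=fps, frame_size=frame_size)


def write_cavity_centers(centers: Sequence[CavityCenter], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"x": c.x, "y": c.y, "cavity_id": str(c.cavity)} for c in centers],
        columns=["x", "y", "cavity_id"],
    )
    df.to_csv(path, index=False)


def read_cavity_centers(path: str | Path) -> list[CavityCenter]:
    df = pd.read_csv(path)
    return [
        CavityCenter(float(row.x), float(row.y), CavityID.parse(row.cavity_id))
        for row in df.itertuples()
    ]
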