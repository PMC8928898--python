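"""Shared domain types: bee and cavity identifiers, timestamps, event kinds,
and the analysis configuration.

Identity conventions
--------------------
Bees carry a thorax tag that is a colored disc bearing a digit.  The shipped
tag alphabet is 3 colors (white, yellow, green) x 8 digits (1-8), i.e. 24
distinct individuals per scene.  Nesting cavities are indexed by their row and
column position on the nesting-unit face, row 1 at the top of the image and
column 1 at the left, up to 12 rows x 10 columns (120 cavities).

Timestamps are carried as (frame_index, seconds) pairs anchored to the first
video frame and render as ``HH:MM:SS.mmm`` in every CSV output.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "Color",
    "BeeID",
    "UNKNOWN_BEE",
    "CavityID",
    "Timestamp",
    "EventType",
    "AnalysisConfig",
    "make_bee_id",
    "make_cavity_id",
    "id_space_sizes",
    "COLORS",
    "DIGITS",
    "MAX_GRID_ROWS",
    "MAX_GRID_COLS",
]

MAX_GRID_ROWS = 12
MAX_GRID_COLS = 10
DIGITS = tuple(range(1, 9))

UNKNOWN_SENTINEL = "unknown"


class Color(str, enum.Enum):
    """Tag disc colors recognized by the shipped tag alphabet."""

    WHITE = "white"
    YELLOW = "yellow"
    GREEN = "green"


COLORS = (Color.WHITE, Color.YELLOW, Color.GREEN)


@dataclasses.dataclass(frozen=True, order=True)
class BeeID:
    """A bee identity: (tag color, tag digit), or the UNKNOWN sentinel.

    The UNKNOWN value (both fields ``None``) stands for a bee whose tag could
    not be resolved; it renders as ``"unknown"``.
    """

    color: Color | None
    digit: int | None

    def __post_init__(self) -> None:
        if (self.color is None) != (self.digit is None):
            raise ValueError("BeeID requires both color and digit, or neither")
        if self.color is not None:
            if not isinstance(self.color, Color):
                object.__setattr__(self, "color", Color(self.color))
            if self.digit not in DIGITS:
                raise ValueError(f"tag digit must be in [1, 8], got {self.digit!r}")

    @property
    def is_unknown(self) -> bool:
        return self.color is None

    def __str__(self) -> str:
        if self.is_unknown:
            return UNKNOWN_SENTINEL
        return f"{self.color.value}-{self.digit}"

    @classmethod
    def parse(cls, text: str) -> "BeeID":
        text = text.strip()
        if text == UNKNOWN_SENTINEL:
            return UNKNOWN_BEE
        try:
            color, digit = text.rsplit("-", 1)
            return cls(Color(color), int(digit))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"unparseable bee ID {text!r}") from exc


UNKNOWN_BEE = BeeID(None, None)


def make_bee_id(color: str | Color, digit: int | str) -> BeeID:
    """Build a validated :class:`BeeID`.

    Passing the sentinel string ``"unknown"`` for either component yields
    UNKNOWN.  Colors outside {white, yellow, green} and digits outside [1, 8]
    are rejected.
    """
    if color == UNKNOWN_SENTINEL or digit == UNKNOWN_SENTINEL:
        return UNKNOWN_BEE
    try:
        color = Color(color)
    except ValueError:
        raise ValueError(
            f"unrecognized tag color {color!r}; valid colors: "
            + ", ".join(c.value for c in COLORS)
        ) from None
    return BeeID(color, int(digit))


@dataclasses.dataclass(frozen=True, order=True)
class CavityID:
    """A nesting-cavity position: row (1 = topmost) and column (1 = leftmost)."""

    row: int
    column: int

    def __post_init__(self) -> None:
        if not 1 <= self.row <= MAX_GRID_ROWS:
            raise ValueError(f"cavity row must be in [1, {MAX_GRID_ROWS}], got {self.row}")
        if not 1 <= self.column <= MAX_GRID_COLS:
            raise ValueError(
                f"cavity column must be in [1, {MAX_GRID_COLS}], got {self.column}"
            )

    def __str__(self) -> str:
        return f"R{self.row}C{self.column}"

    @classmethod
    def parse(cls, text: str) -> "CavityID":
        text = text.strip()
        if not text.startswith("R") or "C" not in text:
            raise ValueError(f"unparseable cavity ID {text!r}")
        row_part, col_part = text[1:].split("C", 1)
        return cls(int(row_part), int(col_part))


def make_cavity_id(row: int, column: int) -> CavityID:
    """Build a validated :class:`CavityID` (row in [1,12], column in [1,10])."""
    return CavityID(int(row), int(column))


def id_space_sizes(
    colors: Iterable[Color] | None = None,
    digits: Iterable[int] | None = None,
    grid_rows: int = MAX_GRID_ROWS,
    grid_cols: int = MAX_GRID_COLS,
) -> tuple[int, int]:
    """Number of representable (non-UNKNOWN) bee IDs and cavity IDs.

    With the shipped defaults this is (24, 120): 3 colors x 8 digits and a
    12 x 10 cavity grid.
    """
    n_colors = len(set(colors)) if colors is not None else len(COLORS)
    n_digits = len(set(digits)) if digits is not None else len(DIGITS)
    return n_colors * n_digits, grid_rows * grid_cols


@dataclasses.dataclass(frozen=True, order=True)
class Timestamp:
    """A point in video time: seconds since the first frame, plus the frame index."""

    seconds: float
    frame_index: int

    @classmethod
    def from_frame(cls, frame_index: int, fps: float) -> "Timestamp":
        return cls(seconds=frame_index / fps, frame_index=int(frame_index))

    def render(self) -> str:
        """CSV rendering ``HH:MM:SS.mmm`` (zero-padded, millisecond precision)."""
        total_ms = round(self.seconds * 1000.0)
        ms = total_ms % 1000
        total_s = total_ms // 1000
        h, rem = divmod(total_s, 3600)
        m, s = divmod(rem, 60)
        return f"{h:02d}:{m:02d}:{s:02d}.{ms:03d}"

    def __str__(self) -> str:
        return self.render()


class EventType(str, enum.Enum):
    """A bee either enters or leaves a cavity; these are the only event kinds."""

    ENTER = "enter"
    LEAVE = "leave"


_POSITIVE_FIELDS = (
    "min_inside_duration_s",
    "min_outside_duration_s",
    "fps",
    "tracker_max_match_dist_px",
)


@dataclasses.dataclass
class AnalysisConfig:
    """Tunable thresholds of the analysis pipeline.

    min_inside_duration_s
        Minimum stay inside a cavity for a nest assignment: the time a nesting
        female minimally needs to unload pollen for provisioning (default 40 s).
    min_outside_duration_s
        Minimum span after leaving during which the bee must not enter another
        cavity: the time minimally needed to collect pollen or mud (default 40 s).
    fps
        Video frame rate; timestamps are frame_index / fps.
    tracker_max_match_dist_px
        Maximum centroid displacement (pixels) for linking a detection to an
        existing movement path.
    tracker_max_missed_frames
        Frames a path survives without a detection before it is closed.
    cavity_assoc_radius_px
        Radius for snapping a path endpoint to a cavity center; ``None`` means
        half the median cavity-center spacing of the indexed grid.
    min_track_length_frames
        Paths with fewer detections are discarded as noise.
    """

    min_inside_duration_s: float = 40.0
    min_outside_duration_s: float = 40.0
    fps: float = 25.0
    tracker_max_match_dist_px: float = 80.0
    tracker_max_missed_frames: int = 15
    cavity_assoc_radius_px: float | None = None
    min_track_length_frames: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in _POSITIVE_FIELDS:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.cavity_assoc_radius_px is not None and self.cavity_assoc_radius_px <= 0:
            raise ValueError("cavity_assoc_radius_px must be strictly positive")
        if self.tracker_max_missed_frames < 0:
            raise ValueError("tracker_max_missed_frames must be non-negative")
        if self.min_track_length_frames < 1:
            raise ValueError("min_track_length_frames must be >= 1")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in mapping.items():
            if key not in known:
                warnings.warn(f"ignoring unknown config key {key!r}", stacklevel=2)
                continue
            kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a flat key: value (YAML-compatible) config file.

        Unknown keys produce a warning and are ignored, so configs written for
        extended setups remain loadable.
        """
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ValueError(f"config file {path} must contain a flat mapping")
        return cls.from_mapping(data)
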