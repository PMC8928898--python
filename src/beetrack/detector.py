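"""Per-frame bee detection, tag classification, and cavity-grid indexing.

Two interchangeable backends produce :class:`Detection` objects:

* the **classical** backend (:func:`detect_cavities`, :func:`detect_bees`,
  :func:`classify_tag`) works on rendered frames using thresholding, blob
  labelling, hue ranges, and template correlation;
* the **oracle** backend (:func:`stream_detections`) converts a simulator
  detection stream verbatim, bypassing imaging.

Both emit the same record shape (bee box, tag color, digit, confidence), so a
learned detector could be slotted in behind the same interface.

Image coordinates: origin top-left, x rightward, y downward; positions are
real-valued, frame indices integer.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.color import rgb2hsv
from skimage.transform import resize

from .core import MAX_GRID_COLS, MAX_GRID_ROWS, CavityID, Color
from .glyphs import DIGIT_TEMPLATE_SHAPE, digit_templates

__all__ = [
    "TagRead",
    "Detection",
    "CavityGrid",
    "detect_cavities",
    "index_cavity_grid",
    "detect_bees",
    "classify_tag",
    "stream_detections",
]

# Hue is on [0, 1): yellow tags sit near 0.12, green near 0.36.  The boundary
# between them is the reproducible confusion axis of the tag alphabet.
_YELLOW_GREEN_HUE_BOUNDARY = 0.22
_GREEN_HUE_MAX = 0.50
_MIN_SATURATION = 0.35
_WHITE_MIN_VALUE = 0.92
_WHITE_MAX_SATURATION = 0.15
_GLYPH_MAX_VALUE = 0.35
_DIGIT_SCORE_THRESHOLD = 0.45


@dataclasses.dataclass(frozen=True)
class TagRead:
    """One attempted read of a bee's tag: color, digit, and a confidence.

    Either component may be unreadable (``None``).  Confidence is 0 exactly
    when both are unreadable.
    """

    color: Color | None
    digit: int | None
    confidence: float

    def __post_init__(self) -> None:
        both_unreadable = self.color is None and self.digit is None
        if both_unreadable and self.confidence != 0.0:
            raise ValueError("fully unreadable tag must have confidence 0")
        if not both_unreadable and self.confidence <= 0.0:
            raise ValueError("partially readable tag must have confidence > 0")

    @property
    def fully_readable(self) -> bool:
        return self.color is not None and self.digit is not None


UNREADABLE_TAG = TagRead(None, None, 0.0)


@dataclasses.dataclass(frozen=True)
class Detection:
    """One localized bee observation in one frame."""

    frame_index: int
    centroid: tuple[float, float]
    bbox: tuple[float, float, float, float]  # (x, y, w, h)
    tag: TagRead

    def __post_init__(self) -> None:
        x, y, w, h = self.bbox
        cx, cy = self.centroid
        if not (x <= cx <= x + w and y <= cy <= y + h):
            raise ValueError("detection centroid must lie inside its bbox")


@dataclasses.dataclass
class CavityGrid:
    """Cavity centers indexed by row (top to bottom) and column (left to right)."""

    centers: list[tuple[tuple[float, float], CavityID]]
    row_boundaries: np.ndarray
    column_boundaries: np.ndarray

    @property
    def median_spacing(self) -> float:
        """Median spacing between adjacent row/column band centers, px."""
        xs = sorted({c.column for _, c in self.centers})
        ys = sorted({c.row for _, c in self.centers})
        col_x: dict[int, list[float]] = {}
        row_y: dict[int, list[float]] = {}
        for (x, y), cid in self.centers:
            col_x.setdefault(cid.column, []).append(x)
            row_y.setdefault(cid.row, []).append(y)
        spacings: list[float] = []
        col_means = [float(np.mean(col_x[c])) for c in xs]
        row_means = [float(np.mean(row_y[r])) for r in ys]
        spacings.extend(np.diff(col_means))
        spacings.extend(np.diff(row_means))
        if not spacings:
            return 80.0  # single cavity: fall back to a nominal spacing
        return float(np.median(spacings))

    def nearest(self, point: tuple[float, float]) -> tuple[CavityID, float]:
        """Nearest cavity center to ``point`` and its distance in px."""
        pts = np.array([c for c, _ in self.centers], dtype=float)
        d = np.hypot(pts[:, 0] - point[0], pts[:, 1] - point[1])
        i = int(np.argmin(d))
        return self.centers[i][1], float(d[i])


def _gap_cluster(coords: np.ndarray, min_split_px: float = 10.0) -> np.ndarray:
    """1-D clustering by splitting at large gaps in the sorted coordinates.

    The split threshold is half the estimated band spacing (median of the
    gaps larger than the mean gap), floored at ``min_split_px`` so that
    sub-pixel jitter never fragments a single band.
    Returns integer labels (0-based, ordered by coordinate) per input point.
    """
    coords = np.asarray(coords, dtype=float)
    order = np.argsort(coords, kind="stable")
    labels = np.zeros(len(coords), dtype=int)
    if len(coords) <= 1:
        return labels
    sorted_c = coords[order]
    gaps = np.diff(sorted_c)
    big = gaps[gaps >= gaps.mean()] if gaps.mean() > 0 else np.array([])
    if big.size:
        threshold = max(float(np.median(big)) / 2.0, min_split_px)
    else:
        threshold = np.inf
    cluster_of_sorted = np.concatenate([[0], np.cumsum(gaps > threshold)])
    labels[order] = cluster_of_sorted
    return labels


def index_cavity_grid(centers: Sequence[tuple[float, float]]) -> CavityGrid:
    """Assign row/column IDs to cavity centers of a frontally filmed unit.

    Rows come from 1-D gap clustering of the y coordinates and columns from
    the x coordinates; row 1 is topmost, column 1 leftmost.  Rejects center
    sets that cluster into more than 12 rows or 10 columns.  The result is
    invariant to the order of the input centers.
    """
    if not centers:
        raise ValueError("cannot index an empty cavity set")
    pts = np.asarray(centers, dtype=float)
    row_labels = _gap_cluster(pts[:, 1])
    col_labels = _gap_cluster(pts[:, 0])
    n_rows = int(row_labels.max()) + 1
    n_cols = int(col_labels.max()) + 1
    if n_rows > MAX_GRID_ROWS:
        raise ValueError(f"clustering yields {n_rows} rows (> {MAX_GRID_ROWS})")
    if n_cols > MAX_GRID_COLS:
        raise ValueError(f"clustering yields {n_cols} columns (> {MAX_GRID_COLS})")

    indexed = [
        ((float(x), float(y)), CavityID(int(r) + 1, int(c) + 1))
        for (x, y), r, c in zip(pts, row_labels, col_labels)
    ]
    indexed.sort(key=lambda item: (item[1].row, item[1].column))

    def _boundaries(labels: np.ndarray, coords: np.ndarray) -> np.ndarray:
        means = [coords[labels == k].mean() for k in range(labels.max() + 1)]
        means = np.sort(np.asarray(means))
        return (means[:-1] + means[1:]) / 2.0

    return CavityGrid(
        centers=indexed,
        row_boundaries=_boundaries(row_labels, pts[:, 1]),
        column_boundaries=_boundaries(col_labels, pts[:, 0]),
    )


def detect_cavities(
    frame: np.ndarray,
    dark_threshold: float = 90.0,
    min_area_px: int = 40,
    max_eccentricity: float = 0.85,
) -> list[tuple[float, float]]:
    """Centers of the dark circular cavity openings in a frame.

    Dark pixels are labelled into blobs; elongated blobs (e.g. bee bodies)
    are rejected by eccentricity.  Intended for a bee-free reference frame of
    the nesting-unit face; an empty frame yields an empty list.
    """
    gray = np.asarray(frame, dtype=float).mean(axis=2)
    mask = gray < dark_threshold
    labelled = measure.label(mask)
    centers: list[tuple[float, float]] = []
    for region in measure.regionprops(labelled):
        if region.area < min_area_px:
            continue
        if region.eccentricity > max_eccentricity:
            continue
        cy, cx = region.centroid
        centers.append((float(cx), float(cy)))
    return centers


def classify_tag(patch: np.ndarray) -> TagRead:
    """Read (color, digit) from an image patch centered on a candidate tag disc.

    Color is decided from the dominant hue of saturated pixels (white by low
    saturation at high brightness); hues beyond the green range are
    unreadable.  The digit is the best normalized correlation between the
    dark glyph pixels and the eight digit templates; a best score below
    threshold is unreadable.
    """
    patch = np.asarray(patch)
    if patch.size == 0:
        return UNREADABLE_TAG
    hsv = rgb2hsv(patch)
    hue, sat, val = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    saturated = (sat > _MIN_SATURATION) & (val > 0.3)
    whiteish = (val > _WHITE_MIN_VALUE) & (sat < _WHITE_MAX_SATURATION)

    color: Color | None = None
    if saturated.sum() >= 10 and saturated.sum() >= whiteish.sum():
        h = float(np.median(hue[saturated]))
        if h < _YELLOW_GREEN_HUE_BOUNDARY:
            color = Color.YELLOW
        elif h < _GREEN_HUE_MAX:
            color = Color.GREEN
    elif whiteish.sum() >= 10:
        color = Color.WHITE

    digit: int | None = None
    best_score = 0.0
    # the glyph is the dark hole inside the disc; filling the disc mask and
    # subtracting it isolates glyph pixels from dark body pixels at the margin
    disc = saturated | whiteish
    glyph = np.zeros_like(disc)
    if disc.any():
        interior = ndimage.binary_fill_holes(disc)
        glyph = interior & (val < _GLYPH_MAX_VALUE)
    if glyph.any():
        ys, xs = np.nonzero(glyph)
        crop = glyph[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1].astype(float)
        if crop.shape[0] >= 4 and crop.shape[1] >= 2:
            vec = resize(crop, DIGIT_TEMPLATE_SHAPE, anti_aliasing=True).ravel()
            vec = vec - vec.mean()
            norm = np.linalg.norm(vec)
            if norm > 0:
                vec /= norm
                for d, tmpl in digit_templates().items():
                    score = float(vec @ tmpl)
                    if score > best_score:
                        best_score, digit = score, d
                if best_score < _DIGIT_SCORE_THRESHOLD:
                    digit = None

    if color is None and digit is None:
        return UNREADABLE_TAG
    confidence = 0.5 * (color is not None) + 0.5 * max(best_score, 0.0) * (
        digit is not None
    )
    return TagRead(color, digit, float(np.clip(confidence, 1e-3, 1.0)))


def detect_bees(
    frame: np.ndarray,
    frame_index: int = 0,
    min_area_px: int = 30,
    body_margin_px: float = 14.0,
) -> list[Detection]:
    """Detect tag-bearing bees in a rendered frame (tags unread are allowed).

    Candidate tag discs are saturated colored blobs or very bright white
    blobs; each yields one detection whose centroid is the disc centroid and
    whose bbox inflates the disc box by a body margin.  Tags are then read
    with :func:`classify_tag`.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        return []
    hsv = rgb2hsv(frame)
    sat, val = hsv[..., 1], hsv[..., 2]
    disc_mask = ((sat > _MIN_SATURATION) & (val > 0.3)) | (
        (val > _WHITE_MIN_VALUE) & (sat < _WHITE_MAX_SATURATION)
    )
    labelled = measure.label(disc_mask)
    h, w = frame.shape[:2]
    detections: list[Detection] = []
    for region in measure.regionprops(labelled):
        if region.area < min_area_px:
            continue
        cy, cx = region.centroid
        r0, c0, r1, c1 = region.bbox
        pr0 = max(0, int(r0 - body_margin_px))
        pc0 = max(0, int(c0 - body_margin_px))
        pr1 = min(h, int(r1 + body_margin_px))
        pc1 = min(w, int(c1 + body_margin_px))
        # classify on a tight patch around the disc only, to avoid picking up
        # glyphs or discs of a nearby bee
        tag = classify_tag(frame[max(0, r0 - 2) : r1 + 2, max(0, c0 - 2) : c1 + 2])
        detections.append(
            Detection(
                frame_index=frame_index,
                centroid=(float(cx), float(cy)),
                bbox=(float(pc0), float(pr0), float(pc1 - pc0), float(pr1 - pr0)),
                tag=tag,
            )
        )
    detections.sort(key=lambda d: d.centroid)
    return detections


def stream_detections(stream) -> list[list[Detection]]:
    """Oracle backend: convert a simulator detection stream verbatim.

    ``stream`` must expose ``frames`` (per-frame lists of records with
    ``frame, x, y, color, digit, readable`` fields).  Tag confidence is 1 for
    readable records, 0 otherwise.
    """
    out: list[list[Detection]] = []
    for frame_index, records in enumerate(stream.frames):
        dets: list[Detection] = []
        for rec in records:
            if rec.frame != frame_index:
                raise ValueError(
                    f"stream record at slot {frame_index} carries frame {rec.frame}"
                )
            if rec.readable:
                tag = TagRead(Color(rec.color), int(rec.digit), 1.0)
            else:
                tag = UNREADABLE_TAG
            half = 20.0
            dets.append(
                Detection(
                    frame_index=frame_index,
                    centroid=(float(rec.x), float(rec.y)),
                    bbox=(float(rec.x) - half, float(rec.y) - half, 2 * half, 2 * half),
                    tag=tag,
                )
            )
        out.append(dets)
    return out
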