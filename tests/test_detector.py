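import math

import numpy as np
import pytest
from skimage.color import hsv2rgb, rgb2hsv

from beetrack.core import CavityID, Color
from beetrack.detector import (
    TagRead,
    classify_tag,
    detect_bees,
    detect_cavities,
    index_cavity_grid,
    stream_detections,
)
from beetrack.simulator import SimScenario, render_frames, simulate_session


def _lattice(rows, cols, spacing=80.0, origin=(100.0, 100.0)):
    return [
        (origin[0] + c * spacing, origin[1] + r * spacing)
        for r in range(rows)
        for c in range(cols)
    ]


class TestGridIndexing:
    def test_perfect_lattice_raster_order(self):
        grid = index_cavity_grid(_lattice(2, 3))
        assert [str(c) for _, c in grid.centers] == [
            "R1C1", "R1C2", "R1C3", "R2C1", "R2C2", "R2C3",
        ]

    def test_jitter_invariance_against_nearest_lattice_oracle(self):
        rng = np.random.default_rng(0)
        clean = _lattice(5, 7)
        jittered = [(x + rng.uniform(-1, 1), y + rng.uniform(-1, 1)) for x, y in clean]
        grid = index_cavity_grid(jittered)
        # oracle: snap each jittered point to the nearest clean lattice point
        for (x, y), cid in grid.centers:
            dists = [math.hypot(x - cx, y - cy) for cx, cy in clean]
            r, c = divmod(int(np.argmin(dists)), 7)
            assert cid == CavityID(r + 1, c + 1)

    def test_permutation_invariance(self):
        pts = _lattice(3, 4)
        rng = np.random.default_rng(1)
        shuffled = [pts[i] for i in rng.permutation(len(pts))]
        a = index_cavity_grid(pts)
        b = index_cavity_grid(shuffled)
        assert sorted(((p, c) for p, c in a.centers), key=str) == sorted(
            ((p, c) for p, c in b.centers), key=str
        )

    def test_too_many_rows_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            index_cavity_grid(_lattice(13, 2))
        with pytest.raises(ValueError, match="columns"):
            index_cavity_grid(_lattice(2, 11))

    def test_single_row_is_not_fragmented_by_jitter(self):
        rng = np.random.default_rng(2)
        pts = [(100.0 + 80 * c, 100.0 + rng.uniform(-1.5, 1.5)) for c in range(10)]
        grid = index_cavity_grid(pts)
        assert {c.row for _, c in grid.centers} == {1}
        assert {c.column for _, c in grid.centers} == set(range(1, 11))


class TestCavityDetection:
    @pytest.mark.parametrize("rows,cols", [(3, 4), (12, 10)])
    def test_counts_on_rendered_grid(self, rows, cols):
        sc = SimScenario(n_bees=1, grid_rows=rows, grid_cols=cols, duration_s=60.0,
                         initial_inside_range_s=(50.0, 55.0), rng_seed=0)
        truth, stream = simulate_session(sc)
        frame = next(render_frames(truth, stream, (1920, 1080), frame_range=(0, 1)))
        centers = detect_cavities(frame)
        assert len(centers) == rows * cols
        grid = index_cavity_grid(centers)
        assert max(c.row for _, c in grid.centers) == rows
        assert max(c.column for _, c in grid.centers) == cols

    def test_blank_frame_yields_nothing(self):
        blank = np.full((270, 480, 3), 255, dtype=np.uint8)
        assert detect_cavities(blank) == []


class TestTagClassification:
    def _patch(self, color, digit, seed=0):
        """A rendered bee patch, cut from a synthetic scene frame."""
        from beetrack.core import BeeID
        from beetrack.simulator import _Segment, GroundTruth, cavity_layout
        from beetrack.events import RawEvent

        bee = BeeID(color, digit)
        truth = GroundTruth(
            events=[], nest_map={bee: CavityID(1, 1)}, probe_counts={bee: []},
            segments={bee: [_Segment("transit", 0, 10,
                                     waypoints=[(900.0, 540.0), (1000.0, 540.0)])]},
            cavity_centers=cavity_layout(2, 2, (1920, 1080)),
            fps=25.0, n_frames=1, frame_size=(1920, 1080),
        )
        frame = next(render_frames(truth, None, (1920, 1080), frame_range=(0, 1)))
        return frame[540 - 16 : 540 + 16, 900 - 16 : 900 + 16]

    @pytest.mark.parametrize("color", [Color.WHITE, Color.YELLOW, Color.GREEN])
    @pytest.mark.parametrize("digit", [1, 5, 8])
    def test_rendered_tags_read_back(self, color, digit):
        tag = classify_tag(self._patch(color, digit))
        assert tag.color is color
        assert tag.digit == digit
        assert tag.confidence > 0.5

    def test_uniform_gray_is_unreadable(self):
        tag = classify_tag(np.full((32, 32, 3), 128, dtype=np.uint8))
        assert tag.color is None and tag.digit is None and tag.confidence == 0.0

    def test_green_shifted_toward_yellow_reads_yellow(self):
        """The documented color failure: green and yellow spectra converge."""
        patch = self._patch(Color.GREEN, 5)
        hsv = rgb2hsv(patch)
        green = hsv[..., 1] > 0.35
        hsv[..., 0][green] = 0.18  # past the yellow/green decision boundary
        shifted = (hsv2rgb(hsv) * 255).astype(np.uint8)
        tag = classify_tag(shifted)
        assert tag.color is Color.YELLOW

    def test_confidence_zero_iff_fully_unreadable(self):
        with pytest.raises(ValueError):
            TagRead(None, None, 0.5)
        with pytest.raises(ValueError):
            TagRead(Color.GREEN, 5, 0.0)


class TestOracleBackend:
    def test_noise_free_stream_converts_verbatim(self, small_session):
        _, truth, stream = small_session
        per_frame = stream_detections(stream)
        assert len(per_frame) == truth.n_frames
        for records, dets in zip(stream.frames, per_frame):
            assert len(records) == len(dets)
            for rec, det in zip(records, dets):
                assert det.centroid == (rec.x, rec.y)
                assert det.tag.fully_readable

    def test_unreadable_rate_one_blanks_all_tags(self):
        from beetrack.simulator import NoiseModel

        sc = SimScenario(n_bees=2, duration_s=300.0, rng_seed=4,
                         initial_inside_range_s=(5.0, 30.0),
                         noise=NoiseModel(tag_unreadable_rate=1.0))
        _, stream = simulate_session(sc)
        dets = [d for frame in stream_detections(stream) for d in frame]
        assert dets and all(d.tag.confidence == 0.0 for d in dets)


def test_backends_agree_on_noise_free_rendered_frames(small_session):
    """Classical imaging backend vs oracle backend on the same frames."""
    _, truth, stream = small_session
    oracle = stream_detections(stream)
    w, h = truth.frame_size
    margin = 40
    checked = 0
    for f in range(truth.n_frames):
        recs = stream.frames[f]
        if not recs or checked >= 6:
            continue
        # only frames where every bee is fully in view
        if not all(margin < r.x < w - margin and margin < r.y < h - margin for r in recs):
            continue
        frame = next(render_frames(truth, stream, (w, h), frame_range=(f, f + 1)))
        classical = sorted(detect_bees(frame, frame_index=f), key=lambda d: d.centroid)
        expected = sorted(oracle[f], key=lambda d: d.centroid)
        assert len(classical) == len(expected)
        for c, o in zip(classical, expected):
            assert math.hypot(c.centroid[0] - o.centroid[0], c.centroid[1] - o.centroid[1]) < 2.0
            assert c.tag.color is o.tag.color
            assert c.tag.digit == o.tag.digit
        checked += 1
    assert checked == 6
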