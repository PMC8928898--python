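import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from beetrack.core import (
    AnalysisConfig,
    BeeID,
    CavityID,
    Color,
    EventType,
    Timestamp,
    UNKNOWN_BEE,
)
from beetrack.detector import index_cavity_grid
from beetrack.events import (
    RawEvent,
    assign_nests,
    correct_events,
    flight_activity,
    flight_list,
    nest_recognition,
)

GREEN5 = BeeID(Color.GREEN, 5)
WHITE2 = BeeID(Color.WHITE, 2)
NEST = CavityID(3, 4)
OTHER = CavityID(1, 2)


def ev(t, kind, bee=GREEN5, cavity=NEST):
    return RawEvent(Timestamp(float(t), int(t * 25)), bee, cavity, kind)


E, L = EventType.ENTER, EventType.LEAVE


def ts(t):
    return Timestamp(float(t), int(t * 25))


class TestExtractEvents:
    def _grid(self):
        return index_cavity_grid(
            [(100.0 + 80 * c, 100.0 + 80 * r) for r in range(4) for c in range(4)]
        )

    def _track(self, start_xy, end_xy, first=100, n=10, resolved=GREEN5):
        from beetrack.detector import Detection, UNREADABLE_TAG
        from beetrack.tracker import Track

        dets = []
        for i in range(n):
            u = i / (n - 1)
            x = start_xy[0] + u * (end_xy[0] - start_xy[0])
            y = start_xy[1] + u * (end_xy[1] - start_xy[1])
            dets.append(Detection(first + i, (x, y), (x - 5, y - 5, 10, 10), UNREADABLE_TAG))
        t = Track(0, dets, first, first + n - 1, state="closed")
        t.resolved_id = resolved
        return t

    def test_endpoints_near_cavities_become_events(self, cfg):
        from beetrack.events import extract_events

        grid = self._grid()
        # starts 5 px from R1C1, ends 5 px from R3C4
        track = self._track((105.0, 100.0), (345.0, 260.0))
        events = extract_events([track], grid, cfg)
        assert [(e.kind, str(e.cavity)) for e in events] == [
            (EventType.LEAVE, "R1C1"),
            (EventType.ENTER, "R3C4"),
        ]
        assert events[0].timestamp.frame_index == 100
        assert events[1].timestamp.frame_index == 109

    def test_midair_endpoints_yield_nothing(self, cfg):
        from beetrack.events import extract_events

        grid = self._grid()
        track = self._track((500.0, 500.0), (700.0, 700.0))
        assert extract_events([track], grid, cfg) == []


class TestCorrectEvents:
    def test_perfect_alternation_all_usable(self):
        out = correct_events([ev(0, E), ev(50, L), ev(100, E), ev(150, L)])
        assert all(e.usable for e in out)

    def test_missing_leave_flags_both_flanking_enters(self):
        out = correct_events([ev(0, E, cavity=CavityID(1, 1)), ev(50, E, cavity=CavityID(2, 2))])
        assert [e.usable for e in out] == [False, False]

    def test_unknown_bee_events_removed(self):
        raw = [ev(i * 10, E if i % 2 == 0 else L) for i in range(10)]
        raw[2] = dataclasses.replace(raw[2], bee=UNKNOWN_BEE)
        raw[5] = dataclasses.replace(raw[5], bee=UNKNOWN_BEE)
        raw[7] = dataclasses.replace(raw[7], bee=UNKNOWN_BEE)
        out = correct_events(raw)
        assert len(out) == 7

    def test_gap_flags_exactly_the_flanking_pair(self):
        # enter, leave, leave, enter: only the inner same-kind pair is flagged;
        # the outer events stay usable but are separated by the gap
        out = correct_events([ev(0, E), ev(10, L), ev(20, L), ev(30, E)])
        assert [e.usable for e in out] == [True, False, False, True]

    def test_same_kind_run_flags_every_member(self):
        out = correct_events([ev(0, E), ev(10, E), ev(20, E)])
        assert [e.usable for e in out] == [False] * 3

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.sampled_from([E, L]), max_size=12))
    def test_usable_runs_always_alternate(self, kinds):
        """Within every unbroken run of usable events, kinds alternate."""
        raw = [ev(10.0 * i, k) for i, k in enumerate(kinds)]
        out = correct_events(raw)
        for prev, nxt in zip(out, out[1:]):
            if prev.usable and nxt.usable:
                assert prev.kind != nxt.kind


class TestAssignNests:
    def _corrected(self, seq):
        return correct_events([ev(t, k, cavity=c) for t, k, c in seq])

    def test_double_rule_met(self, cfg):
        events = self._corrected(
            [(0, E, NEST), (45, L, NEST), (95, E, OTHER), (100, L, OTHER)]
        )
        out = assign_nests(events, cfg, video_end=ts(1000))
        assert [(a.bee, a.cavity) for a in out] == [(GREEN5, NEST)]

    def test_exact_40s_stay_and_aftertime_assigned(self, cfg):
        events = self._corrected([(10, E, NEST), (50, L, NEST)])
        out = assign_nests(events, cfg, video_end=ts(90))
        assert len(out) == 1

    def test_one_frame_short_stay_rejected(self, cfg):
        events = self._corrected([(10, E, NEST), (49.96, L, NEST)])
        assert assign_nests(events, cfg, video_end=ts(1000)) == []

    def test_short_aftertime_at_video_end_withheld(self, cfg):
        events = self._corrected([(10, E, NEST), (50, L, NEST)])
        assert assign_nests(events, cfg, video_end=ts(89.9)) == []

    def test_other_cavity_reentry_vetoes(self, cfg):
        events = self._corrected(
            [(0, E, NEST), (60, L, NEST), (70, E, OTHER), (75, L, OTHER)]
        )
        assert assign_nests(events, cfg, video_end=ts(1000)) == []

    def test_own_cavity_reentry_does_not_veto(self, cfg):
        events = self._corrected(
            [(0, E, NEST), (60, L, NEST), (70, E, NEST), (130, L, NEST)]
        )
        out = assign_nests(events, cfg, video_end=ts(1000))
        assert [(a.bee, a.cavity) for a in out] == [(GREEN5, NEST)]
        assert len(out) == 1  # duplicate qualification not re-added

    def test_raising_inside_threshold_never_adds_assignments(self, cfg):
        events = [
            (0, E, NEST), (45, L, NEST), (120, E, NEST), (200, L, NEST),
            (300, E, OTHER), (304, L, OTHER), (400, E, NEST), (475, L, NEST),
        ]
        counts = []
        for thr in (30.0, 40.0, 50.0, 80.0, 200.0):
            cfg2 = AnalysisConfig(min_inside_duration_s=thr)
            counts.append(len(assign_nests(self._corrected(events), cfg2, video_end=ts(1000))))
        assert counts == sorted(counts, reverse=True)


class TestDerivedOutputs:
    def _session(self):
        """leave nest, probe OTHER, re-enter nest (qualifying stay), leave,
        direct return."""
        seq = [
            (0, E, NEST), (100, L, NEST),          # qualifying stay: assigned
            (200, E, OTHER), (205, L, OTHER),      # probe on the way home
            (210, E, NEST), (300, L, NEST),        # second stay + flight
            (500, E, NEST),
        ]
        events = correct_events([ev(t, k, cavity=c) for t, k, c in seq])
        assignments = assign_nests(events, AnalysisConfig(), video_end=ts(1000))
        return events, assignments

    def test_nest_recognition_counts_wrong_cavities(self):
        events, assignments = self._session()
        records = nest_recognition(events, assignments)
        assert [(r.n_probed, r.timestamp.seconds) for r in records] == [
            (0, 0.0),   # initial entry, window from video start
            (1, 210.0), # probed OTHER once
            (0, 500.0), # direct return
        ]

    def test_flight_list_durations_and_probe_inclusion(self):
        events, assignments = self._session()
        records = flight_list(events, assignments)
        assert [(r.duration_s, r.timestamp.seconds) for r in records] == [
            (110.0, 100.0),  # probe is inside the flight, not a split
            (200.0, 300.0),
        ]

    def test_flight_before_video_end_without_return_unrecorded(self):
        seq = [(0, E, NEST), (100, L, NEST)]
        events = correct_events([ev(t, k, cavity=c) for t, k, c in seq])
        assignments = assign_nests(events, AnalysisConfig(), video_end=ts(1000))
        assert flight_list(events, assignments) == []

    def test_unusable_window_suppresses_records(self):
        # drop the probe's leave: enter OTHER / enter NEST become unusable
        seq = [
            (0, E, NEST), (100, L, NEST),
            (200, E, OTHER),                 # missing leave here
            (210, E, NEST), (300, L, NEST), (500, E, NEST),
        ]
        events = correct_events([ev(t, k, cavity=c) for t, k, c in seq])
        assert [e.usable for e in events] == [True, True, False, False, True, True]
        assignments = assign_nests(events, AnalysisConfig(), video_end=ts(1000))
        records = nest_recognition(events, assignments)
        # the 210 homecoming vanished with the gap; the 500 one has a clean
        # window starting at the usable leave at 300
        assert [(r.n_probed, r.timestamp.seconds) for r in records] == [
            (0, 0.0),
            (0, 500.0),
        ]
        flights = flight_list(events, assignments)
        # the 100 -> 210 flight window spans the gap and is suppressed; the
        # 300 -> 500 flight is clean
        assert [(r.duration_s, r.timestamp.seconds) for r in flights] == [(200.0, 300.0)]

    def test_flight_activity_proportion(self):
        from beetrack.events import FlightRecord

        flights = [FlightRecord(GREEN5, 100.0, ts(0)), FlightRecord(WHITE2, 50.0, ts(1))]
        roster = {GREEN5, WHITE2, BeeID(Color.YELLOW, 1), BeeID(Color.WHITE, 4)}
        active, prop = flight_activity(flights, roster)
        assert active == {GREEN5, WHITE2}
        assert prop == 0.5

    def test_flight_activity_empty_roster_rejected(self):
        with pytest.raises(ValueError):
            flight_activity([], set())

    def test_no_flights_means_nobody_active(self):
        active, prop = flight_activity([], {GREEN5})
        assert active == set() and prop == 0.0
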