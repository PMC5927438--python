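import math

import pytest

from tsi import (
    AreaScheme,
    BrushingEvent,
    BrushingSession,
    EmptySessionError,
    SessionSummary,
    SessionValidationError,
    UndefinedIndexError,
    c_value,
    i_value,
    restrict_to_surfaces,
    summarize_session,
    tsi,
)
from tsi.schemes import ORAL, VESTIBULAR

from conftest import make_session

A = (1, VESTIBULAR)
B = (1, ORAL)


def summary(b, x, i, d=None):
    return SessionSummary(b=b, x=x, i=i, d=d or {})


class TestSummarize:
    def test_alternating_three_events(self, scheme_all):
        s = summarize_session(make_session([A, B, A]), scheme_all)
        assert (s.b, s.x, s.i) == (2, 30.0, 2)
        assert s.d == {A: 20.0, B: 10.0}

    def test_single_event(self, scheme_all):
        s = summarize_session(make_session([A], duration=60.0), scheme_all)
        assert (s.b, s.x, s.i) == (0, 60.0, 1)

    def test_complete_session(self, complete_session, scheme_all):
        s = summarize_session(complete_session, scheme_all)
        assert (s.b, s.i) == (15, 16)
        assert s.x == pytest.approx(210.0)

    def test_pause_without_area_change_is_not_a_change(self, scheme_all):
        s = summarize_session(make_session([A, A], gap=5.0), scheme_all)
        assert s.b == 0
        assert s.x == 20.0

    def test_empty_session_rejected(self, scheme_all):
        with pytest.raises(EmptySessionError):
            summarize_session(BrushingSession([]), scheme_all)

    def test_area_outside_scheme_names_event(self, scheme_all):
        session = make_session([A, (2, "incisal")])
        with pytest.raises(SessionValidationError, match="event 1"):
            summarize_session(session, scheme_all)


class TestCValue:
    @pytest.mark.parametrize(
        "b, x, i, expected",
        [
            (15, 210, 16, 0.928571),   # complete isochronal reference
            (15, 480, 16, 0.96875),    # longest duration, fewest changes
            (79, 30, 16, 0.0),         # b > x: raw negative, clamped
            (0, 60, 1, 0.0625),        # single area
        ],
    )
    def test_examples(self, scheme_all, b, x, i, expected):
        assert c_value(summary(b, x, i), scheme_all) == pytest.approx(
            expected, abs=1e-6
        )

    def test_zero_duration_rejected(self, scheme_all):
        with pytest.raises(UndefinedIndexError):
            c_value(summary(0, 0.0, 1), scheme_all)

    def test_i_above_n_rejected(self, scheme_all):
        with pytest.raises(UndefinedIndexError):
            c_value(summary(0, 10.0, 17), scheme_all)


def brute_force_i(durations, x, n):
    """Literal evaluation: one minus MAD of relative durations over its
    maximum 2(n-1)/n^2."""
    padded = list(durations) + [0.0] * (n - len(durations))
    mad = sum(abs(d / x - 1 / n) for d in padded) / n
    return 1.0 - mad / (2 * (n - 1) / n**2)


class TestIValue:
    def test_uniform_gives_one(self, scheme_all):
        d = {a: 210.0 / 16 for a in scheme_all}
        assert i_value(summary(15, 210.0, 16, d), scheme_all) == 1.0

    def test_single_area_gives_zero(self, scheme_all):
        d = {A: 60.0}
        assert i_value(summary(0, 60.0, 1, d), scheme_all) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_four_area_hand_example(self):
        # d = (2, 1, 1, 0), x = 4, n = 4 -> 1 - (4/6)(0.25 + 0 + 0 + 0.25)
        scheme = AreaScheme(tuple((s, VESTIBULAR) for s in (1, 2, 3, 4)))
        d = dict(zip(scheme, (2.0, 1.0, 1.0)))
        got = i_value(summary(2, 4.0, 3, d), scheme)
        assert got == pytest.approx(2 / 3)
        assert got == pytest.approx(brute_force_i([2, 1, 1, 0], 4.0, 4))

    def test_matches_brute_force_on_uneven_split(self, scheme_all):
        durs = [50.0, 30.0, 20.0, 10.0]
        d = dict(zip(scheme_all, durs))
        got = i_value(summary(3, 110.0, 4, d), scheme_all)
        assert got == pytest.approx(brute_force_i(durs, 110.0, 16))

    def test_degenerate_inputs_rejected(self, scheme_all):
        with pytest.raises(UndefinedIndexError):
            i_value(summary(0, 0.0, 0), scheme_all)
        single = AreaScheme(((1, VESTIBULAR),))
        with pytest.raises(UndefinedIndexError):
            i_value(summary(0, 10.0, 1, {(1, VESTIBULAR): 10.0}), single)


class TestTsi:
    def test_complete_isochronal_reference(self, complete_session, scheme_all):
        r = tsi(complete_session, scheme_all)
        assert round(r.c_value, 2) == 0.93
        assert r.i_value == 1.0
        assert round(r.tsi, 2) == 1.93

    def test_perfect_long_session(self, scheme_all):
        dwell = 480.0 / 16
        events = [
            BrushingEvent(j * dwell, (j + 1) * dwell, area)
            for j, area in enumerate(scheme_all)
        ]
        r = tsi(BrushingSession(events), scheme_all)
        assert r.tsi == pytest.approx(1.96875)

    def test_single_area_session_is_c_only(self, scheme_all):
        r = tsi(make_session([A], duration=60.0), scheme_all)
        assert r.i_value == pytest.approx(0.0, abs=1e-12)
        assert r.tsi == pytest.approx(0.0625)

    def test_tsi_is_sum_of_components(self, complete_session, scheme_all):
        r = tsi(complete_session, scheme_all)
        assert r.tsi == r.c_value + r.i_value


class TestRestrictToSurfaces:
    def test_filter_drops_events_and_shrinks_scheme(self, scheme_all):
        session = make_session([A, (1, "occlusal"), A])
        sub_session, sub_scheme = restrict_to_surfaces(
            session, scheme_all, {VESTIBULAR, ORAL}
        )
        assert sub_scheme.n == 12
        s = summarize_session(sub_session, sub_scheme)
        # the two vestibular events become adjacent: same area, no change
        assert (s.b, s.x, s.i) == (0, 20.0, 1)

    def test_identity_when_no_event_excluded(self, scheme_all):
        session = make_session([A, B, A])
        sub_session, sub_scheme = restrict_to_surfaces(
            session, scheme_all, {VESTIBULAR, ORAL}
        )
        assert sub_scheme.n == 12
        before = summarize_session(session, scheme_all)
        after = summarize_session(sub_session, sub_scheme)
        assert (before.b, before.x, before.i) == (after.b, after.x, after.i)
        assert before.d == after.d

    def test_all_events_excluded_is_an_error(self, scheme_all):
        session = make_session([(1, "occlusal"), (3, "occlusal")])
        with pytest.raises(EmptySessionError, match="selected surfaces"):
            restrict_to_surfaces(session, scheme_all, {VESTIBULAR, ORAL})


class TestSessionInvariants:
    def test_events_sorted_on_construction(self):
        e1 = BrushingEvent(10.0, 20.0, A)
        e2 = BrushingEvent(0.0, 5.0, B)
        session = BrushingSession([e1, e2])
        assert [e.onset for e in session] == [0.0, 10.0]

    def test_overlap_rejected(self):
        with pytest.raises(SessionValidationError, match="overlap"):
            BrushingSession(
                [BrushingEvent(0.0, 10.0, A), BrushingEvent(5.0, 15.0, B)]
            )

    @pytest.mark.parametrize("onset, offset", [(5.0, 5.0), (5.0, 4.0), (-1.0, 2.0)])
    def test_bad_event_times_rejected(self, onset, offset):
        with pytest.raises(SessionValidationError):
            BrushingEvent(onset, offset, A)

    def test_summary_duration_identity(self, complete_session, scheme_all):
        s = summarize_session(complete_session, scheme_all)
        assert s.x == pytest.approx(sum(s.d.values()))
        assert s.i == sum(1 for v in s.d.values() if v > 0)
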