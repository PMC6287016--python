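import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hpbu.config import VisionConfig
from hpbu.motor import DoneSignal
from hpbu.trajectory import Trajectory
from hpbu.vision import (
    VisionLevel,
    angle_belief,
    angle_bin_centers,
    event_endpoint,
    to_oculocentric,
)


def line_trajectory(heading, n=60, speed=1.0, rate=100.0, start=(0.0, 0.0)):
    t = np.arange(n) / rate
    d = np.array([math.cos(heading), math.sin(heading)])
    xy = np.asarray(start) + np.outer(t * speed, d)
    return Trajectory(t, xy)


class TestAngleBelief:
    def test_eastward_motion_peaks_at_zero_bin(self):
        b = angle_belief([[0, 0], [1, 0]], n_angle=16)
        assert b.argmax_label == 0

    def test_northward_motion_peaks_at_quarter_turn(self):
        b = angle_belief([[0, 0], [0, 1]], n_angle=16)
        assert b.argmax_label == 4  # pi/2 at 16 bins

    def test_diagonal_split_matches_kernel_oracle(self):
        kappa, n = 8.0, 16
        b = angle_belief([[0, 0], [1, 1]], n_angle=n, kappa=kappa)
        centers = angle_bin_centers(n)
        expected = np.exp(kappa * np.cos(centers - math.pi / 4))
        expected /= expected.sum()
        assert np.allclose(b.probs, expected, atol=1e-9)
        # pi/4 is the center of bin 2 at 16 bins: its neighbours split evenly
        assert b.argmax_label == 2
        assert b.probs[1] == pytest.approx(b.probs[3], abs=1e-12)

    def test_zero_displacement_is_uniform(self):
        b = angle_belief([[1, 2], [1, 2]], n_angle=16)
        assert np.allclose(b.probs, 1 / 16)


class TestOculocentric:
    @pytest.mark.parametrize(
        "origin, current, angle, length",
        [
            ((0, 0), (1, 0), 0.0, 1.0),
            ((0, 0), (1, 1), math.pi / 4, math.sqrt(2)),
            ((0, 0), (0, 0), 0.0, 0.0),
        ],
    )
    def test_examples(self, origin, current, angle, length):
        ev = to_oculocentric(origin, current, 0.1)
        assert ev.angle == pytest.approx(angle, abs=1e-12)
        assert ev.length == pytest.approx(length, abs=1e-12)

    @given(
        st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5)
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, ox, oy, cx, cy):
        ev = to_oculocentric((ox, oy), (cx, cy), 0.0)
        back = event_endpoint((ox, oy), ev)
        assert np.allclose(back, [cx, cy], atol=1e-9)

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            to_oculocentric((0, 0), (1, 0), -0.1)


class TestSurpriseSegmentation:
    def test_straight_line_yields_no_interior_events(self):
        vl = VisionLevel(VisionConfig())
        traj = line_trajectory(0.3, n=80)
        events = vl.segment(traj)
        # only the terminal event for the final stroke
        assert len(events) == 1

    def test_right_angle_corner_fires_once_at_corner(self):
        rate = 100.0
        n = 50
        t = np.arange(2 * n) / rate
        leg1 = np.outer(np.arange(n), [0.01, 0.0])
        leg2 = leg1[-1] + np.outer(np.arange(1, n + 1), [0.0, 0.01])
        traj = Trajectory(t, np.vstack([leg1, leg2]))
        vl = VisionLevel(VisionConfig())
        events = vl.segment(traj)
        assert len(events) == 2  # corner + terminal
        corner = event_endpoint([0, 0], events[0])
        # fired within a few samples after the corner at (0.49, 0)
        assert corner[0] == pytest.approx(leg1[-1][0], abs=0.05)
        assert corner[1] < 0.12

    def test_burn_in_blocks_early_events(self):
        vl = VisionLevel(VisionConfig())
        for k in range(3):  # fewer than n_burn informative samples
            assert vl.step(k / 100.0, np.array([k * 0.01, 0.0])) is None

    def test_event_count_invariant_to_translation_and_scale(self, corpus_all):
        vl = VisionLevel(VisionConfig())
        digit, seed, traj = corpus_all.items[37]
        base = len(vl.segment(traj))
        shifted = Trajectory(traj.t, traj.xy + np.array([5.0, -3.0]))
        scaled = Trajectory(traj.t, traj.xy * 2.5)
        assert len(vl.segment(shifted)) == base
        assert len(vl.segment(scaled)) == base

    def test_replaying_training_trajectory_reproduces_stored_events(
        self, corpus_no4, repertoire_no4
    ):
        digit, seed, traj = corpus_no4.items[11]
        vl = VisionLevel(repertoire_no4.config.vision)
        events = vl.segment(traj)
        stored = next(
            s for s in repertoire_no4.sequences
            if s.source_digit == digit and len(s.events) == len(events)
            and all(
                abs(a.angle - b.angle) < 1e-9 for a, b in zip(s.events, events)
            )
        )
        bin_width = 2 * math.pi / repertoire_no4.config.vision.n_angle
        for stored_ev, seen_ev in zip(stored.events, events):
            assert abs(stored_ev.angle - seen_ev.angle) < bin_width
            assert abs(stored_ev.dt - seen_ev.dt) <= 0.01 + 1e-9


class TestMotorConfirmation:
    def _level_with_event(self, pos, t):
        vl = VisionLevel(VisionConfig(), sample_rate=100.0)
        # drive a corner past the event position to segment one event
        xs = np.linspace(0, pos[0], 30)
        for k, x in enumerate(xs):
            vl.step(k / 100.0, np.array([x, 0.0]))
        for k in range(20):
            vl.step((30 + k) / 100.0, np.array([pos[0], (k + 1) * 0.02]))
        assert vl.events, "no event segmented in fixture"
        return vl

    def test_congruent_feedback_forwards_event(self):
        vl = self._level_with_event(np.array([0.3, 0.0]), 0.3)
        latest = vl.events[-1]
        done = DoneSignal(subgoal=latest.pos.copy(), time=latest.t, reached=True)
        assert vl.confirm_motor_done(done, stroke_length=0.3) is not None

    def test_distant_subgoal_fails_confirmation(self):
        vl = self._level_with_event(np.array([0.3, 0.0]), 0.3)
        latest = vl.events[-1]
        done = DoneSignal(
            subgoal=latest.pos + np.array([1.0, 1.0]), time=latest.t, reached=True
        )
        assert vl.confirm_motor_done(done, stroke_length=0.3) is None

    def test_stale_event_fails_time_window(self):
        vl = self._level_with_event(np.array([0.3, 0.0]), 0.3)
        latest = vl.events[-1]
        done = DoneSignal(subgoal=latest.pos.copy(), time=latest.t + 1.0, reached=True)
        assert vl.confirm_motor_done(done, stroke_length=0.3) is None
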