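import math

import numpy as np
import pytest

from hpbu.beliefs import DiscreteBelief, Mode
from hpbu.config import SequenceConfig
from hpbu.sequences import (
    EndOfSequence,
    ObservedSequence,
    SequenceHypothesis,
    SequenceLevel,
    compare_sequences,
    emit_motor_goal,
    sequence_likelihood,
    subgoal_positions,
)
from hpbu.vision import SurpriseEvent

CFG = SequenceConfig()


def seq(events, id="h", **kw):
    return SequenceHypothesis(id=id, events=tuple(SurpriseEvent(*e) for e in events),
                              schema_id=kw.get("schema_id", "c0"),
                              source_digit=kw.get("source_digit"))


def obs(events):
    return ObservedSequence([SurpriseEvent(*e) for e in events])


ZIGZAG = seq([(0.0, 0.4, 0.0), (1.8, 0.5, 0.3), (-1.2, 0.3, 0.2), (2.4, 0.6, 0.25)])


class TestCompare:
    def test_identical_prefix_scores_one(self):
        o = obs([(0.0, 0.4, 0.0), (1.8, 0.5, 0.3)])
        assert compare_sequences(o, ZIGZAG, CFG) == pytest.approx(1.0, abs=1e-12)

    def test_opposite_angles_score_near_zero(self):
        o = obs([(0.0 + math.pi, 0.4, 0.0), (1.8 - math.pi, 0.5, 0.3)])
        assert compare_sequences(o, ZIGZAG, CFG) < 1e-3

    def test_single_event_one_sigma_angle_offset(self):
        # hypothesis built so that merging its events can never win
        hyp = seq([(0.0, 0.4, 0.0), (math.pi, 0.4, 0.3)])
        o = obs([(CFG.sigma_angle, 0.4, 0.0)])
        expected = math.exp(-0.5)
        assert compare_sequences(o, hyp, CFG) == pytest.approx(expected, rel=1e-9)

    def test_overrun_penalized_per_extra_event(self):
        o = obs([(0.0, 0.4, 0.0), (math.pi, 0.4, 0.3), (0.0, 0.4, 0.2)])
        hyp = seq([(0.0, 0.4, 0.0), (math.pi, 0.4, 0.3)])
        val = compare_sequences(o, hyp, CFG)
        assert val == pytest.approx(math.exp(-CFG.overrun_rate), rel=1e-6)

    def test_full_mode_penalizes_unconsumed_tail(self):
        o = obs([(0.0, 0.4, 0.0)])
        prefix = compare_sequences(o, ZIGZAG, CFG)
        full = compare_sequences(o, ZIGZAG, CFG, full=True)
        assert full < prefix

    def test_boundary_split_absorbed_by_merge(self):
        # one stored stroke observed as two collinear halves
        hyp = seq([(0.0, 0.6, 0.0), (math.pi / 2, 0.5, 0.3)])
        o = obs([(0.0, 0.3, 0.0), (0.0, 0.3, 0.1), (math.pi / 2, 0.5, 0.2)])
        assert compare_sequences(o, hyp, CFG) > 0.8

    def test_empty_observation_rejected(self):
        with pytest.raises(ValueError):
            compare_sequences(ObservedSequence(), ZIGZAG, CFG)


class TestLikelihood:
    def test_identical_events_and_timing(self):
        o = obs([(0.0, 0.4, 0.0), (1.8, 0.5, 0.3)])
        assert sequence_likelihood(o, ZIGZAG, CFG) == pytest.approx(1.0, abs=1e-12)

    def test_timing_off_by_one_precision_width(self):
        o = obs([(0.0, 0.4, 0.0), (1.8, 0.5, 0.3 + CFG.pi_s_temporal)])
        assert sequence_likelihood(o, ZIGZAG, CFG) == pytest.approx(
            math.exp(-0.5), rel=1e-9
        )

    def test_spatial_and_temporal_factors_multiply(self):
        # iota = 0.8 via a pure length offset on a single event
        dl = CFG.sigma_length_frac * 0.4 * math.sqrt(2 * math.log(1 / 0.8))
        hyp = seq([(0.0, 0.4, 0.0), (math.pi, 0.4, 0.3)])
        o = obs([(0.0, 0.4 + dl, 2 * CFG.pi_s_temporal)])
        # first event's stored delay is 0; mismatch is 2 pi_S
        got = sequence_likelihood(o, hyp, CFG)
        assert got == pytest.approx(0.8 * math.exp(-2.0), rel=1e-6)

    def test_monotone_in_timing_mismatch(self):
        vals = [
            sequence_likelihood(obs([(0.0, 0.4, 0.0), (1.8, 0.5, 0.3 + d)]), ZIGZAG, CFG)
            for d in (0.0, 0.05, 0.1, 0.2, 0.4)
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("pi_s, expect", [(1e4, 1.0), (1e-4, 0.0)])
    def test_precision_limits(self, pi_s, expect):
        import dataclasses

        cfg = dataclasses.replace(CFG, pi_s_temporal=pi_s)
        o = obs([(0.0, 0.4, 0.0), (1.8, 0.5, 0.45)])  # timing off by 0.15
        assert sequence_likelihood(o, ZIGZAG, cfg) == pytest.approx(expect, abs=1e-3)

    def test_self_comparison_is_one_for_every_stored_sequence(self, small_repertoire):
        for s in small_repertoire.sequences:
            o = ObservedSequence(list(s.events))
            assert compare_sequences(o, s, small_repertoire.config.sequence) == (
                pytest.approx(1.0, abs=1e-9)
            )


class TestLevel:
    def make_level(self):
        hyps = [
            seq([(0.0, 0.4, 0.0), (1.8, 0.5, 0.3)], id="s0", schema_id="c0"),
            seq([(0.0, 0.4, 0.0), (1.9, 0.5, 0.31)], id="s1", schema_id="c0"),
            seq([(math.pi, 0.4, 0.0), (-1.2, 0.5, 0.3)], id="s2", schema_id="c1"),
        ]
        return SequenceLevel(hyps, SequenceConfig())

    def test_no_event_keeps_posterior(self):
        level = self.make_level()
        before = level.state.posterior.probs.copy()
        level.step(DiscreteBelief.uniform(("c0", "c1")), None, Mode.PERCEPTION)
        assert np.allclose(level.state.posterior.probs, before)

    def test_matching_event_concentrates_on_matching_schema(self):
        level = self.make_level()
        up = level.step(
            DiscreteBelief.uniform(("c0", "c1")),
            SurpriseEvent(0.0, 0.4, 0.0),
            Mode.PERCEPTION,
        )
        assert up.labels == ("c0", "c1")
        assert up.prob_of("c0") > 0.9

    def test_upward_message_matches_evidence_mass(self):
        level = self.make_level()
        level.step(
            DiscreteBelief.uniform(("c0", "c1")),
            SurpriseEvent(0.0, 0.4, 0.0),
            Mode.PERCEPTION,
        )
        up = level.upward_message()
        ev = level.evidence
        c0 = sum(p for lbl, p in zip(ev.labels, ev.probs) if lbl in ("s0", "s1"))
        assert up.prob_of("c0") == pytest.approx(c0, abs=1e-6)

    def test_point_mass_schema_prediction_supports_only_members(self):
        level = self.make_level()
        td = level.top_down_from_schemas(
            DiscreteBelief(("c0", "c1"), [1.0, 0.0])
        )
        assert td.prob_of("s2") < 1e-6
        assert td.prob_of("s0") == pytest.approx(0.5, abs=1e-6)

    def test_trial_reset_clears_observation_and_blends_prior(self):
        level = self.make_level()
        level.step(
            DiscreteBelief.uniform(("c0", "c1")),
            SurpriseEvent(0.0, 0.4, 0.0),
            Mode.PERCEPTION,
        )
        level.reset_trial()
        assert len(level.observed) == 0
        assert len(level.evidence) == 3
        assert np.allclose(level.evidence.probs, 1 / 3)


class TestMotorGoals:
    def test_first_goal_is_projection_of_first_event(self):
        goal, length, dt = emit_motor_goal(ZIGZAG, 0, origin=(1.0, 2.0))
        assert np.allclose(goal, [1.0 + 0.4, 2.0], atol=1e-12)
        assert length == pytest.approx(0.4)
        assert dt == 0.0

    def test_past_end_raises_end_of_sequence(self):
        with pytest.raises(EndOfSequence):
            emit_motor_goal(ZIGZAG, len(ZIGZAG), origin=(0, 0))

    def test_subgoal_chain_is_cumulative(self):
        pos = subgoal_positions(ZIGZAG, (0.0, 0.0))
        assert pos.shape == (4, 2)
        assert np.allclose(pos[0], [0.4, 0.0], atol=1e-12)
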