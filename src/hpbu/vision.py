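"""Vision level: writing-angle beliefs and surprise segmentation.

The level receives raw pen samples and represents the instantaneous
writing direction as a discrete belief over ``n_angle`` circular bins,
spread with a von-Mises kernel.  An exponentially discounted mixture of
past angle beliefs serves as the level's prediction of the next writing
angle; when the surprise of the current angle under that prediction
exceeds a threshold, a stroke event is segmented.  Events are coded in
an oculocentric frame: relative polar coordinates (angle, length)
anchored at the previous event's position, plus the elapsed time, and
the anchor then moves to the current pen position.  The angle-history
predictor restarts at each event, so a sustained curve accumulates
deviation from the heading at the segment start and is carved into arc
events, while straight motion stays fully predicted.

During production the level additionally arbitrates the long-range
loop from motor control: a "done" notification is only forwarded to
the sequence level if a visual stroke event confirms it close to the
announced subgoal in both time and space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .beliefs import DiscreteBelief, LevelState, Mode, update_level
from .config import VisionConfig
from .motor import DoneSignal

__all__ = [
    "SurpriseEvent",
    "angle_bin_centers",
    "angle_belief",
    "predictor_surprise",
    "to_oculocentric",
    "event_endpoint",
    "VisionLevel",
]


@dataclass(frozen=True)
class SurpriseEvent:
    """One segmented stroke in the oculocentric frame.

    ``angle`` is the polar angle (canvas frame) of the current pen
    position seen from the previous event's position, ``length`` the
    Euclidean distance, ``dt`` the elapsed time since the previous
    event (0 for the first event of a trajectory by convention).
    """

    angle: float   # rad
    length: float  # canvas units
    dt: float      # s

    def __post_init__(self):
        if self.length < 0:
            raise ValueError("event length must be >= 0")
        if self.dt < 0:
            raise ValueError("event dt must be >= 0")


def angle_bin_centers(n_angle: int) -> np.ndarray:
    """Equally spaced circular bin centers on [0, 2pi)."""
    return 2.0 * np.pi * np.arange(n_angle) / n_angle


def angle_belief(window, n_angle: int = 16, kappa: float = 8.0) -> DiscreteBelief:
    """Belief over writing-angle bins from the latest displacement.

    ``window`` is an (m, 2) array-like of recent pen positions (m >= 2).
    The heading of the last displacement is spread over the circular
    bins with a von-Mises kernel of concentration ``kappa``.  A zero
    displacement carries no direction information and yields the
    uniform belief.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] < 2:
        raise ValueError("need at least two pen positions")
    d = window[-1] - window[-2]
    labels = tuple(range(n_angle))
    if np.hypot(*d) == 0.0:
        return DiscreteBelief.uniform(labels)
    heading = math.atan2(d[1], d[0])
    weights = np.exp(kappa * np.cos(angle_bin_centers(n_angle) - heading))
    return DiscreteBelief(labels, weights)


def predictor_surprise(predictor: DiscreteBelief, current: DiscreteBelief) -> float:
    """Surprise (nats) of the current modal angle under the predictor."""
    return -math.log(predictor.prob_of(current.argmax_label))


def to_oculocentric(origin, current, dt: float) -> SurpriseEvent:
    """Cartesian-to-relative-polar event coding.

    A degenerate zero-length displacement gets angle 0 by convention.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    origin = np.asarray(origin, dtype=float)
    current = np.asarray(current, dtype=float)
    d = current - origin
    length = float(np.hypot(*d))
    angle = float(math.atan2(d[1], d[0])) if length > 0 else 0.0
    return SurpriseEvent(angle=angle, length=length, dt=dt)


def event_endpoint(origin, event: SurpriseEvent) -> np.ndarray:
    """Inverse of :func:`to_oculocentric`: re-project to the canvas."""
    origin = np.asarray(origin, dtype=float)
    return origin + event.length * np.array([math.cos(event.angle), math.sin(event.angle)])


@dataclass
class _TimedEvent:
    event: SurpriseEvent
    pos: np.ndarray  # absolute anchor (event endpoint) on the canvas
    t: float         # absolute time


class VisionLevel:
    """Stateful vision level fed one pen sample at a time."""

    def __init__(self, config: VisionConfig = VisionConfig(), sample_rate: float = 100.0):
        self.config = config
        self.sample_rate = sample_rate
        labels = tuple(range(config.n_angle))
        uniform = DiscreteBelief.uniform(labels)
        self.state = LevelState(posterior=uniform, precision=config.precision)
        self._labels = labels
        self.reset()

    def reset(self) -> None:
        self._prev_sample = None       # (t, pos)
        self._origin = None            # oculocentric anchor
        self._origin_t = 0.0
        self._predictor_w = None       # unnormalised discounted mixture
        self._history_count = 0
        self.events: list[_TimedEvent] = []
        self._fwd_anchor = None  # (pos, t) of the last forwarded event
        uniform = DiscreteBelief.uniform(self._labels)
        self.state = LevelState(posterior=uniform, precision=self.config.precision)

    # -- predictor bookkeeping ----------------------------------------
    def _reset_history(self) -> None:
        self._predictor_w = None
        self._history_count = 0

    def _predictor(self) -> DiscreteBelief | None:
        if self._predictor_w is None or self._history_count < self.config.n_burn:
            return None
        return DiscreteBelief.from_weights(self._labels, self._predictor_w)

    def _push_history(self, belief: DiscreteBelief) -> None:
        # Exponentially discounted mixture anchored at the segment
        # start: a belief arriving k samples after the last event gets
        # weight lambda^k.  The predictor therefore encodes the heading
        # established right after the event; steady drift away from it
        # (a sustained curve) accumulates surprise instead of being
        # tracked, so curves are carved into arc events.
        lam = self.config.history_decay
        w = belief.probs * (lam ** self._history_count)
        if self._predictor_w is None:
            self._predictor_w = w.copy()
        else:
            self._predictor_w = self._predictor_w + w
        self._history_count += 1

    # -- main step -----------------------------------------------------
    def step(self, t: float, pos) -> SurpriseEvent | None:
        """Consume one pen sample; return a new stroke event if one fires."""
        pos = np.asarray(pos, dtype=float)
        cfg = self.config
        if self._prev_sample is None:
            self._prev_sample = (t, pos)
            self._origin = pos.copy()
            self._origin_t = t
            self._start_t = t
            self._start_pos = pos.copy()
            return None

        belief = angle_belief(
            np.vstack([self._prev_sample[1], pos]), cfg.n_angle, cfg.kappa_angle
        )
        self._prev_sample = (t, pos)
        moved = belief.entropy() < math.log(cfg.n_angle) - 1e-9  # uniform = no motion
        if not moved:
            return None

        predictor = self._predictor()
        fired = None
        if predictor is not None:
            surprise = predictor_surprise(predictor, belief)
            # free-energy trace: prediction from history vs incoming belief
            self.state = update_level(
                LevelState(
                    posterior=self.state.posterior,
                    precision=cfg.precision,
                    mode=Mode.PERCEPTION,
                ),
                p_td=predictor,
                p_bu=belief,
            )
            if surprise > cfg.surprise_threshold:
                dt = 0.0 if not self.events else t - self._origin_t
                candidate = to_oculocentric(self._origin, pos, dt)
                if candidate.length >= cfg.min_event_length:
                    fired = candidate
                    self.events.append(_TimedEvent(event=fired, pos=pos.copy(), t=t))
                    self._origin = pos.copy()
                    self._origin_t = t
                self._reset_history()
        else:
            self.state.posterior = belief

        self._push_history(belief)
        return fired

    def finish(self) -> SurpriseEvent | None:
        """Close the trajectory: emit a final event for the tail segment.

        The pen stopping is itself the terminal boundary; without this
        the last stroke after the final surprise would be dropped.
        """
        if self._prev_sample is None or self._origin is None:
            return None
        t, pos = self._prev_sample
        if float(np.hypot(*(pos - self._origin))) < self.config.min_event_length:
            return None
        dt = 0.0 if not self.events else t - self._origin_t
        ev = to_oculocentric(self._origin, pos, dt)
        self.events.append(_TimedEvent(event=ev, pos=pos.copy(), t=t))
        self._origin = pos.copy()
        self._origin_t = t
        self._reset_history()
        return ev

    # -- long-range loop ----------------------------------------------
    def confirm_motor_done(
        self, done: DoneSignal, stroke_length: float
    ) -> SurpriseEvent | None:
        """Forward the latest stroke event iff it confirms the done signal.

        Confirmation requires a segmented event within ``tau_confirm``
        sampling periods of the notification and within
        ``r_confirm_frac`` of the subgoal's stroke length from the
        announced subgoal.  Otherwise nothing is forwarded and the
        mismatch persists as unexplained prediction error upstream.

        The forwarded event is re-anchored at the previously *forwarded*
        event's position, so the stroke chain the sequence level sees
        stays geometrically consistent even when an intermediate
        confirmation was missed (the next confirmed event then carries
        the merged displacement).
        """
        if not self.events:
            return None
        tau = self.config.tau_confirm_periods / self.sample_rate
        radius = max(
            self.config.r_confirm_frac * max(stroke_length, 1e-9),
            self.config.r_confirm_min,
        )
        latest = self.events[-1]
        if abs(latest.t - done.time) <= tau + 1e-12 and (
            float(np.hypot(*(latest.pos - np.asarray(done.subgoal)))) <= radius
        ):
            return self._forward(latest)
        return None

    def _forward(self, timed: _TimedEvent, t_event: float | None = None) -> SurpriseEvent:
        t = timed.t if t_event is None else t_event
        if self._fwd_anchor is None:
            # first forwarded event: anchored at the trajectory start,
            # zero delay by the same convention as perception
            ev = to_oculocentric(self._start_pos, timed.pos, 0.0)
        else:
            anchor_pos, anchor_t = self._fwd_anchor
            ev = to_oculocentric(anchor_pos, timed.pos, max(t - anchor_t, 1e-9))
        self._fwd_anchor = (timed.pos.copy(), t)
        return ev

    # -- batch segmentation -------------------------------------------
    def segment(self, traj) -> list[SurpriseEvent]:
        """Segment a whole trajectory into stroke events (fresh state)."""
        self.reset()
        for t, p in zip(traj.t, traj.xy):
            self.step(float(t), p)
        self.finish()
        return [te.event for te in self.events]
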