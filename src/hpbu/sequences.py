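"""Sequence level: stored stroke-event sequences and their likelihoods.

A sequence hypothesis is an ordered list of oculocentric stroke events
with learned per-event timing.  An observation accumulated during a
trial is scored against each hypothesis in two factors:

* a spatial comparison ``iota`` in [0, 1] — the geometric mean of
  per-event Gaussian kernels on the circular angle difference and the
  relative length difference of the aligned prefix (hypotheses shorter
  than the observation pay an exponential overrun penalty);
* a temporal-binding factor ``exp(-(dt' - dt_i)^2 / (2 pi_S^2))`` on
  the latest event's observed vs. stored delay, whose width pi_S is
  the level's temporal precision: a sharp pi_S makes unpredicted
  delays collapse the likelihood, a wide one makes timing irrelevant.

The level posterior combines this bottom-up evidence with the schema
level's top-down prediction through the shared precision-weighted
update, and the within-schema posterior mass is passed back up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .beliefs import DiscreteBelief, LevelState, Mode, update_level
from .config import SequenceConfig
from .vision import SurpriseEvent, event_endpoint

__all__ = [
    "SequenceHypothesis",
    "ObservedSequence",
    "compare_sequences",
    "sequence_likelihood",
    "subgoal_positions",
    "emit_motor_goal",
    "EndOfSequence",
    "SequenceLevel",
]

_MIN_LENGTH_SCALE = 1e-3


@dataclass(frozen=True)
class SequenceHypothesis:
    """A stored writing sequence; ``source_digit`` is evaluation-only."""

    id: str
    events: tuple
    schema_id: str | None = None
    source_digit: int | None = None

    def __post_init__(self):
        events = tuple(self.events)
        if len(events) < 2:
            raise ValueError("a sequence hypothesis needs >= 2 events")
        if events[0].dt != 0.0:
            raise ValueError("the first event of a sequence must have dt = 0")
        object.__setattr__(self, "events", events)

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class ObservedSequence:
    """Events accumulated during the current trial (the online s')."""

    events: list = field(default_factory=list)

    def append(self, event: SurpriseEvent) -> None:
        self.events.append(event)

    def clear(self) -> None:
        self.events.clear()

    def __len__(self) -> int:
        return len(self.events)


def _circ_diff(a: float, b: float) -> float:
    """Signed circular difference wrapped to (-pi, pi]."""
    d = (a - b + math.pi) % (2.0 * math.pi) - math.pi
    return d if d != -math.pi else math.pi


def _merged_chord(events, i: int, p: int):
    """Chord (angle, length, path) of events[i:i+p] merged by vector sum.

    Consecutive oculocentric events are displacement vectors; summing
    them gives the geometry of the same pen path segmented one level
    coarser, which is exactly what a boundary split/merge produces.
    ``path`` is the summed event length; its excess over the chord
    length measures how much curvature the merge would hide.
    """
    vx = sum(ev.length * math.cos(ev.angle) for ev in events[i : i + p])
    vy = sum(ev.length * math.sin(ev.angle) for ev in events[i : i + p])
    path = sum(ev.length for ev in events[i : i + p])
    length = math.hypot(vx, vy)
    angle = math.atan2(vy, vx) if length > 0 else 0.0
    return angle, length, path


def _log_kernel(obs_chord, hyp_chord, config: SequenceConfig) -> float:
    """Log Gaussian kernel between two (possibly merged) chords.

    Besides the angle and length terms, each side pays for the slack
    between its path length and its chord length: a merge of nearly
    collinear sub-events (a genuine boundary split) is almost free,
    while straightening a curve into a chord is heavily penalized.
    """
    da = _circ_diff(obs_chord[0], hyp_chord[0])
    sigma_a = config.sigma_angle
    sigma_l = config.sigma_length_frac * max(hyp_chord[1], _MIN_LENGTH_SCALE)
    dl = obs_chord[1] - hyp_chord[1]
    out = -(da * da) / (2.0 * sigma_a * sigma_a) - (dl * dl) / (2.0 * sigma_l * sigma_l)
    for chord in (obs_chord, hyp_chord):
        slack = chord[2] - chord[1]
        sigma_s = config.sigma_length_frac * max(chord[1], _MIN_LENGTH_SCALE)
        out -= (slack * slack) / (2.0 * sigma_s * sigma_s)
    return out


#: allowed alignment steps (events consumed from observation, hypothesis);
#: merges absorb segmentation boundary splits up to a factor of three
_ALIGN_STEPS = ((1, 1), (1, 2), (2, 1), (1, 3), (3, 1))


def compare_sequences(
    observed: ObservedSequence,
    hypothesis: SequenceHypothesis,
    config: SequenceConfig = SequenceConfig(),
    full: bool = False,
) -> float:
    """Spatial comparison iota(s', s_i) in [0, 1].

    Prefix-anchored alignment of the observation against the leading
    events of the hypothesis: both sides are consumed in order from the
    start, and each alignment step compares one event — or the merged
    chord of up to three consecutive events, which makes the score
    robust to surprise-boundary splits — through a Gaussian kernel on
    the circular angle difference and the relative length difference
    (width proportional to the stored chord length, so the score is
    invariant under uniform rescaling of both sequences).  iota is the
    geometric mean of the per-event kernels, weighted per observed
    event, maximized over alignments by dynamic programming; identical
    prefixes score exactly 1.  If the observation overruns a shorter
    hypothesis, each unmatched event multiplies the score by
    ``exp(-overrun_rate)``.

    With ``full=True`` (whole-sequence similarity, used for schema
    clustering) an unconsumed hypothesis tail is penalized at the same
    per-event rate, so a sequence that merely *starts* like a longer
    one no longer scores as its equal.
    """
    n_obs = len(observed)
    if n_obs == 0:
        raise ValueError("cannot compare an empty observation")
    obs = observed.events
    hyp = hypothesis.events
    n_hyp = len(hyp)

    neg_inf = float("-inf")
    # dp[i][j]: best sum over match steps of (obs events consumed) * log k,
    # having consumed i observed and j hypothesis events
    dp = [[neg_inf] * (n_hyp + 1) for _ in range(n_obs + 1)]
    dp[0][0] = 0.0
    for i in range(n_obs + 1):
        for j in range(n_hyp + 1):
            cur = dp[i][j]
            if cur == neg_inf:
                continue
            for p, q in _ALIGN_STEPS:
                if i + p > n_obs or j + q > n_hyp:
                    continue
                lk = _log_kernel(_merged_chord(obs, i, p), _merged_chord(hyp, j, q), config)
                cand = cur + p * lk
                if cand > dp[i + p][j + q]:
                    dp[i + p][j + q] = cand

    # best full consumption of the observation; overrunning events (only
    # possible once the hypothesis is exhausted) are penalized per event
    best = neg_inf
    for j in range(n_hyp + 1):
        for i in range(n_obs + 1):
            if dp[i][j] == neg_inf:
                continue
            overrun = n_obs - i
            if overrun > 0 and j < n_hyp:
                continue  # may only overrun past the hypothesis end
            leftover = (n_hyp - j) if full else 0
            matched = i
            if matched == 0:
                score = -config.overrun_rate * (overrun + leftover)
            else:
                score = dp[i][j] / matched - config.overrun_rate * (overrun + leftover)
            if score > best:
                best = score
    return min(math.exp(best), 1.0)


def sequence_likelihood(
    observed: ObservedSequence,
    hypothesis: SequenceHypothesis,
    config: SequenceConfig = SequenceConfig(),
) -> float:
    """P(s' | s_i): spatial comparison times the temporal-binding factor."""
    if config.pi_s_temporal <= 0:
        raise ValueError("temporal precision pi_S must be positive")
    iota = compare_sequences(observed, hypothesis, config)
    j = len(observed) - 1
    dt_obs = observed.events[j].dt
    dt_hyp = hypothesis.events[min(j, len(hypothesis) - 1)].dt
    delta = dt_obs - dt_hyp
    temporal = math.exp(-(delta * delta) / (2.0 * config.pi_s_temporal**2))
    return iota * temporal


def subgoal_positions(hypothesis: SequenceHypothesis, start) -> np.ndarray:
    """Re-project a sequence's events into canvas subgoal positions."""
    pos = np.asarray(start, dtype=float)
    out = []
    for ev in hypothesis.events:
        pos = event_endpoint(pos, ev)
        out.append(pos)
    return np.array(out)


class EndOfSequence(Exception):
    """Raised when a motor goal is requested past the end (production done)."""


def emit_motor_goal(hypothesis: SequenceHypothesis, step_index: int, origin):
    """Subgoal for one production step.

    Returns ``(subgoal_xy, stroke_length, dt)`` where the subgoal is the
    event's endpoint relative to the current oculocentric origin and
    ``dt`` its stored timing goal.  Past the last event the production
    is complete and :class:`EndOfSequence` is raised.
    """
    if step_index >= len(hypothesis):
        raise EndOfSequence(hypothesis.id)
    ev = hypothesis.events[step_index]
    return event_endpoint(origin, ev), ev.length, ev.dt


class SequenceLevel:
    """Stateful sequence level over a fixed repertoire."""

    def __init__(
        self,
        hypotheses: list,
        config: SequenceConfig = SequenceConfig(),
        schema_of: dict | None = None,
    ):
        if not hypotheses:
            raise ValueError("sequence level needs a nonempty repertoire")
        self.hypotheses = list(hypotheses)
        self.config = config
        self.by_id = {h.id: h for h in self.hypotheses}
        self.schema_of = schema_of or {h.id: h.schema_id for h in self.hypotheses}
        for h in self.hypotheses:
            if self.schema_of.get(h.id) is None:
                raise ValueError(f"sequence {h.id} has no schema")
        self.labels = tuple(h.id for h in self.hypotheses)
        self.state = LevelState(
            posterior=DiscreteBelief.uniform(self.labels), precision=config.precision
        )
        #: pure bottom-up evidence accumulated over the trial, in log
        #: space and unfloored (flooring would silently forgive
        #: hypotheses whose cumulative evidence lies below the floor);
        #: its running sum equals the joint log likelihood of the whole
        #: observation.  The upward message aggregates this — never the
        #: blended posterior, so top-down predictions are not echoed
        #: back up.
        self._log_evidence = np.zeros(len(self.labels))
        self.observed = ObservedSequence()
        self._prev_liks = None  # likelihoods at the previous event step
        #: scale applied to stored event delays when predicting timing;
        #: production sets this to its own pacing factor, since the
        #: timing goals it sent to motor control were scaled the same way
        self.dt_scale = 1.0

    # -- trial bookkeeping --------------------------------------------
    def reset_trial(self) -> None:
        """Clear the observation; re-prime the prior toward uniform.

        The previous trial's posterior is blended 50/50 (configurable)
        with the uniform distribution, keeping some carry-over of
        recent context without locking in the last trial's winner.
        """
        self.observed.clear()
        self._prev_liks = None
        self._log_evidence = np.zeros(len(self.labels))
        carry = self.config.reset_carryover
        uniform = DiscreteBelief.uniform(self.labels)
        self.state = LevelState(
            posterior=self.state.posterior.blend(uniform, 1.0 - carry),
            precision=self.config.precision,
        )

    # -- messages ------------------------------------------------------
    def top_down_from_schemas(self, schema_posterior: DiscreteBelief) -> DiscreteBelief:
        """P_td(s) = sum_c P(c) P(s|c), with P(s|c) uniform in the schema."""
        members: dict = {}
        for sid in self.labels:
            members.setdefault(self.schema_of[sid], []).append(sid)
        weights = np.zeros(len(self.labels))
        index = {sid: i for i, sid in enumerate(self.labels)}
        for c, sids in members.items():
            w = schema_posterior.prob_of(c) / len(sids)
            for sid in sids:
                weights[index[sid]] = w
        return DiscreteBelief.from_weights(self.labels, weights)

    @property
    def evidence(self) -> DiscreteBelief:
        """The accumulated evidence, normalized for readout."""
        return DiscreteBelief.from_weights(
            self.labels, np.exp(self._log_evidence - self._log_evidence.max())
        )

    def upward_message(self) -> DiscreteBelief:
        """P_bu(C|S): accumulated bottom-up evidence mass per schema."""
        schema_labels = sorted({self.schema_of[sid] for sid in self.labels})
        index = {c: i for i, c in enumerate(schema_labels)}
        weights = np.zeros(len(schema_labels))
        probs = np.exp(self._log_evidence - self._log_evidence.max())
        probs = probs / probs.sum()
        for sid, p in zip(self.labels, probs):
            weights[index[self.schema_of[sid]]] += p
        return DiscreteBelief.from_weights(tuple(schema_labels), weights)

    def likelihood_of(self, sequence_id: str) -> float:
        """P(s'|s_i) of the current observation for one hypothesis."""
        if len(self.observed) == 0:
            return 1.0
        h = self.by_id[sequence_id]
        iota = compare_sequences(self.observed, h, self.config)
        j = len(self.observed) - 1
        dt_hyp = h.events[min(j, len(h) - 1)].dt * self.dt_scale
        delta = self.observed.events[j].dt - dt_hyp
        temporal = math.exp(-(delta * delta) / (2.0 * self.config.pi_s_temporal**2))
        return iota * temporal

    def completion_update(self, schema_posterior: DiscreteBelief, mode: Mode) -> DiscreteBelief:
        """Evidence step for the end of a trial: the sequence is over.

        The pen lifting is itself informative — a stored sequence whose
        tail was never observed is not what was seen, however well its
        prefix matched.  Each hypothesis is reweighted by the ratio of
        its full-consumption similarity to its prefix similarity, which
        is exactly the penalty for its unconsumed tail.
        """
        if len(self.observed) == 0:
            return self.upward_message()
        w = np.empty(len(self.hypotheses))
        for k, h in enumerate(self.hypotheses):
            prefix = compare_sequences(self.observed, h, self.config)
            full = compare_sequences(self.observed, h, self.config, full=True)
            w[k] = full / max(prefix, 1e-300)
        self._log_evidence = self._log_evidence + np.log(np.maximum(w, 1e-300))
        p_bu = self.state.posterior.reweight(
            np.clip(w, math.exp(-self.config.evidence_clip), 1.0)
        )
        p_td = self.top_down_from_schemas(schema_posterior)
        self.state.mode = mode
        self.state = update_level(self.state, p_td=p_td, p_bu=p_bu)
        return self.upward_message()

    # -- main update ---------------------------------------------------
    def step(
        self,
        schema_posterior: DiscreteBelief,
        event: SurpriseEvent | None,
        mode: Mode,
        miss: bool = False,
    ) -> DiscreteBelief:
        """One level update; returns the upward message P_bu(C|S).

        Stroke events are the level's clock: between events no new
        evidence reaches the level and its posterior persists
        unchanged (the upward message is simply re-sent).  With an
        event the observation grows, the prior is reweighted by the
        incremental likelihood, and the precision-weighted update
        combines the result with the schema prediction.  ``miss=True``
        forces an update with no new evidence — used when a predicted
        action outcome failed to arrive, so the disagreement between
        the empirical prior and the top-down prediction registers as
        free energy instead of silently persisting.
        """
        if event is None and not miss:
            return self.upward_message()
        prior = self.state.posterior
        if event is not None:
            self.observed.append(event)
            n = len(self.observed)
            j = n - 1
            cum_obs = sum(ev.dt for ev in self.observed.events)
            log_joint = np.empty(len(self.hypotheses))
            d_temporal = np.empty(len(self.hypotheses))
            for k, h in enumerate(self.hypotheses):
                iota = compare_sequences(self.observed, h, self.config)
                # joint (product) spatial likelihood of the prefix: the
                # geometric-mean iota raised to the number of events
                log_joint[k] = n * math.log(max(iota, 1e-300))
                # temporal evidence is tempo-invariant: the stored
                # delay is rescaled by the writing tempo estimated from
                # the cumulative delays so far, so a uniformly slower
                # or faster rendition of the same rhythm is not
                # penalized while a different rhythm still is
                dt_hyp = h.events[min(j, len(h) - 1)].dt * self.dt_scale
                cum_hyp = sum(
                    h.events[min(i, len(h) - 1)].dt for i in range(n)
                ) * self.dt_scale
                rho = min(max(cum_obs / cum_hyp, 0.5), 2.0) if cum_hyp > 0 else 1.0
                delta = self.observed.events[j].dt - rho * dt_hyp
                d_temporal[k] = -(delta * delta) / (2.0 * self.config.pi_s_temporal**2)
            # The empirical prior already carries all earlier events'
            # evidence, so the new evidence is the *incremental* joint
            # likelihood; reweighting by the full prefix likelihood
            # every step would compound each event many times over and
            # crush all but one hypothesis to the floor.
            prev = self._prev_liks if self._prev_liks is not None else 0.0
            logw = (log_joint - prev) + d_temporal
            self._prev_liks = log_joint
            logw = logw - logw.max()
            # the evidence accumulator telescopes exactly (its running
            # sum equals the joint log likelihood of the whole
            # observation), so it gets the raw ratios
            self._log_evidence = self._log_evidence + logw
            # the level state's bottom-up signal is clipped: a single
            # event may not carry it further than e^clip against any
            # hypothesis, keeping free energy off the probability
            # floor and the update loop well conditioned
            p_bu = prior.reweight(np.exp(np.maximum(logw, -self.config.evidence_clip)))
        else:
            p_bu = prior
        p_td = self.top_down_from_schemas(schema_posterior)
        self.state.mode = mode
        self.state = update_level(self.state, p_td=p_td, p_bu=p_bu)
        return self.upward_message()
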