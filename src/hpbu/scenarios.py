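"""Scenario runner: the closed perception/production loop.

Four simulation scenarios exercise the hierarchy:

* ``a`` — perceive a known digit: bottom-up evidence accumulates and
  free energy at the sequence level is minimized;
* ``b`` — perceive a digit excluded from training: no stored sequence
  explains the stream and free energy stays high;
* ``c`` — produce a digit with veridical visual feedback: the intended
  schema is enacted through motor control, its own pen trace feeds
  back through vision, and the sense of agency accumulates;
* ``d`` — produce one digit while vision is fed a replayed trajectory
  of a *different* known digit: proprioception is correct but visual
  confirmation fails, so free energy cannot be minimized and the
  agency estimate stays low.

The step clock is one hierarchy update per pen sample; within a step
levels update sequentially from the top (schema, then sequence), the
vision level having first turned the sample into a possible stroke
event.  During production, motor control integrates the spring plant
between samples and announces finished subgoals over the long-range
connection to vision, which forwards a stroke event to the sequence
level only when visual evidence confirms it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agency import AgencyTrace, update_soa
from .beliefs import DiscreteBelief, Mode
from .config import ModelConfig
from .motor import DoneSignal, SpringParams, SpringState, spring_step
from .repertoire import Repertoire, train
from .sequences import SequenceLevel
from .schemas import SchemaLevel
from .synth import NoiseLevels, digit_template, generate_digit
from .trajectory import Trajectory
from .vision import VisionLevel, event_endpoint

__all__ = ["ScenarioConfig", "TrialLog", "Hierarchy", "run_scenario", "summarize"]

logger = logging.getLogger(__name__)

#: scenario -> (perceived, produced, feedback) digit defaults
_SCENARIO_DIGITS = {
    "a": {"perceived_digit": 5},
    "b": {"perceived_digit": 4},
    "c": {"produced_digit": 9},
    "d": {"produced_digit": 1, "feedback_digit": 3},
}

_MAX_STEPS = 3000  # hard cap on trial length (30 s at 100 Hz)


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation trial's parameters."""

    scenario: str
    perceived_digit: int | None = None
    produced_digit: int | None = None
    feedback_digit: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in "abcd" or len(self.scenario) != 1:
            raise ValueError(f"scenario must be one of a, b, c, d: {self.scenario}")
        defaults = _SCENARIO_DIGITS[self.scenario]
        for key, value in defaults.items():
            if getattr(self, key) is None:
                object.__setattr__(self, key, value)
        if self.scenario in "ab" and self.perceived_digit is None:
            raise ValueError("perception scenarios need perceived_digit")
        if self.scenario in "cd" and self.produced_digit is None:
            raise ValueError("production scenarios need produced_digit")
        if self.scenario == "d":
            if self.feedback_digit is None:
                raise ValueError("scenario d needs feedback_digit")
            if self.feedback_digit == self.produced_digit:
                raise ValueError("scenario d requires feedback_digit != produced_digit")


@dataclass
class TrialLog:
    """Per-step record of one trial, aligned across levels."""

    scenario: str
    seed: int
    sequence_labels: tuple = ()
    schema_labels: tuple = ()
    t: list = field(default_factory=list)
    event_fired: list = field(default_factory=list)
    event_forwarded: list = field(default_factory=list)
    free_energy_vision: list = field(default_factory=list)
    free_energy_sequence: list = field(default_factory=list)
    free_energy_schema: list = field(default_factory=list)
    sequence_posterior: list = field(default_factory=list)
    schema_posterior: list = field(default_factory=list)
    soa: list = field(default_factory=list)         # NaN on non-update steps
    intended_sequence: list = field(default_factory=list)
    pen: list = field(default_factory=list)          # produced pen samples (x, y)
    agency: AgencyTrace = field(default_factory=AgencyTrace)
    #: agency estimate at trial end (production scenarios; equals the
    #: initial estimate when no update step ever fired)
    soa_final: float | None = None

    # -- derived summaries --------------------------------------------
    @property
    def n_steps(self) -> int:
        return len(self.t)

    @property
    def terminal_free_energy_sequence(self) -> float:
        return self.free_energy_sequence[-1]

    @property
    def final_soa(self) -> float | None:
        if self.soa_final is not None:
            return self.soa_final
        return self.agency.final if len(self.agency) else None

    @property
    def schema_argmax(self) -> str:
        probs = self.schema_posterior[-1]
        return self.schema_labels[int(np.argmax(probs))]

    @property
    def sequence_argmax(self) -> str:
        probs = self.sequence_posterior[-1]
        return self.sequence_labels[int(np.argmax(probs))]

    def to_frame(self) -> pd.DataFrame:
        seq = np.asarray(self.sequence_posterior)
        sch = np.asarray(self.schema_posterior)
        return pd.DataFrame(
            {
                "step": np.arange(self.n_steps),
                "t": self.t,
                "event_fired": np.asarray(self.event_fired, dtype=int),
                "event_forwarded": np.asarray(self.event_forwarded, dtype=int),
                "free_energy_vision": self.free_energy_vision,
                "free_energy_sequence": self.free_energy_sequence,
                "free_energy_schema": self.free_energy_schema,
                "sequence_max_p": seq.max(axis=1),
                "schema_max_p": sch.max(axis=1),
                "sequence_argmax": [self.sequence_labels[i] for i in seq.argmax(axis=1)],
                "schema_argmax": [self.schema_labels[i] for i in sch.argmax(axis=1)],
                "soa": self.soa,
                "intended_sequence": self.intended_sequence,
            }
        )

    def save(self, out_dir, plots: bool = True) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out_dir / "trial.csv", index=False)
        posteriors = {
            "scenario": self.scenario,
            "seed": self.seed,
            "soa_final": self.final_soa,
            "sequence_labels": list(self.sequence_labels),
            "schema_labels": list(self.schema_labels),
            "sequence_posterior": np.asarray(self.sequence_posterior).tolist(),
            "schema_posterior": np.asarray(self.schema_posterior).tolist(),
        }
        (out_dir / "posteriors.json").write_text(json.dumps(posteriors))
        self.agency.to_frame().to_csv(out_dir / "agency.csv", index=False)
        if self.pen:
            pen = np.asarray(self.pen)
            Trajectory(pen[:, 0], pen[:, 1:3]).to_frame().to_csv(
                out_dir / "produced.csv", index=False
            )
        if plots:
            from .plotting import plot_trial

            plot_trial(self, out_dir)
        return out_dir


class Hierarchy:
    """The assembled belief hierarchy over a trained repertoire."""

    def __init__(self, repertoire: Repertoire, config: ModelConfig | None = None):
        self.repertoire = repertoire
        self.config = config or repertoire.config
        self.vision = VisionLevel(self.config.vision, sample_rate=self.config.sample_rate)
        self.sequence = SequenceLevel(repertoire.sequences, self.config.sequence)
        self.schema = SchemaLevel(repertoire.schemas, self.config.schema)
        self.mode = Mode.PERCEPTION
        self._upward = DiscreteBelief.uniform(self.schema.labels)

    def step(self, t: float, pos, forwarded_event=None, raw: bool = True):
        """One hierarchy update for one pen sample.

        In perception (``raw=True``) the vision level segments the
        sample itself and any fired event is the sequence-level
        evidence.  In production the caller passes the event forwarded
        by the confirmation gate instead (``raw`` still feeds the
        sample to vision for segmentation).
        """
        fired = None
        if pos is not None:
            fired = self.vision.step(t, pos)
        event = fired if (self.mode is Mode.PERCEPTION and raw) else forwarded_event
        schema_posterior = self.schema.step(self._upward, self.mode)
        self._upward = self.sequence.step(schema_posterior, event, self.mode)
        return fired, event

    def finish_trial(self, tail_event=None, settle_steps: int = 25):
        """Close a trial: process the tail stroke and let beliefs settle.

        Because levels update top-first, the schema level lags the
        sequence level by one event; and when the final stroke is the
        decisive one, a single further update cannot move a
        momentum-laden schema posterior.  After the tail stroke is
        processed the hierarchy keeps ticking for a short while on the
        now-static scene (the pen at rest provides samples but no new
        events), which contracts the schema posterior onto the
        accumulated evidence.
        """
        if tail_event is None:
            tail_event = self.vision.finish()
        if tail_event is not None:
            schema_posterior = self.schema.step(self._upward, self.mode)
            self._upward = self.sequence.step(schema_posterior, tail_event, self.mode)
        # the pen lift closes the sequence: penalize unobserved tails
        schema_posterior = self.schema.step(self._upward, self.mode)
        self._upward = self.sequence.completion_update(schema_posterior, self.mode)
        for _ in range(settle_steps):
            self.schema.step(self._upward, self.mode)
        return tail_event


def _holdout_exemplar(digit: int, seed: int, config: ModelConfig) -> Trajectory:
    """A fresh exemplar for perception/feedback, outside the training set."""
    template = digit_template(digit, config.sample_rate)
    child = (7919 * (seed + 1) + 131 * digit + 17) % (2**31 - 1)
    return generate_digit(template, child, NoiseLevels())


def _log_step(
    log: TrialLog, t, hierarchy: Hierarchy, fired, forwarded, soa_value, s_i
) -> None:
    log.t.append(t)
    log.event_fired.append(fired is not None)
    log.event_forwarded.append(forwarded is not None)
    log.free_energy_vision.append(hierarchy.vision.state.free_energy)
    log.free_energy_sequence.append(hierarchy.sequence.state.free_energy)
    log.free_energy_schema.append(hierarchy.schema.state.free_energy)
    log.sequence_posterior.append(hierarchy.sequence.state.posterior.probs.copy())
    log.schema_posterior.append(hierarchy.schema.state.posterior.probs.copy())
    log.soa.append(soa_value if soa_value is not None else float("nan"))
    log.intended_sequence.append(s_i or "")


def run_scenario(config: ScenarioConfig, repertoire: Repertoire) -> TrialLog:
    if config.scenario in "ab":
        return _run_perception(config, repertoire)
    return _run_production(config, repertoire)


def _run_perception(config: ScenarioConfig, repertoire: Repertoire) -> TrialLog:
    model_cfg = repertoire.config
    hierarchy = Hierarchy(repertoire)
    traj = _holdout_exemplar(config.perceived_digit, config.seed, model_cfg)
    log = TrialLog(
        scenario=config.scenario,
        seed=config.seed,
        sequence_labels=hierarchy.sequence.labels,
        schema_labels=hierarchy.schema.labels,
    )
    for t, pos in zip(traj.t, traj.xy):
        fired, event = hierarchy.step(float(t), pos)
        _log_step(log, float(t), hierarchy, fired, event, None, None)
    # the pen lifting closes the final stroke
    tail = hierarchy.finish_trial()
    _log_step(log, float(traj.t[-1]), hierarchy, tail, tail, None, None)
    return log


@dataclass
class _GoalChain:
    """Subdivided, time-stamped production subgoals for one sequence.

    The stroke chords of the enacted sequence are split into waypoints
    at most ``goal_spacing`` apart so the three-goal lookahead stays
    local, each waypoint carrying its share of the stroke's (stretched)
    timing goal.  The motor advances the buffer on that clock; a done
    notification is announced whenever the waypoint closing a true
    stroke is passed.
    """

    waypoints: list
    times: list
    stroke_end: list   # index of the original stroke this waypoint ends, or None
    stroke_lengths: list

    @classmethod
    def build(cls, events, start, model_cfg, t0: float = 0.0) -> "_GoalChain":
        motor_cfg = model_cfg.motor
        pos = np.asarray(start, dtype=float)
        goals = []
        for ev in events:
            pos = event_endpoint(pos, ev)
            goals.append(pos)
        dts = [ev.dt * motor_cfg.time_stretch for ev in events]
        if dts[0] == 0.0:
            # the first event's stored delay is 0 by convention; pace
            # its stroke at the sequence's own average writing speed
            total_l = sum(ev.length for ev in events[1:])
            total_t = sum(dts[1:])
            speed = total_l / total_t if total_t > 0 else 1.0
            dts[0] = events[0].length / max(speed, 1e-9) if events[0].length else 0.05
        waypoints, times, stroke_end = [], [], []
        pos = np.asarray(start, dtype=float)
        t = t0
        for k, (g, dt) in enumerate(zip(goals, dts)):
            d = np.asarray(g) - pos
            n = max(1, int(np.ceil(np.hypot(*d) / motor_cfg.goal_spacing)))
            for j in range(1, n + 1):
                waypoints.append(pos + d * j / n)
                times.append(t + dt * j / n)
                stroke_end.append(k if j == n else None)
            pos = np.asarray(g, dtype=float)
            t += dt
        # terminal hold: let the pen converge onto the final subgoal
        waypoints.append(waypoints[-1].copy())
        times.append(t + 0.3)
        stroke_end.append(None)
        return cls(
            waypoints=waypoints,
            times=times,
            stroke_end=stroke_end,
            stroke_lengths=[ev.length for ev in events],
        )


def _run_production(config: ScenarioConfig, repertoire: Repertoire) -> TrialLog:
    model_cfg = repertoire.config
    hierarchy = Hierarchy(repertoire)
    hierarchy.mode = Mode.PRODUCTION

    schema_id = repertoire.schema_of_digit(config.produced_digit)
    # the model paces its own writing slower than the demonstration;
    # its timing predictions are scaled accordingly
    hierarchy.sequence.dt_scale = model_cfg.motor.time_stretch
    intention = hierarchy.schema.set_intention(schema_id, hierarchy.sequence.state.posterior)
    s_i = intention.intended_sequence
    seq = hierarchy.sequence.by_id[s_i]

    params = SpringParams(
        alpha=model_cfg.motor.alpha,
        beta=model_cfg.motor.beta,
        gamma=model_cfg.motor.gamma,
        mu=model_cfg.motor.mu,
        dt_int=model_cfg.motor.dt_int,
        sample_rate=model_cfg.sample_rate,
        phi_from_bearing=model_cfg.motor.phi_from_bearing,
    )
    start = np.zeros(2)
    chain = _GoalChain.build(seq.events, start, model_cfg)
    motor = SpringState(y=start, y_dot=np.zeros(2), goals=list(chain.waypoints))
    goal_idx = 0
    strokes_done = 0   # completed true strokes, across chain rebuilds
    stroke_base = 0    # strokes completed before the current chain
    last_subgoal_pos = start.copy()

    feedback = None
    if config.scenario == "d":
        feedback = _holdout_exemplar(config.feedback_digit, config.seed, model_cfg)

    log = TrialLog(
        scenario=config.scenario,
        seed=config.seed,
        sequence_labels=hierarchy.sequence.labels,
        schema_labels=hierarchy.schema.labels,
    )
    soa = model_cfg.soa_init
    pending: list[tuple[DoneSignal, float]] = []  # (signal, stroke length)
    sample_period = 1.0 / model_cfg.sample_rate
    substeps = max(1, round(sample_period / params.dt_int))
    tau = model_cfg.vision.tau_confirm_periods * sample_period

    step = 0
    while motor.goals and step < _MAX_STEPS:
        # ---- motor: integrate one sample period; the goal buffer ----
        # ---- advances on the sequence's (stretched) timing goals ----
        for _ in range(substeps):
            if not motor.goals:
                break
            spring_step(motor, params)
            while motor.goals and motor.t >= chain.times[goal_idx]:
                stroke = chain.stroke_end[goal_idx]
                if stroke is not None:
                    stroke_len = chain.stroke_lengths[min(stroke, len(chain.stroke_lengths) - 1)]
                    dist = float(np.hypot(*(motor.current_goal - motor.y)))
                    done = DoneSignal(
                        subgoal=motor.current_goal.copy(),
                        time=motor.t,
                        reached=dist <= model_cfg.vision.r_confirm_frac * max(stroke_len, 1e-9),
                    )
                    is_final = stroke_base + stroke + 1 >= len(seq.events)
                    pending.append((done, stroke_len, is_final))
                    last_subgoal_pos = motor.current_goal.copy()
                    strokes_done = stroke_base + stroke + 1
                motor.goals.pop(0)
                goal_idx += 1
                if goal_idx >= len(chain.times):
                    motor.goals = []
                    break
        t = motor.t
        log.pen.append((t, motor.y[0], motor.y[1]))

        # ---- visual input: own pen (c) or the replayed digit (d) ----
        if config.scenario == "c":
            vis_sample = motor.y
        else:
            vis_sample = feedback.xy[step] if step < len(feedback) else None
        fired = hierarchy.vision.step(t, vis_sample) if vis_sample is not None else None

        # ---- confirmation gate on the long-range done signals ----
        forwarded = None
        miss = False
        still_pending = []
        for done, stroke_len, is_final in pending:
            conf = hierarchy.vision.confirm_motor_done(done, stroke_len)
            if conf is not None and forwarded is None:
                forwarded = conf
            elif t <= done.time + tau or is_final:
                # the last stroke's event can only fire once the pen
                # stops, so its notification stays live to trial end
                still_pending.append((done, stroke_len, is_final))
            else:
                # the announced subgoal found no visual confirmation in
                # time: unexplained prediction error
                miss = True
        pending = still_pending

        # ---- belief updates, top first ----
        schema_posterior = hierarchy.schema.step(hierarchy._upward, Mode.PRODUCTION)
        hierarchy._upward = hierarchy.sequence.step(
            schema_posterior, forwarded, Mode.PRODUCTION, miss=miss
        )

        # ---- agency update on sequence-level evidence steps ----
        soa_value = None
        if forwarded is not None:
            likelihood = hierarchy.sequence.likelihood_of(s_i)
            f_s = hierarchy.sequence.state.free_energy
            soa = update_soa(soa, likelihood, f_s, model_cfg.sequence.precision)
            log.agency.values.append(soa)
            log.agency.gains.append(hierarchy.sequence.state.gain)
            log.agency.likelihoods.append(likelihood)
            soa_value = soa

        # ---- within-schema switch of the enacted sequence ----
        switched = hierarchy.schema.maybe_switch_intended(
            hierarchy.sequence.state.posterior, hierarchy.sequence.schema_of
        )
        if switched is not None and switched != s_i:
            s_i = switched
            seq = hierarchy.sequence.by_id[s_i]
            remaining = seq.events[strokes_done:]
            if remaining:
                # re-anchor the new sequence's remaining subgoals at
                # the last announced subgoal position
                chain = _GoalChain.build(remaining, last_subgoal_pos, model_cfg, t0=motor.t)
                motor.goals = list(chain.waypoints)
                goal_idx = 0
                stroke_base = strokes_done
            else:
                motor.goals = []

        _log_step(log, t, hierarchy, fired, forwarded, soa_value, s_i)
        step += 1

    # pen lifts: the final stroke's event fires only once motion stops,
    # so close the visual stream and give the last done signals a
    # confirmation window covering the terminal hold
    tail = hierarchy.vision.finish()
    forwarded = None
    if tail is not None and pending:
        latest = hierarchy.vision.events[-1]
        for done, stroke_len, _ in pending:
            radius = max(
                model_cfg.vision.r_confirm_frac * max(stroke_len, 1e-9),
                model_cfg.vision.r_confirm_min,
            )
            if float(np.hypot(*(latest.pos - done.subgoal))) <= radius:
                # the tail event has no sharp intrinsic time (it fires
                # when the pen stops); bind it to the announced
                # completion time of the stroke it confirms
                forwarded = hierarchy.vision._forward(latest, t_event=done.time)
                break
    if tail is not None:
        schema_posterior = hierarchy.schema.step(hierarchy._upward, Mode.PRODUCTION)
        hierarchy._upward = hierarchy.sequence.step(schema_posterior, forwarded, Mode.PRODUCTION)
        hierarchy.schema.step(hierarchy._upward, Mode.PRODUCTION)
        soa_value = None
        if forwarded is not None:
            likelihood = hierarchy.sequence.likelihood_of(s_i)
            f_s = hierarchy.sequence.state.free_energy
            soa = update_soa(soa, likelihood, f_s, model_cfg.sequence.precision)
            log.agency.values.append(soa)
            log.agency.gains.append(hierarchy.sequence.state.gain)
            log.agency.likelihoods.append(likelihood)
            soa_value = soa
        _log_step(log, motor.t, hierarchy, tail, forwarded, soa_value, s_i)

    # end of sequence: the intention gate closes
    hierarchy.schema.clear_intention()
    log.soa_final = soa
    return log


def summarize(logs: list) -> pd.DataFrame:
    """Per-trial terminal summary table."""
    rows = []
    for log in logs:
        rows.append(
            {
                "scenario": log.scenario,
                "seed": log.seed,
                "n_steps": log.n_steps,
                "n_events": int(np.sum(log.event_fired)),
                "n_forwarded": int(np.sum(log.event_forwarded)),
                "terminal_free_energy_sequence": log.terminal_free_energy_sequence,
                "terminal_free_energy_schema": log.free_energy_schema[-1],
                "schema_argmax": log.schema_argmax,
                "sequence_argmax": log.sequence_argmax,
                "final_soa": log.final_soa,
                "peak_soa": max(log.agency.values) if len(log.agency) else None,
            }
        )
    return pd.DataFrame(rows)
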