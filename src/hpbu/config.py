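"""Model configuration.

Every tunable constant of the hierarchy is surfaced here and can be
overridden from a YAML or JSON mapping; nothing is hard-coded at use
sites.  Defaults are documented with units where they have any.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["VisionConfig", "SequenceConfig", "SchemaConfig", "MotorConfig", "ModelConfig"]


@dataclass(frozen=True)
class VisionConfig:
    #: number of discrete writing-angle bins on [0, 2pi)
    n_angle: int = 16
    #: von-Mises concentration of the angle kernel; at 8.0 roughly 90%
    #: of the mass of a displacement's belief falls in the true bin and
    #: its two neighbours
    kappa_angle: float = 8.0
    #: surprise threshold (nats) above which a stroke event is emitted
    surprise_threshold: float = 2.5
    #: decay of the exponentially discounted angle-history predictor
    #: (discounted by age since the last event, anchoring the
    #: prediction at the segment start)
    history_decay: float = 0.8
    #: samples of history required before any event can fire
    n_burn: int = 3
    #: minimum stroke length (canvas units) for an event to be
    #: emitted; shorter firings (near-stationary wiggles at corners)
    #: only restart the predictor and the stroke keeps growing
    min_event_length: float = 0.05
    #: level precision pi entering the Kalman gain
    precision: float = 1.0
    #: production-mode confirmation window around a motor done signal,
    #: in sampling periods; covers the segmentation lag of the
    #: surprise detector (an event fires only once the heading has
    #: rotated clearly past a stroke boundary)
    tau_confirm_periods: float = 12.0
    #: confirmation radius as a fraction of the subgoal stroke length
    r_confirm_frac: float = 0.6
    #: absolute floor on the confirmation radius (canvas units), so
    #: very short strokes remain confirmable at all
    r_confirm_min: float = 0.08


@dataclass(frozen=True)
class SequenceConfig:
    #: level precision pi entering the Kalman gain (also gates the
    #: agency filter, which consumes sequence-level quantities)
    precision: float = 1.0
    #: temporal-binding precision pi_S (seconds): width of the Gaussian
    #: likelihood on the observed-vs-stored delay of the latest event
    pi_s_temporal: float = 0.15
    #: angular kernel width of the sequence comparison, radians
    #: (one angle-bin width by default, set in ModelConfig.__post_init__)
    sigma_angle: float = 2.0 * np.pi / 16
    #: length kernel width as a fraction of the stored event length
    sigma_length_frac: float = 0.25
    #: per-extra-event penalty rate when the observation overruns a
    #: shorter stored sequence
    overrun_rate: float = 1.0
    #: cap (nats) on how strongly one event's evidence may count
    #: against any hypothesis in the level update
    evidence_clip: float = 10.0
    #: weight of the previous posterior when re-priming priors at trial
    #: reset (blended with uniform)
    reset_carryover: float = 0.5


@dataclass(frozen=True)
class SchemaConfig:
    precision: float = 2.0
    #: multiplicative intention boost applied every step while active
    boost: float = 3.0
    #: single-linkage cut: similarities below this start a new schema
    link_threshold: float = 0.6
    #: during production, switch the enacted sequence to a same-schema
    #: member whose posterior exceeds the current one by this factor
    switch_factor: float = 2.0


@dataclass(frozen=True)
class MotorConfig:
    alpha: float = 25.0
    beta: float = 6.25
    gamma: float = 10.0
    mu: float = 1.0 / np.pi
    dt_int: float = 0.001          # s
    phi_from_bearing: bool = True
    #: arrival tolerance as a fraction of the subgoal stroke length
    tolerance_frac: float = 0.05
    #: per-subgoal integration timeout, seconds
    timeout: float = 2.0
    #: production subgoal chains are subdivided so consecutive
    #: waypoints are at most this far apart (canvas units); keeps the
    #: three-goal lookahead local to the stroke being drawn
    goal_spacing: float = 0.05
    #: production is paced slower than the demonstration by this
    #: factor (careful writing); reduces the spring's pursuit lag
    time_stretch: float = 1.3


@dataclass(frozen=True)
class ModelConfig:
    """Full hierarchy configuration."""

    prob_floor: float = 1e-10
    sample_rate: float = 100.0     # Hz, pen trajectory sampling
    #: initial agency estimate
    soa_init: float = 0.0
    vision: VisionConfig = field(default_factory=VisionConfig)
    sequence: SequenceConfig = field(default_factory=SequenceConfig)
    schema: SchemaConfig = field(default_factory=SchemaConfig)
    motor: MotorConfig = field(default_factory=MotorConfig)

    def __post_init__(self):
        # keep the comparison kernel tied to the angular resolution
        # unless explicitly overridden
        if self.sequence.sigma_angle is None:
            object.__setattr__(
                self,
                "sequence",
                dataclasses.replace(
                    self.sequence, sigma_angle=2.0 * np.pi / self.vision.n_angle
                ),
            )

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        data = dict(data)
        kwargs = {}
        for name, sub_cls in (
            ("vision", VisionConfig),
            ("sequence", SequenceConfig),
            ("schema", SchemaConfig),
            ("motor", MotorConfig),
        ):
            if name in data:
                kwargs[name] = sub_cls(**data.pop(name))
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def load(cls, path) -> "ModelConfig":
        """Load from a YAML (or JSON) mapping file."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def save(self, path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
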