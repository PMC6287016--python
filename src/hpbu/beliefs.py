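"""Discrete beliefs, free energy, and the precision-weighted belief update.

Every level of the hierarchy represents its hypotheses as a discrete
probability distribution over a finite labelled set.  Perception and
production share one update rule: the level free energy

    F = H(P) + D_KL(P || Q) = -sum_i P_i ln Q_i

(the cross-entropy of the driving signal Q under the posterior-role
signal P) sets a Kalman gain K = F / (F + pi), and the new level
posterior is a convex combination of the bottom-up and top-down
signals.  In perception the bottom-up signal drives the update and the
top-down prediction plays the posterior role; production inverts the
two.  High free energy (large prediction error) therefore shifts weight
toward the non-driving signal, while the level precision ``pi`` damps
that shift.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DEFAULT_PROB_FLOOR",
    "DiscreteBelief",
    "Mode",
    "LevelState",
    "free_energy",
    "kalman_gain",
    "update_level",
]

#: Probability floor applied before any logarithm; keeps surprise finite
#: on hypotheses that have never been observed.
DEFAULT_PROB_FLOOR = 1e-10


class BeliefError(ValueError):
    """Contract violation on belief operations (label mismatch etc.)."""


class Mode(enum.Enum):
    """Which signal drives a level update."""

    PERCEPTION = "perception"
    PRODUCTION = "production"


@dataclass(frozen=True)
class DiscreteBelief:
    """A normalized probability distribution over labelled hypotheses.

    Parameters
    ----------
    labels
        Ordered, unique hypothesis identifiers.
    probs
        One probability per label.  Values are floored at ``floor`` and
        renormalized on construction, so a belief never assigns exactly
        zero mass to any hypothesis.
    """

    labels: tuple
    probs: np.ndarray
    floor: float = DEFAULT_PROB_FLOOR

    def __post_init__(self):
        labels = tuple(self.labels)
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 1 or len(labels) != probs.size:
            raise BeliefError("labels and probs must be 1-d and the same length")
        if len(set(labels)) != len(labels):
            raise BeliefError("labels must be unique")
        if probs.size == 0:
            raise BeliefError("belief needs at least one hypothesis")
        if np.any(~np.isfinite(probs)) or np.any(probs < 0):
            raise BeliefError("probs must be finite and non-negative")
        total = probs.sum()
        if total <= 0:
            raise BeliefError("probs must have positive mass")
        probs = probs / total
        probs = np.maximum(probs, self.floor)
        probs = probs / probs.sum()
        probs.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "probs", probs)

    @classmethod
    def uniform(cls, labels, floor: float = DEFAULT_PROB_FLOOR) -> "DiscreteBelief":
        labels = tuple(labels)
        return cls(labels, np.full(len(labels), 1.0 / len(labels)), floor)

    @classmethod
    def from_weights(cls, labels, weights, floor: float = DEFAULT_PROB_FLOOR) -> "DiscreteBelief":
        """Normalize non-negative weights into a belief.

        All-zero weights degrade to the uniform distribution (no
        evidence discriminates the hypotheses).
        """
        weights = np.asarray(weights, dtype=float)
        if np.all(weights <= 0):
            return cls.uniform(labels, floor)
        return cls(labels, weights, floor)

    def __len__(self) -> int:
        return len(self.labels)

    def prob_of(self, label) -> float:
        return float(self.probs[self.labels.index(label)])

    @property
    def argmax_label(self):
        return self.labels[int(np.argmax(self.probs))]

    def entropy(self) -> float:
        """Shannon entropy in nats."""
        return float(-np.sum(self.probs * np.log(self.probs)))

    def kl_to(self, other: "DiscreteBelief") -> float:
        """D_KL(self || other) in nats."""
        _check_same_labels(self, other)
        return float(np.sum(self.probs * (np.log(self.probs) - np.log(other.probs))))

    def blend(self, other: "DiscreteBelief", weight: float) -> "DiscreteBelief":
        """Convex combination ``self + weight * (other - self)``."""
        _check_same_labels(self, other)
        mixed = self.probs + weight * (other.probs - self.probs)
        return DiscreteBelief(self.labels, mixed, self.floor)

    def reweight(self, weights) -> "DiscreteBelief":
        """Multiply by non-negative weights and renormalize (Bayes step)."""
        weights = np.asarray(weights, dtype=float)
        return DiscreteBelief.from_weights(self.labels, self.probs * weights, self.floor)


def _check_same_labels(a: DiscreteBelief, b: DiscreteBelief) -> None:
    if a.labels != b.labels:
        raise BeliefError("beliefs are over different hypothesis sets")


def free_energy(posterior: DiscreteBelief, prior: DiscreteBelief) -> float:
    """Level free energy F = H(P) + D_KL(P || Q), in nats.

    Algebraically this collapses to the cross-entropy -sum_i P_i ln Q_i,
    so F >= H(P) >= 0 with equality to H(P) iff P == Q.
    """
    _check_same_labels(posterior, prior)
    return float(-np.sum(posterior.probs * np.log(prior.probs)))


def kalman_gain(free_energy_value: float, precision: float) -> float:
    """Gain K = F / (F + pi), in [0, 1).

    Monotone increasing in the free energy, decreasing in the precision:
    a confident level (large pi) resists being pulled off its driving
    signal even under large prediction error.
    """
    if precision <= 0:
        raise ValueError(f"precision must be positive, got {precision}")
    if free_energy_value < 0:
        raise ValueError(f"free energy must be non-negative, got {free_energy_value}")
    return free_energy_value / (free_energy_value + precision)


@dataclass
class LevelState:
    """Per-level belief state threaded through successive update steps."""

    posterior: DiscreteBelief
    precision: float
    mode: Mode = Mode.PERCEPTION
    free_energy: float = 0.0
    gain: float = 0.0
    prior: DiscreteBelief = None  # previous-step posterior (empirical prior)

    def __post_init__(self):
        if self.precision <= 0:
            raise ValueError("level precision must be positive")
        if self.prior is None:
            self.prior = self.posterior


def update_level(state: LevelState, p_td: DiscreteBelief, p_bu: DiscreteBelief) -> LevelState:
    """One precision-weighted belief update of a hierarchy level.

    In perception the bottom-up signal drives: F is the cross-entropy of
    p_bu under p_td and the posterior is ``p_bu + K (p_td - p_bu)``.  In
    production the roles invert.  The result's posterior is stored as
    the next step's empirical prior.
    """
    _check_same_labels(p_td, p_bu)
    if state.mode is Mode.PERCEPTION:
        f = free_energy(p_td, p_bu)
        k = kalman_gain(f, state.precision)
        posterior = p_bu.blend(p_td, k)
    else:
        f = free_energy(p_bu, p_td)
        k = kalman_gain(f, state.precision)
        posterior = p_td.blend(p_bu, k)
    return replace(
        state,
        prior=state.posterior,
        posterior=posterior,
        free_energy=f,
        gain=k,
    )
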