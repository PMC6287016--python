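"""Schema level: clusters of similar sequences and the intention gate.

Schemas partition the sequence repertoire by full-sequence similarity
(single-linkage agglomerative clustering on 1 - iota, cut at a
configurable link threshold).  The level maintains a posterior over
schemas, sends its posterior down as a prediction over member
sequences, and hosts the intention gating signal: production only
starts when a schema is explicitly intended, which applies a
maintained multiplicative boost to that schema's probability on every
update step and selects a member sequence for enactment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .beliefs import DiscreteBelief, LevelState, Mode, update_level
from .config import SchemaConfig, SequenceConfig
from .sequences import ObservedSequence, SequenceHypothesis, compare_sequences

__all__ = ["SchemaHypothesis", "IntentionState", "pairwise_iota", "build_schemas", "SchemaLevel"]


@dataclass(frozen=True)
class SchemaHypothesis:
    id: str
    member_sequence_ids: tuple

    def __post_init__(self):
        members = tuple(self.member_sequence_ids)
        if not members:
            raise ValueError("a schema needs at least one member sequence")
        object.__setattr__(self, "member_sequence_ids", members)


@dataclass
class IntentionState:
    """The gating signal that licenses production of one schema."""

    target_schema: str | None = None
    boost: float = 3.0
    active: bool = False
    intended_sequence: str | None = None  # s_I


def _full_iota(a: SequenceHypothesis, b: SequenceHypothesis, config: SequenceConfig) -> float:
    """Symmetrized full-sequence similarity (iota is prefix-anchored)."""
    obs_a = ObservedSequence(list(a.events))
    obs_b = ObservedSequence(list(b.events))
    return 0.5 * (
        compare_sequences(obs_a, b, config, full=True)
        + compare_sequences(obs_b, a, config, full=True)
    )


def pairwise_iota(sequences: list, config: SequenceConfig = SequenceConfig()) -> np.ndarray:
    """Symmetric matrix of full-sequence similarities."""
    n = len(sequences)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = _full_iota(sequences[i], sequences[j], config)
    return sim


def build_schemas(
    sequences: list,
    link_threshold: float = 0.6,
    config: SequenceConfig = SequenceConfig(),
) -> list:
    """Cluster sequences into schemas by single linkage on 1 - iota.

    Links with similarity below ``link_threshold`` are cut.  The result
    is deterministic for a given input order; schemas are numbered by
    the lowest member sequence id.  Returns new
    :class:`SequenceHypothesis` objects with ``schema_id`` assigned,
    plus the schema list: ``(sequences, schemas)``.
    """
    if not sequences:
        raise ValueError("cannot build schemas from an empty repertoire")
    n = len(sequences)
    if n == 1:
        flat = np.array([1])
    else:
        sim = pairwise_iota(sequences, config)
        dist = squareform(1.0 - sim, checks=False)
        z = linkage(dist, method="single")
        flat = fcluster(z, t=1.0 - link_threshold, criterion="distance")

    # deterministic schema ids: order clusters by their lowest member id
    clusters: dict = {}
    for seq, c in zip(sequences, flat):
        clusters.setdefault(c, []).append(seq)
    ordered = sorted(clusters.values(), key=lambda seqs: min(s.id for s in seqs))
    out_sequences, schemas = [], []
    for k, members in enumerate(ordered):
        schema_id = f"schema_{k:02d}"
        member_ids = tuple(sorted(s.id for s in members))
        schemas.append(SchemaHypothesis(id=schema_id, member_sequence_ids=member_ids))
        for s in members:
            out_sequences.append(replace(s, schema_id=schema_id))
    out_sequences.sort(key=lambda s: s.id)
    return out_sequences, schemas


class SchemaLevel:
    """Stateful top level of the hierarchy."""

    def __init__(self, schemas: list, config: SchemaConfig = SchemaConfig()):
        if not schemas:
            raise ValueError("schema level needs at least one schema")
        self.schemas = list(schemas)
        self.config = config
        self.by_id = {s.id: s for s in self.schemas}
        self.labels = tuple(sorted(s.id for s in self.schemas))
        self.state = LevelState(
            posterior=DiscreteBelief.uniform(self.labels), precision=config.precision
        )
        self.intention = IntentionState(boost=config.boost)

    def reset_trial(self, carryover: float = 0.5) -> None:
        uniform = DiscreteBelief.uniform(self.labels)
        self.state = LevelState(
            posterior=self.state.posterior.blend(uniform, 1.0 - carryover),
            precision=self.config.precision,
        )

    # -- intention gate ------------------------------------------------
    def set_intention(self, schema_id: str, sequence_posterior: DiscreteBelief) -> IntentionState:
        """Mark a schema for production and pick the enacted sequence s_I.

        s_I is the member with the highest current sequence posterior,
        ties broken by lowest id.  The hierarchy mode switches to
        production at the caller.
        """
        if schema_id not in self.by_id:
            raise KeyError(f"unknown schema: {schema_id}")
        members = self.by_id[schema_id].member_sequence_ids
        best_p = max(sequence_posterior.prob_of(sid) for sid in members)
        candidates = sorted(sid for sid in members if sequence_posterior.prob_of(sid) >= best_p - 1e-15)
        self.intention = IntentionState(
            target_schema=schema_id,
            boost=self.config.boost,
            active=True,
            intended_sequence=candidates[0],
        )
        return self.intention

    def clear_intention(self) -> None:
        self.intention = IntentionState(boost=self.config.boost)

    def maybe_switch_intended(self, sequence_posterior: DiscreteBelief, schema_of: dict) -> str | None:
        """Within-schema switch of s_I when another member dominates.

        If a member of the intended schema holds more than
        ``switch_factor`` times the posterior of the current s_I, the
        enacted sequence switches to it (ties to lowest id).  Returns
        the new s_I or None if unchanged.
        """
        if not self.intention.active or self.intention.intended_sequence is None:
            return None
        current = self.intention.intended_sequence
        p_cur = sequence_posterior.prob_of(current)
        members = [
            sid
            for sid in self.by_id[self.intention.target_schema].member_sequence_ids
            if sid != current
        ]
        threshold = self.config.switch_factor * p_cur
        better = sorted(
            (sid for sid in members if sequence_posterior.prob_of(sid) > threshold),
            key=lambda sid: (-sequence_posterior.prob_of(sid), sid),
        )
        if better:
            self.intention.intended_sequence = better[0]
            return better[0]
        return None

    # -- main update ---------------------------------------------------
    def step(self, upward: DiscreteBelief, mode: Mode) -> DiscreteBelief:
        """One level update from the sequence level's upward message.

        The top-down signal is the level's own empirical prior; while
        an intention is active the target schema's probability is
        multiplied by the boost and renormalized (a maintained boost,
        applied every step).  Returns the new posterior.
        """
        p_td = self.state.posterior
        if self.intention.active and self.intention.target_schema is not None:
            weights = np.ones(len(self.labels))
            weights[self.labels.index(self.intention.target_schema)] = self.intention.boost
            p_td = p_td.reweight(weights)
        self.state.mode = mode
        self.state = update_level(self.state, p_td=p_td, p_bu=upward)
        return self.state.posterior
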