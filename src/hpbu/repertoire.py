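"""Repertoire: the trained store of sequences and schemas.

Training segments every corpus trajectory into a stroke-event sequence
through the vision level, stores it as a sequence hypothesis, and
clusters the hypotheses into schemas.  Online learning of new
representations during simulation is deliberately absent: the
repertoire is fixed once trained, and sustained high free energy is
the diagnostic that the repertoire lacks an explanation.

Persistence is a versioned JSON file holding every event triple, the
schema memberships, and the configuration used at training time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from .config import ModelConfig
from .schemas import SchemaHypothesis, build_schemas
from .sequences import SequenceHypothesis
from .vision import SurpriseEvent, VisionLevel

__all__ = ["Repertoire", "train"]

logger = logging.getLogger(__name__)

FORMAT_TAG = "hpbu-repertoire-1"


@dataclass
class Repertoire:
    sequences: list
    schemas: list
    config: ModelConfig

    def __post_init__(self):
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in repertoire")
        member_union = []
        for c in self.schemas:
            member_union.extend(c.member_sequence_ids)
        if sorted(member_union) != sorted(ids):
            raise ValueError("schemas must partition the sequence repertoire")

    def schema_of_digit(self, digit: int) -> str:
        """Schema whose members mostly carry this source digit.

        Evaluation convenience: with a well-separated corpus each digit
        maps onto one schema.
        """
        by_id = {s.id: s for s in self.sequences}
        best, best_count = None, -1
        for c in sorted(self.schemas, key=lambda c: c.id):
            count = sum(1 for sid in c.member_sequence_ids if by_id[sid].source_digit == digit)
            if count > best_count:
                best, best_count = c.id, count
        if best_count <= 0:
            raise KeyError(f"no schema contains sequences of digit {digit}")
        return best

    def sequences_of_digit(self, digit: int) -> list:
        return [s for s in self.sequences if s.source_digit == digit]

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        data = {
            "format": FORMAT_TAG,
            "config": self.config.to_dict(),
            "sequences": [
                {
                    "id": s.id,
                    "schema_id": s.schema_id,
                    "source_digit": s.source_digit,
                    "events": [[e.angle, e.length, e.dt] for e in s.events],
                }
                for s in self.sequences
            ],
            "schemas": [
                {"id": c.id, "members": list(c.member_sequence_ids)} for c in self.schemas
            ],
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def load(cls, path) -> "Repertoire":
        data = json.loads(Path(path).read_text())
        if data.get("format") != FORMAT_TAG:
            raise ValueError(f"unrecognised repertoire format: {data.get('format')}")
        config = ModelConfig.from_dict(data["config"])
        sequences = [
            SequenceHypothesis(
                id=s["id"],
                events=tuple(SurpriseEvent(a, l, dt) for a, l, dt in s["events"]),
                schema_id=s["schema_id"],
                source_digit=s["source_digit"],
            )
            for s in data["sequences"]
        ]
        schemas = [
            SchemaHypothesis(id=c["id"], member_sequence_ids=tuple(c["members"]))
            for c in data["schemas"]
        ]
        return cls(sequences=sequences, schemas=schemas, config=config)


def train(corpus, config: ModelConfig = ModelConfig()) -> Repertoire:
    """Segment a corpus and cluster it into a repertoire.

    Trajectories yielding fewer than two stroke events cannot form a
    sequence hypothesis and are skipped with a warning.
    """
    if len(corpus) == 0:
        raise ValueError("cannot train on an empty corpus")
    vision = VisionLevel(config.vision, sample_rate=config.sample_rate)
    counters: dict = {}
    sequences = []
    for digit, seed, traj in corpus.trajectories():
        events = vision.segment(traj)
        k = counters.get(digit, 0)
        counters[digit] = k + 1
        if len(events) < 2:
            logger.warning(
                "skipping digit %s exemplar %d: only %d stroke events", digit, k, len(events)
            )
            continue
        sequences.append(
            SequenceHypothesis(
                id=f"seq_d{digit}_{k:02d}",
                events=tuple(events),
                source_digit=digit,
            )
        )
    if not sequences:
        raise ValueError("no trajectory produced enough stroke events to train on")
    sequences, schemas = build_schemas(
        sequences, link_threshold=config.schema.link_threshold, config=config.sequence
    )
    return Repertoire(sequences=sequences, schemas=schemas, config=config)
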