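"""Write a digit through the motor hierarchy and perceive the result.

Setting an intention on the digit-9 schema switches the hierarchy to
production: the selected sequence's stroke events become spring-system
subgoals, the plant draws the trajectory, and the pen trace is fed
back through vision.  The example then re-perceives the self-produced
trajectory and confirms the hierarchy recognizes its own handwriting.
"""

import numpy as np

from hpbu import CorpusSpec, generate_corpus, train
from hpbu.scenarios import Hierarchy, ScenarioConfig, run_scenario

corpus = generate_corpus(CorpusSpec(n_per_digit=10, master_seed=0))
repertoire = train(corpus)

log = run_scenario(ScenarioConfig(scenario="c", produced_digit=9, seed=0), repertoire)
pen = np.asarray(log.pen)
path = np.hypot(*np.diff(pen[:, 1:3], axis=0).T).sum()
print(
    f"produced digit 9: {len(pen)} pen samples over {pen[-1, 0]:.2f} s, "
    f"path length {path:.2f} canvas units"
)
print(f"confirmed {sum(log.event_forwarded)} of {sum(log.event_fired)} stroke events")

h = Hierarchy(repertoire)
for t, pos in zip(pen[:, 0], pen[:, 1:3]):
    h.step(float(t), pos)
h.finish_trial()
winner = h.schema.state.posterior.argmax_label
by_id = {s.id: s for s in repertoire.sequences}
schema = next(c for c in repertoire.schemas if c.id == winner)
digit = {by_id[m].source_digit for m in schema.member_sequence_ids}
print(f"re-perceiving its own trace selects schema {winner} -> digit {digit}")
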