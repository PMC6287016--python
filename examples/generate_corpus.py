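"""Build the synthetic handwriting corpus and inspect one exemplar.

Generates ten noisy exemplars per digit from single-stroke templates
and prints per-digit trajectory statistics.  The corpus stands in for
a tablet-recorded set of handwritten digits: same writer, consistent
shapes, small angle/scale/timing variability.
"""

import numpy as np

from hpbu import CorpusSpec, generate_corpus, save_corpus

corpus = generate_corpus(CorpusSpec(n_per_digit=10, master_seed=0))
print(f"{len(corpus)} trajectories ({corpus.spec.n_per_digit} per digit)")
print("digit  samples  duration[s]  path length")
for digit in range(10):
    items = [t for d, _, t in corpus.trajectories() if d == digit]
    n = np.mean([len(t) for t in items])
    dur = np.mean([t.t[-1] for t in items])
    path = np.mean([np.hypot(*np.diff(t.xy, axis=0).T).sum() for t in items])
    print(f"  {digit}     {n:5.0f}     {dur:6.2f}      {path:6.2f}")

out = save_corpus(corpus, "scratch/corpus")
print(f"\nwritten to {out}/ (one CSV per exemplar + manifest.json)")
print("each row of a CSV is one pen sample: t [s], x, y [canvas units]")
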