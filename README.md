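# hpbu — hierarchical predictive belief update over handwriting

`hpbu` is a computational cognitive-neuroscience model of how a
sensorimotor system can both *perceive* and *produce* actions with the
same representations, and — crucially — tell its own actions apart from
someone else's. The domain is single-stroke handwritten digits: pen
trajectories in, pen trajectories out.

The model is a four-level active-inference hierarchy:

* **Vision** turns raw pen samples into a discrete belief over writing
  angles and segments the stream into stroke events wherever the
  current angle is *surprising* given the recent past; events are coded
  oculocentrically (relative polar coordinates anchored at the previous
  event).
* **Sequence** stores a repertoire of event sequences and scores the
  growing observation s′ against each stored sequence sᵢ with a
  spatial comparison ι(s′, sᵢ) ∈ [0, 1] and a temporal-binding factor
  `P(s′|sᵢ) = ι(s′,sᵢ) · exp(−(Δt′ − Δtᵢ)² / 2π_S²)`.
* **Schema** clusters similar sequences and hosts the *intention* gate:
  production only starts when a schema is explicitly intended, which
  applies a maintained probability boost and selects a sequence to
  enact.
* **Motor control** is a single-joint equilibrium-point plant — a
  critically damped spring with a goal-forcing term and three-goal
  lookahead (`ÿ = α(β(x_{i+3} − y) − ẏ) + (x_i − y)·γφe^{−μ|φ|}`,
  α = 25, β = 6.25, γ = 10, μ = 1/π) — that drives the pen through the
  sequence's subgoals. Motor control has **no** direct feedback path to
  the sequence level: the loop closes through vision, which forwards a
  stroke event only when visual evidence confirms the announced
  subgoal in time and space.

Every level shares one update rule: free energy
`F = H(P) + D_KL(P‖Q)` (cross-entropy of the driving signal under the
posterior-role signal) sets a Kalman gain `K = F/(F+π)`, and the level
posterior blends the bottom-up and top-down signals
`P_t = P_bu + K(P_td − P_bu)` (roles invert in production). On top of
this, a **sense-of-agency** (SoA) estimate accumulates the likelihood
of the intended sequence through the same gain:
`â_t = â_{t−1} + K_t (P(s′|s_I) − â_{t−1})`.

Because no handwriting recordings ship with the package, a synthetic
corpus module generates them: per-digit single-stroke templates with
controllable angle/scale/timing noise, deterministic per seed.

## Worked example

```bash
python examples/sense_of_agency.py
```

trains on the synthetic corpus (digits 0–9 without 4, ten exemplars
each) and runs the two production scenarios:

```
scenario c (write 9, see own pen):
  confirmed events: 6
  agency trace:     0.38, 0.40, 0.41, 0.43, 0.38, 0.32
  final estimate:   0.316
scenario d (write 1, see replayed 3):
  confirmed events: 0
  agency trace:     (no update ever fired)
  final estimate:   0.000
```

With congruent feedback each stroke the model writes is visually
confirmed, and the agency estimate rises with every correctly
predicted action. With incongruent feedback (it writes a 1 but is
shown a 3) no announced subgoal is ever confirmed, prediction error
persists, and the estimate stays at zero — the model refuses to
attribute the observed action to itself. The other examples
(`perceive_digit.py`, `produce_digit.py`, `generate_corpus.py`) walk
through recognition, production, and the corpus generator the same
way.

A thin CLI wraps the same functions:

```bash
hpbu gen-corpus --out corpus/ --exclude 4
hpbu train --corpus corpus/ --out repertoire.json
hpbu run --scenario d --repertoire repertoire.json --seed 0 --out out/
hpbu summarize --logs out/ --out summary.csv
```

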