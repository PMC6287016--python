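# Methods

## Model overview and assumptions

The package implements a hierarchical generative model of handwriting
perception and production with four levels — vision (V), sequence (S),
schema (C), and motor control (M) — all operating on *discrete*
probability distributions over discrete hypothesis sets. The guiding
assumptions:

* **Common coding.** The same sequence representations serve
  recognition and production; the only difference is which signal
  drives the update (bottom-up in perception, top-down in production).
* **Free-energy-gated belief updates.** Each level computes
  `F = H(P) + D_KL(P‖Q) = −Σᵢ Pᵢ ln Qᵢ` between its top-down and
  bottom-up signals (the posterior role is taken by the top-down
  signal in perception and the bottom-up signal in production), turns
  it into a gain `K = F/(F+π)`, and blends the two signals. High
  prediction error shifts weight toward the non-driving signal; the
  per-level precision π damps that shift.
* **Vision-only loop closure.** Motor control has no direct feedback
  connection to the sequence level. When the plant finishes a subgoal
  it notifies vision over a long-range connection; vision forwards a
  stroke event upward only if visual evidence confirms the subgoal.
  This is what makes the model *trickable*: replaying a different
  digit's trajectory into vision breaks the loop even though
  proprioception is flawless.
* **No online learning.** The repertoire is fixed after training;
  sustained high free energy is the diagnostic that no stored
  hypothesis explains the input.

## Level mechanics

### Vision: surprise segmentation

Pen input arrives as `(t, x, y)` samples at 100 Hz. Each displacement
is spread over 16 circular angle bins with a von-Mises kernel
(κ = 8, ≈90 % of mass in the true bin and its two neighbours). The
level predicts the next writing angle with an exponentially discounted
mixture of the angle beliefs seen since the last event, **anchored at
the segment start**: a belief arriving k samples after the last event
gets weight λᵏ (λ = 0.8). Anchoring matters — a recency-weighted
average adapts to steady curvature within ~1/(1−λ) samples, and curved
digits then never surprise it. With the anchored predictor, straight
motion stays fully predicted while a sustained curve accumulates
deviation and is carved into arc events, and corners fire immediately.
An event fires when `−ln P_pred(current modal angle)` exceeds 2.5 nats
(after a 3-sample burn-in); firings closer than 0.05 canvas units to
the previous event only restart the predictor (near-stationary corner
wiggles are not strokes). Each event is coded oculocentrically —
`(angle, length, Δt)` relative to the previous event's position — and
the pen stopping closes the final stroke.

### Sequence: comparison, likelihood, evidence

The spatial comparison ι(s′, sᵢ) aligns the observation against the
leading events of the hypothesis, in order from the start. Each
alignment step compares one event — or the merged chord (displacement
vector sum) of up to three consecutive events on either side — through
Gaussian kernels on the circular angle difference (σ_a = 2π/16) and
the relative length difference (σ_l = 0.25 of the stored chord).
Merging absorbs the main nuisance of surprise segmentation, boundary
splits (one arc observed as two sub-arcs), but each merged chord also
pays for the *slack* between its path length and chord length, so
straightening genuine curvature is expensive. The best alignment is
found by exact dynamic programming; ι is the geometric mean of the
per-event kernels weighted per observed event, so identical prefixes
score exactly 1 regardless of length. Observations that overrun a
shorter hypothesis pay `e^{−1}` per extra event; for whole-sequence
similarity (used in clustering and at trial end) an *unconsumed
hypothesis tail* pays the same rate, so a sequence that merely starts
like a longer one does not score as its equal.

The temporal-binding factor multiplies ι by
`exp(−(Δt′ − Δtᵢ)²/2π_S²)` on the latest event's observed vs. stored
delay (π_S = 0.15 s). This absolute form drives the sense-of-agency
likelihood. For *evidence accumulation* the stored delay is first
rescaled by the cumulative tempo ratio observed so far (clamped to
[0.5, 2]), making recognition tempo-invariant: a uniformly slower
rendition of the same rhythm is not mistaken for a digit with slower
strokes, while a genuinely different rhythm is still penalized.

Bottom-up evidence accumulates event by event as the *incremental*
joint likelihood: the log of `n·ln ι` plus the temporal terms,
differenced against the previous event's value. The running sum
telescopes to the joint log likelihood of the whole observation, so
the terminal evidence equals what a single batch evaluation would
give. Two numerical safeguards: the evidence accumulator lives in log
space and is never floored (flooring would silently forgive
hypotheses whose cumulative evidence lies below the floor, handing
them a windfall when a later event redeems them), and the
*level-state* bottom-up signal clips each event's evidence at 10 nats
so free energy stays off the probability-floor ceiling and the gain
remains informative.

The upward message `P_bu(C|S)` sums the pure evidence per schema. It
deliberately does **not** aggregate the blended level posterior:
echoing top-down influence back upward creates a resonance in which an
early wrong schema reinforces itself against later evidence.

At trial end two closing operations run: a *completion* update that
reweights every hypothesis by the ratio of its full-consumption to its
prefix similarity (the pen lift is evidence that the sequence ended),
and ~25 settling updates of the schema level on the now-static scene
(levels update top-first within a step, so without settling a decisive
final stroke could never propagate to the top).

### Schema: clustering and the intention gate

Schemas are built by single-linkage agglomerative clustering on
`1 − ι` over full sequences (symmetrized), cut at similarity 0.6. On
the default corpus this yields digit-pure clusters, usually one per
digit (the closed-loop zero occasionally splits into two sub-clusters,
which is harmless downstream). During each update the level's top-down
signal is its own empirical prior; while an intention is active the
target schema's probability is multiplied by the boost (3.0) and
renormalized *every step* — a maintained boost, needed to keep the
enacted hypothesis from being displaced mid-production. The enacted
sequence s_I is the intended schema's highest-posterior member (ties
to lowest id) and may switch mid-trial to a same-schema member whose
posterior exceeds s_I's by a factor of 2.

### Motor control: equilibrium-point plant

The pen is a point mass under

    φ = angle(x_i − y) − angle(ẏ),  wrapped to (−π, π]
    g = (x_i − y) · γ φ e^{−μ|φ|}
    ÿ = α(β(x_{i+3} − y) − ẏ) + g

with α = 25 s⁻¹, β = 6.25 s⁻¹ (critical damping of the linear part,
repeated eigenvalue −12.5 s⁻¹), γ = 10, μ = 1/π, integrated by
semi-implicit Euler at 1 ms and sampled at 100 Hz. Zero velocity
leaves the heading undefined; the forcing is zero for that step.

Two facts shape the production loop. First, the plant's fixed point is
`x_{i+3}`, not `x_i`, so advancing subgoals on arrival deadlocks; the
goal buffer instead advances on the sequence's stored *timing goals*.
Second, with the stroke events of this corpus (5–10 per digit) a
three-goal lookahead spans half the digit; stroke chords are therefore
subdivided into waypoints ≤ 0.05 canvas units apart, which keeps the
lookahead local while preserving the printed dynamics. Production is
paced 1.3× slower than the demonstration (careful writing): pursuit
lag scales with speed (≈ v/12.5 s), and at demonstration speed it
distorts the shapes beyond recognition. Done notifications are emitted
at true stroke boundaries only.

### Confirmation windows

A done notification is confirmed if a visual stroke event lies within
12 sampling periods of it (surprise events lag or lead the announced
boundary by up to ~100 ms) and within 60 % of the stroke's length of
the announced subgoal (floor 0.08 units, so short strokes remain
confirmable). The final stroke's notification stays live until trial
end — its event can only fire once the pen stops — and is then bound
to the announced completion time, since the visual tail has no sharp
intrinsic time of its own. Under these windows congruent
self-observation confirms essentially every stroke while a replayed
different digit confirms none. Forwarded events are re-anchored at the
previous *forwarded* event, so the chain the sequence level sees stays
geometrically consistent even across a missed confirmation. An
expired, unconfirmed notification triggers a no-evidence level update,
so the failure registers as free energy rather than silence.

### Sense of agency

`â_t = â_{t−1} + K_t (P(s′|s_I) − â_{t−1})` with
`K_t = F_S/(F_S + π_S)` computed from the sequence level's free energy
and precision (1.0), updated once per confirmed event, `â₀ = 0`. The
update is a convex combination, so the estimate is bounded by the
likelihood range and one step never moves it by more than K_t. Note
the inherited tension: *higher* free energy makes the estimate track
the likelihood *faster*; the formula is implemented as stated and the
tension documented rather than resolved.

## Synthetic corpus

Templates are hand-designed single-stroke polylines (cursive one-stroke
forms for 4; a squarish oval for 0, whose concentrated corner turns
segment stably where a pure ellipse's terminal arc sits exactly at the
surprise threshold and flips between 6 and 7 events). Exemplars jitter
each control-point displacement by a rotation (σ = 0.04 rad) and scale
(σ = 4 %) and each segment duration by σ = 6 %, then interpolate x(t),
y(t) with monotone cubics through the timed control points at 100 Hz
(0.8–1.5 s per digit). The noise levels emulate a *single writer's*
repetitions — consistent stroke order and shape, small metric
variability — which is exactly the regime in which digit-wise schemas
form. Angle noise is zero-mean, so exemplar headings are unbiased
around the template. Seeds: one master seed expands into per-exemplar
child seeds recorded in the manifest; everything downstream is
deterministic given the corpus.

What the generator does *not* emulate: pen-up strokes (all templates
are single-stroke by design, since the hierarchy has no pen-lift
concept), pressure/tilt channels, writer-to-writer variation, and the
device characteristics of any particular tablet. Tests passing on this
corpus therefore show the machinery is sound under single-writer
conditions, not that it would survive multi-writer digit variation.

## Default constants

| constant | value | meaning |
|---|---|---|
| n_angle / κ | 16 / 8.0 | angle bins, kernel concentration |
| surprise threshold | 2.5 nats | event segmentation |
| λ | 0.8 | anchored history discount |
| min event length | 0.05 u | wiggle suppression |
| π (V, S, C) | 1.0, 1.0, 2.0 | level precisions |
| π_S (temporal) | 0.15 s | temporal-binding width |
| σ_a, σ_l | 2π/16, 0.25·len | comparison kernel widths |
| overrun rate | 1.0 /event | unmatched-event penalty |
| evidence clip | 10 nats | per-event cap (level state only) |
| link threshold | 0.6 | schema clustering cut |
| boost | 3.0 | maintained intention boost |
| α, β, γ, μ | 25, 6.25, 10, 1/π | spring constants |
| goal spacing / stretch | 0.05 u / 1.3 | production subgoal chain |
| τ_confirm / r_confirm | 12 periods / 0.6·len (≥0.08 u) | confirmation windows |
| â₀ | 0.0 | initial agency estimate |

All constants live in `hpbu.config.ModelConfig` and can be overridden
from YAML/JSON.

## Problem sizes

The shipped simulations use ten exemplars per digit (90 sequences
when the 4 is withheld for the unknown-digit scenario), trajectories
of 80–150 samples, and trials of 100–250 hierarchy steps; training
takes a few seconds and a scenario well under a second on one core.

## Known limitations

* Recognition margins on *self-produced* trajectories are thinner than
  on corpus exemplars (the plant smooths corners); with some corpus
  seeds one digit's production is misattributed to a similar digit.
* The free-energy convention (posterior role taken by the top-down
  signal in perception) makes F entropy-dominated when beliefs are
  diffuse; F is therefore best read as a relative trace within a
  trial, not an absolute error measure.
* The agency estimate in the congruent scenario plateaus in the 0.3–0.5
  range rather than near 1: confirmed events carry residual spatial and
  timing mismatch from the plant's pursuit dynamics.
* Timing is modelled only through per-event delays; the plant does not
  track time explicitly, and the stored delays enter production as a
  schedule, not a control target.
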