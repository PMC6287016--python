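"""Sense-of-agency accumulation.

During production the sequence level repeatedly scores the visually
confirmed action stream against the *intended* sequence.  That
likelihood is folded into a scalar agency estimate a_t in [0, 1]
through a Kalman-style filter whose gain is set by the sequence level's
free energy F_S and precision pi_S:

    K_t = F_S / (F_S + pi_S)
    a_t = a_{t-1} + K_t * (P(s'|s_I) - a_{t-1})

Each step moves the estimate at most K_t toward the current likelihood,
so strong single-step fluctuations are dampened and the estimate
reflects the accumulated success of predicting one's own action stream.
Note the deliberate asymmetry inherited from the gain: high free energy
(poor prediction) makes the estimate *track the likelihood faster* —
confident, well-predicted episodes change the running estimate slowly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beliefs import kalman_gain

__all__ = ["AgencyTrace", "update_soa", "run_agency"]


@dataclass
class AgencyTrace:
    """Per-step record of the agency filter."""

    values: list = field(default_factory=list)       # a_t
    gains: list = field(default_factory=list)        # K_t
    likelihoods: list = field(default_factory=list)  # P(s'|s_I)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def final(self) -> float:
        return self.values[-1] if self.values else 0.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "step": np.arange(len(self.values)),
                "likelihood": self.likelihoods,
                "gain": self.gains,
                "soa": self.values,
            }
        )


def update_soa(prev: float, likelihood: float, f_s: float, pi_s: float) -> float:
    """One agency update; returns a_t.

    Raises on out-of-range inputs rather than clipping: the caller is
    feeding quantities that are probabilities / free energies by
    construction, so a violation is a wiring bug.
    """
    if not 0.0 <= prev <= 1.0:
        raise ValueError(f"previous agency estimate out of [0,1]: {prev}")
    if not 0.0 <= likelihood <= 1.0:
        raise ValueError(f"likelihood out of [0,1]: {likelihood}")
    k = kalman_gain(f_s, pi_s)
    return prev + k * (likelihood - prev)


def run_agency(trial, pi_s: float, a0: float = 0.0) -> AgencyTrace:
    """Fold the agency filter over a trial.

    ``trial`` is an iterable of ``(likelihood, F_S)`` pairs, one per
    sequence-level update step.  Returns the full trace.
    """
    trace = AgencyTrace()
    a = a0
    for likelihood, f_s in trial:
        k = kalman_gain(f_s, pi_s)
        a = a + k * (likelihood - a)
        trace.values.append(a)
        trace.gains.append(k)
        trace.likelihoods.append(likelihood)
    return trace
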