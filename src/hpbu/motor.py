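"""Single-joint equilibrium-point motor plant.

The pen is modelled as a point mass driven by a damped spring whose set
point is placed three subgoals ahead of the one currently being
visited, plus a goal-forcing term that bends the motion toward the
current subgoal:

    phi      = angle(x_i - y) - angle(y_dot)        (wrapped to (-pi, pi])
    phi_dot  = gamma * phi * exp(-mu * |phi|)
    g        = (x_i - y) * phi_dot
    y_ddot   = alpha * (beta * (x_{i+3} - y) - y_dot) + g

With the default constants the linear part is critically damped
(repeated eigenvalue -alpha/2), so a single fixed goal is approached
without overshoot, while the lookahead keeps up momentum through a
chain of subgoals instead of braking at every one.  Integration is
semi-implicit Euler at a fine internal step; pen samples are emitted at
the trajectory sampling rate.

By design this module exposes no message back to the sequence level:
the production loop is closed through vision, which receives the
"done" notification emitted when a subgoal is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpringParams", "SpringState", "DoneSignal", "spring_step", "run_to_goal"]


@dataclass(frozen=True)
class SpringParams:
    """Constants of the spring system.

    alpha, beta set the damped spring (critically damped when
    beta = alpha/4); gamma scales the goal-forcing turn rate and mu its
    saturation with angular error.  dt_int is the internal integration
    step, sample_rate the rate at which pen samples are recorded.
    """

    alpha: float = 25.0          # 1/s
    beta: float = 6.25           # 1/s
    gamma: float = 10.0          # turn-rate scale
    mu: float = 1.0 / np.pi      # 1/rad
    dt_int: float = 0.001        # s
    sample_rate: float = 100.0   # Hz
    #: use the bearing from position to goal for phi (default); if
    #: False, use the velocity direction toward the goal instead.
    phi_from_bearing: bool = True

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma", "mu", "dt_int", "sample_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SpringState:
    """Pen position/velocity plus the subgoal buffer."""

    y: np.ndarray                 # planar position
    y_dot: np.ndarray             # planar velocity
    goals: list = field(default_factory=list)   # remaining subgoals, goals[0] = x_i
    t: float = 0.0

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).copy()
        self.y_dot = np.asarray(self.y_dot, dtype=float).copy()
        self.goals = [np.asarray(g, dtype=float) for g in self.goals]

    @property
    def current_goal(self) -> np.ndarray:
        if not self.goals:
            raise IndexError("goal buffer is empty")
        return self.goals[0]

    @property
    def lookahead_goal(self) -> np.ndarray:
        """x_{i+3}, clamped to the final goal near the sequence end."""
        return self.goals[min(3, len(self.goals) - 1)]


@dataclass(frozen=True)
class DoneSignal:
    """Long-range notification from motor to vision: subgoal finished."""

    subgoal: np.ndarray
    time: float
    reached: bool


def _wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]."""
    a = (a + np.pi) % (2.0 * np.pi) - np.pi
    if a == -np.pi:
        a = np.pi
    return a


def spring_step(state: SpringState, params: SpringParams) -> SpringState:
    """Advance the plant by one internal integration step (in place)."""
    y, v = state.y, state.y_dot
    x_i = state.current_goal
    x_ahead = state.lookahead_goal

    to_goal = x_i - y
    speed = float(np.hypot(*v))
    dist = float(np.hypot(*to_goal))
    # zero velocity leaves the heading undefined -> no forcing this step
    if speed > 0.0 and dist > 0.0:
        phi = _wrap_angle(np.arctan2(to_goal[1], to_goal[0]) - np.arctan2(v[1], v[0]))
        if not params.phi_from_bearing:
            phi = -phi
        phi_dot = params.gamma * phi * np.exp(-params.mu * abs(phi))
        g = to_goal * phi_dot
    else:
        g = np.zeros(2)

    acc = params.alpha * (params.beta * (x_ahead - y) - v) + g
    v = v + params.dt_int * acc
    y = y + params.dt_int * v
    state.y, state.y_dot = y, v
    state.t += params.dt_int
    return state


def run_to_goal(
    state: SpringState,
    params: SpringParams,
    tolerance: float,
    timeout: float = 2.0,
):
    """Integrate until the current subgoal is within ``tolerance``.

    Returns ``(samples, done)`` where ``samples`` is an (n, 3) array of
    ``t, x, y`` pen samples recorded at the sampling rate and ``done``
    is the long-range signal sent to vision.  On timeout the subgoal is
    abandoned and the signal is flagged unreached, which downstream
    shows up as unexplained prediction error.  The reached (or
    abandoned) subgoal is popped from the buffer.
    """
    x_i = state.current_goal
    samples = []
    sample_period = 1.0 / params.sample_rate
    next_sample_t = state.t  # record a sample at entry
    t_start = state.t
    reached = float(np.hypot(*(x_i - state.y))) < tolerance
    while not reached and state.t - t_start < timeout:
        if state.t >= next_sample_t - 0.5 * params.dt_int:
            samples.append((state.t, state.y[0], state.y[1]))
            next_sample_t += sample_period
        spring_step(state, params)
        reached = float(np.hypot(*(x_i - state.y))) < tolerance
    samples.append((state.t, state.y[0], state.y[1]))
    state.goals.pop(0)
    done = DoneSignal(subgoal=x_i.copy(), time=state.t, reached=reached)
    return np.array(samples, dtype=float), done
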