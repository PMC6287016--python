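import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hpbu.beliefs import (
    DiscreteBelief,
    LevelState,
    Mode,
    free_energy,
    kalman_gain,
    update_level,
)


def random_belief(n, rng):
    return DiscreteBelief(tuple(range(n)), rng.dirichlet(np.ones(n)))


probs_strategy = st.lists(
    st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=12
)


class TestFreeEnergy:
    def test_identical_uniform_gives_entropy(self):
        u = DiscreteBelief.uniform(range(4))
        assert free_energy(u, u) == pytest.approx(math.log(4), abs=1e-9)

    def test_point_mass_against_uniform_is_pure_divergence(self):
        p = DiscreteBelief(tuple(range(4)), [1.0, 0.0, 0.0, 0.0])
        q = DiscreteBelief.uniform(range(4))
        # entropy of the (floored) point mass is ~0, so F ~ KL = ln 4
        assert free_energy(p, q) == pytest.approx(math.log(4), abs=1e-6)

    def test_cross_entropy_form(self):
        p = DiscreteBelief((0, 1), [0.7, 0.3])
        q = DiscreteBelief((0, 1), [0.5, 0.5])
        # -0.7 ln 0.5 - 0.3 ln 0.5 = ln 2
        assert free_energy(p, q) == pytest.approx(0.693147, abs=1e-5)
        assert free_energy(p, q) == pytest.approx(p.entropy() + p.kl_to(q), abs=1e-9)

    @given(probs_strategy)
    @settings(max_examples=50, deadline=None)
    def test_uniform_prior_collapses_to_log_n(self, weights):
        p = DiscreteBelief.from_weights(tuple(range(len(weights))), weights)
        u = DiscreteBelief.uniform(range(len(weights)))
        assert free_energy(p, u) == pytest.approx(math.log(len(weights)), abs=1e-9)

    @given(probs_strategy)
    @settings(max_examples=50, deadline=None)
    def test_equals_entropy_iff_equal(self, weights):
        p = DiscreteBelief.from_weights(tuple(range(len(weights))), weights)
        assert free_energy(p, p) == pytest.approx(p.entropy(), abs=1e-9)
        rng = np.random.default_rng(0)
        q = random_belief(len(p), rng)
        if not np.allclose(p.probs, q.probs):
            assert free_energy(p, q) > p.entropy()

    def test_label_mismatch_rejected(self):
        p = DiscreteBelief((0, 1), [0.5, 0.5])
        q = DiscreteBelief((0, 2), [0.5, 0.5])
        with pytest.raises(ValueError):
            free_energy(p, q)


class TestKalmanGain:
    @pytest.mark.parametrize(
        "f, pi, expected",
        [
            (0.0, 1.0, 0.0),
            (2.5, 2.5, 0.5),
            (math.log(4), 1.0, math.log(4) / (math.log(4) + 1)),
        ],
    )
    def test_values(self, f, pi, expected):
        assert kalman_gain(f, pi) == pytest.approx(expected, abs=1e-9)

    @given(
        st.floats(min_value=0.0, max_value=50.0),
        st.floats(min_value=0.01, max_value=50.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_monotonicity(self, f, pi):
        k = kalman_gain(f, pi)
        assert 0.0 <= k < 1.0
        assert kalman_gain(f + 1.0, pi) > k
        assert kalman_gain(f, pi + 1.0) <= k

    def test_nonpositive_precision_rejected(self):
        with pytest.raises(ValueError):
            kalman_gain(1.0, 0.0)


class TestUpdateLevel:
    def test_convex_combination_by_hand(self):
        bu = DiscreteBelief((0, 1), [0.8, 0.2])
        td = DiscreteBelief((0, 1), [0.2, 0.8])
        blended = bu.blend(td, 0.25)
        assert np.allclose(blended.probs, [0.65, 0.35], atol=1e-9)

    def test_zero_gain_returns_driving_signal(self):
        bu = DiscreteBelief((0, 1), [0.8, 0.2])
        # F = 0 iff td == bu and both are point... zero-error case: equal signals
        state = LevelState(posterior=bu, precision=1.0, mode=Mode.PERCEPTION)
        new = update_level(state, p_td=bu, p_bu=bu)
        assert np.allclose(new.posterior.probs, bu.probs, atol=1e-9)
        assert new.gain < 0.5  # entropy-driven only

    def test_mode_swap_symmetry(self):
        rng = np.random.default_rng(3)
        bu, td = random_belief(5, rng), random_belief(5, rng)
        perc = update_level(
            LevelState(posterior=bu, precision=1.0, mode=Mode.PERCEPTION), td, bu
        )
        prod = update_level(
            LevelState(posterior=bu, precision=1.0, mode=Mode.PRODUCTION), bu, td
        )
        # swapping mode together with the two signals is a no-op
        assert np.allclose(perc.posterior.probs, prod.posterior.probs, atol=1e-12)
        assert perc.free_energy == pytest.approx(prod.free_energy, abs=1e-12)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_posterior_stays_normalized(self, seed):
        rng = np.random.default_rng(seed)
        bu, td = random_belief(6, rng), random_belief(6, rng)
        state = LevelState(posterior=bu, precision=1.0, mode=Mode.PERCEPTION)
        new = update_level(state, td, bu)
        assert new.posterior.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert 0.0 <= new.gain < 1.0
        assert new.free_energy >= 0.0
        # convexity: posterior lies between the two signals componentwise
        lo = np.minimum(bu.probs, td.probs) - 1e-9
        hi = np.maximum(bu.probs, td.probs) + 1e-9
        assert np.all(new.posterior.probs >= lo - 1e-6)
        assert np.all(new.posterior.probs <= hi + 1e-6)

    def test_stores_empirical_prior(self):
        rng = np.random.default_rng(1)
        bu, td = random_belief(4, rng), random_belief(4, rng)
        state = LevelState(posterior=bu, precision=1.0, mode=Mode.PERCEPTION)
        new = update_level(state, td, bu)
        assert new.prior is state.posterior


class TestDiscreteBelief:
    def test_flooring_keeps_all_mass_positive(self):
        b = DiscreteBelief((0, 1, 2), [1.0, 0.0, 0.0])
        assert np.all(b.probs > 0)
        assert b.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            DiscreteBelief((0, 0), [0.5, 0.5])

    def test_from_weights_zero_degrades_to_uniform(self):
        b = DiscreteBelief.from_weights((0, 1, 2), [0.0, 0.0, 0.0])
        assert np.allclose(b.probs, 1 / 3)
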