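"""The four unit models: utility, beliefs, activations, learning rules."""

import math

import numpy as np
import pytest

from neurongame import (
    AgentHyperParams,
    BayesBelief,
    PerceptronState,
    RLState,
    bayes_activation,
    belief_density,
    belief_update,
    encode,
    perceptron_activation,
    perceptron_update,
    phi_density_given_f,
    reward,
    rl_activation,
    sarsa_update,
    thompson_activation,
    utility,
)
from neurongame.agent_core import soft_activation, unit_rng
from neurongame.agent_models import (
    KAPPA_GRID,
    PerceptronAgent,
    SarsaAgent,
    ThompsonAgent,
    _sarsa_step,
    expected_distance_profile,
)
from neurongame._circular import circ_dist

TWO_PI = 2 * math.pi


class TestUtility:
    @pytest.mark.parametrize(
        "a,phi,nu,expected",
        [
            (1, 1.3, 1.3, math.pi / 2),
            (1, 0.0, math.pi, -math.pi / 2),
            (0, 0.7, 2.9, 0.0),
            (1, 0.0, math.pi / 2, 0.0),
        ],
    )
    def test_values(self, a, phi, nu, expected):
        assert utility(a, phi, nu) == pytest.approx(expected)


class TestPhiDensity:
    def test_support_and_height(self, params):
        dens = phi_density_given_f(encode(1.0, params), params)
        assert dens.half_width == pytest.approx(math.pi / 360)
        assert dens.height == pytest.approx(360 / TWO_PI)
        assert dens(dens.center) == pytest.approx(360 / TWO_PI)
        assert dens(dens.center + 3 * dens.half_width) == 0.0

    def test_integrates_to_one(self, params):
        dens = phi_density_given_f(encode(2.5, params), params)
        grid = np.linspace(0, TWO_PI, 200_000, endpoint=False)
        assert np.trapezoid(dens(grid), grid) == pytest.approx(1.0, abs=1e-2)

    def test_invalid_feature_vector_rejected(self, params):
        with pytest.raises(ValueError):
            phi_density_given_f(np.zeros(360), params)


class TestBeliefUpdate:
    def test_first_observation(self):
        b = belief_update(BayesBelief(), 1.1)
        assert b.r0 == pytest.approx(1.0)
        assert b.phi == pytest.approx(1.1)
        assert b.c == 1

    def test_antipodal_observations_cancel(self):
        b = belief_update(BayesBelief(), [0.4, 0.4 + math.pi])
        assert b.r0 == pytest.approx(0.0, abs=1e-9)
        assert b.c == 2

    def test_identical_observations_stack(self):
        b = belief_update(BayesBelief(), [2.2] * 7)
        assert b.r0 == pytest.approx(7.0)
        assert b.phi == pytest.approx(2.2)
        assert b.c == 7

    def test_resultant_never_exceeds_count(self, rng):
        b = BayesBelief()
        for ang in rng.uniform(0, TWO_PI, 50):
            b = belief_update(b, ang)
            assert b.r0 <= b.c


class TestBeliefDensity:
    def test_uninformed_belief_is_uniform_over_direction(self):
        nu, kappa, p = belief_density(BayesBelief())
        marginal = p.sum(axis=1)
        assert np.allclose(marginal, marginal[0])

    def test_normalization(self):
        b = belief_update(BayesBelief(), [1.0, 1.2, 0.9])
        nu, kappa, p = belief_density(b)
        dnu = TWO_PI / len(nu)
        dk = np.gradient(kappa)
        assert (p * dnu * dk[None, :]).sum() == pytest.approx(1.0)

    def test_mode_at_mean_direction(self):
        b = belief_update(BayesBelief(), [1.0, 1.2, 0.9, 1.1])
        nu, kappa, p = belief_density(b)
        mode_nu = nu[p.sum(axis=1).argmax()]
        assert circ_dist(mode_nu, b.phi) < 0.05

    def test_inconsistent_belief_rejected(self):
        with pytest.raises(ValueError):
            belief_density(BayesBelief(r0=2.0, phi=float("nan"), c=5))


class TestBayesActivation:
    def test_uninformed_belief_gives_zero(self, params):
        f = encode(0.3, params)
        assert bayes_activation(BayesBelief(), f, params) == 0.0

    def test_concentrated_belief_approaches_max_utility(self, params):
        nu0 = 1.7
        b = belief_update(BayesBelief(), [nu0] * 500)
        g = bayes_activation(b, encode(nu0, params), params)
        assert g == pytest.approx(math.pi / 2, abs=0.05)

    def test_opposed_belief_is_negative(self, params):
        b = belief_update(BayesBelief(), [0.0] * 100)
        g = bayes_activation(b, encode(math.pi, params), params)
        assert g < -1.0

    def test_refinement_oracle(self, params, rng):
        """A 10x denser direction grid and phi quadrature changes the
        activation by less than 1e-2 for random beliefs and features."""
        for _ in range(5):
            angs = rng.vonmises(rng.uniform(0, TWO_PI), 3.0, size=25) % TWO_PI
            b = belief_update(BayesBelief(), angs)
            f = encode(rng.uniform(0, TWO_PI), params)
            coarse = bayes_activation(b, f, params)
            fine = bayes_activation(b, f, params, grid_size=3600, phi_points=160)
            assert abs(coarse - fine) < 1e-2

    def test_parameter_recovery(self, rng):
        """The posterior mode over the direction converges to the true
        direction after 200 observations."""
        mu = 2.0
        b = belief_update(BayesBelief(), rng.vonmises(mu, 8.0, size=200) % TWO_PI)
        nu, kappa, p = belief_density(b)
        mode_nu = nu[p.sum(axis=1).argmax()]
        assert circ_dist(mode_nu, mu) < 0.1


class TestThompsonActivation:
    def test_range(self, params, rng):
        b = belief_update(BayesBelief(), [0.5, 1.5, 2.5])
        f = encode(1.0, params)
        for _ in range(200):
            g = thompson_activation(b, f, rng, params)
            assert -math.pi / 2 <= g <= math.pi / 2

    def test_degenerate_belief_matches_bayes(self, params, rng):
        """A point-mass belief makes the sample nearly deterministic."""
        nu0 = 0.9
        b = belief_update(BayesBelief(), [nu0] * 2000)
        f = encode(nu0, params)
        g_b = bayes_activation(b, f, params)
        samples = [thompson_activation(b, f, rng, params) for _ in range(100)]
        assert abs(np.mean(samples) - g_b) < 0.02

    def test_unbiased_estimator_of_bayes(self, params, rng):
        """Monte-Carlo mean of the sampled utility equals the quadrature
        expected utility within 3 standard errors."""
        angs = rng.vonmises(1.2, 2.0, size=30) % TWO_PI
        b = belief_update(BayesBelief(), angs)
        f = encode(1.0, params)
        g_b = bayes_activation(b, f, params)
        n = 50_000
        samples = np.array([thompson_activation(b, f, rng, params) for _ in range(n)])
        se = samples.std(ddof=1) / math.sqrt(n)
        assert abs(samples.mean() - g_b) < 3 * se + 1e-3  # + direction-grid slack


class TestReward:
    @pytest.mark.parametrize(
        "s0,s1,expected",
        [((0.0, 0.0), (5.0, 0.0), 1), ((0.0, 0.0), (0.0, 0.0), 0), ((5.0, 0.0), (0.0, 0.0), -1)],
    )
    def test_sign(self, s0, s1, expected):
        assert reward(s0, s1, (10.0, 0.0)) == expected


class TestSarsa:
    def test_zero_weights_zero_reward_stay_zero(self):
        state = RLState(n_features=4)
        f = np.array([1, 0, 1, 0])
        out = sarsa_update(state, f, 1, 0.0, f, 1)
        assert np.all(out.w == 0.0)

    def test_hand_worked_single_update(self):
        """alpha=0.1, gamma=0.9, lambda=0.8, zero init, r=1: the TD error is
        1 and only the replaced trace entries move, by alpha."""
        state = RLState(n_features=4, alpha=0.1, gamma=0.9, lam=0.8)
        f_t = np.array([1, 0, 1, 0])
        f_t1 = np.array([0, 1, 0, 1])
        out = sarsa_update(state, f_t, 1, 1.0, f_t1, 0)
        expected_w = np.zeros(8)
        expected_w[[4, 6]] = 0.1  # press-block entries of f_t
        assert np.allclose(out.w, expected_w)
        expected_z = np.zeros(8)
        expected_z[[4, 6]] = 0.9 * 0.8  # replaced to 1, then decayed
        assert np.allclose(out.z, expected_z)
        assert np.all(state.w == 0.0)  # functional update left input alone

    def test_replacing_traces_bounded(self, rng):
        state = RLState(n_features=6, alpha=0.05)
        for _ in range(200):
            f = (rng.random(6) < 0.5).astype(int)
            a = int(rng.random() < 0.5)
            _sarsa_step(state, np.flatnonzero(f), a, float(rng.choice([-1, 0, 1])),
                        np.flatnonzero(f), a)
            assert np.all(state.z <= 1.0 + 1e-12) and np.all(state.z >= 0.0)

    def test_activation_is_block_difference(self):
        state = RLState(n_features=3)
        state.w = np.array([0.5, 0.0, -0.25, 1.0, 2.0, 0.0])
        f = np.array([1, 0, 1])
        assert rl_activation(state, f) == pytest.approx((1.0 + 0.0) - (0.5 - 0.25))

    def test_bandit_reward_ordering(self):
        """On a frozen two-context bandit, pressing in the rewarded context
        acquires a higher activation than pressing in the punished one."""
        state = RLState(n_features=4, alpha=0.05, gamma=0.0, lam=0.0)
        f_good = np.array([1, 1, 0, 0])
        f_bad = np.array([0, 0, 1, 1])
        for _ in range(200):
            state = sarsa_update(state, f_good, 1, 1.0, f_bad, 0)
            state = sarsa_update(state, f_bad, 1, -1.0, f_good, 0)
        assert rl_activation(state, f_good) > 0 > rl_activation(state, f_bad)


class TestPerceptron:
    def test_activation_is_dot_plus_bias(self):
        st = PerceptronState(n_features=4, b=1.0)
        assert perceptron_activation(st, np.zeros(4)) == pytest.approx(1.0)
        st.w = np.array([0.5, -1.0, 2.0, 0.0])
        assert perceptron_activation(st, np.array([1, 0, 1, 0])) == pytest.approx(3.5)

    @pytest.mark.parametrize("variant", ["feature_based", "as_printed"])
    def test_no_update_when_training_signal_agrees(self, variant):
        st = PerceptronState(n_features=3, variant=variant)
        st.w = np.array([1.0, 2.0, 3.0])
        st.b = 0.5
        out = perceptron_update(st, np.array([1, 1, 0]), spiked=1, training_signal=1)
        assert np.array_equal(out.w, st.w) and out.b == st.b

    def test_as_printed_zero_init_is_fixed_point(self):
        """The multiplicative rule never leaves the all-zero initial state:
        a documented degeneracy of that variant."""
        st = PerceptronState(n_features=3, variant="as_printed")
        for t_signal in (0, 0, 1, 0):
            st = perceptron_update(st, np.array([1, 0, 1]), 1, t_signal)
        assert np.all(st.w == 0.0) and st.b == 0.0

    def test_feature_based_punishes_active_features(self):
        st = PerceptronState(n_features=3, alpha=0.1)
        out = perceptron_update(st, np.array([1, 0, 1]), 1, 0)
        assert np.allclose(out.w, [-0.1, 0.0, -0.1])
        assert out.b == pytest.approx(-0.1)

    def test_idle_unit_never_updates(self):
        st = PerceptronState(n_features=3)
        out = perceptron_update(st, np.array([1, 1, 1]), spiked=0, training_signal=0)
        assert np.all(out.w == 0.0) and out.b == 0.0

    def test_punitive_learning_orders_directions(self, params):
        """After punitive training with a fixed true direction, the unit is
        more likely to press for aligned than for opposed stimuli."""
        agent = PerceptronAgent(params, unit_rng(0, 0), alpha=0.01)
        mu = 1.0
        rng = np.random.default_rng(5)
        for _ in range(3000):
            psi = rng.uniform(0, TWO_PI)
            a = agent.act(psi)
            if a:
                good = circ_dist(agent._phi, mu) < math.pi / 2
                agent.observe_outcome((math.cos(mu), math.sin(mu)), 1 if good else -1)
        g_aligned = perceptron_activation(agent.state, encode(mu, params))
        g_opposed = perceptron_activation(agent.state, encode(mu + math.pi, params))
        s = params.gain
        assert soft_activation(g_aligned, s) > soft_activation(g_opposed, s)


class TestBeliefAgentRecovery:
    def test_thompson_unit_learns_its_direction(self, params):
        """Driven with displacements along its true direction, the unit's
        belief concentrates there (d_C < 0.1 rad well before 200 updates)."""
        agent = ThompsonAgent(params, unit_rng(1, 0))
        mu = 4.0
        rng = np.random.default_rng(9)
        while agent.belief.c < 200:
            psi = rng.uniform(0, TWO_PI)
            if agent.act(psi):
                d = rng.vonmises(mu, 8.0)
                agent.observe_outcome((10 * math.cos(d), 10 * math.sin(d)), 1)
        assert circ_dist(agent.belief.phi, mu) < 0.1


class TestSnapshots:
    def test_snapshots_serialize_to_json(self, params):
        import json

        from neurongame.agent_models import BayesAgent, make_agents

        for model in ("bayes", "thompson", "rl", "ann"):
            (agent,) = make_agents(model, params, seed=0, n_players=1)
            agent.act(1.0)
            agent.observe_outcome((10.0, 0.0), 1)
            snap = json.loads(json.dumps(agent.snapshot()))
            assert "spikes" in snap
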