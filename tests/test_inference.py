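import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mazenav.errors import (
    InvalidArgumentError,
    NumericalDegeneracyError,
    PrecisionFloorWarning,
)
from mazenav.inference import (
    expected_free_energy,
    infer_states,
    learn_likelihood,
    novelty_kernel,
    policy_posterior,
    run_trial,
    select_action,
    softmax,
    update_precision,
)
from mazenav.model_core import (
    AgentConfig,
    GenerativeModel,
    LikelihoodModel,
    PolicySet,
    PreferenceModel,
    TransitionSet,
    build_model,
)


def toy_model(a_what, B, d, horizon=1):
    """Small hand-built model with an uninformative where modality."""
    n = a_what.shape[1]
    policies = PolicySet(
        horizon=horizon,
        actions=tuple(range(B.shape[0])),
        policies=np.array(list(itertools.product(range(B.shape[0]), repeat=horizon))),
    )
    return GenerativeModel(
        likelihood=LikelihoodModel(a_what=a_what, A_where=np.full((n, n), 1.0 / n)),
        transitions=TransitionSet(B=B),
        preferences=PreferenceModel(c_what=np.zeros(2), c_where=np.zeros(n)),
        d=d,
        policy_set=policies,
        shape=(1, n),
    )


def exact_chain_posterior(A, B_seq, d, outcomes):
    """Enumerate all state sequences; return marginals of the exact posterior."""
    n = len(d)
    T = len(B_seq) + 1
    marginals = np.zeros((T, n))
    total = 0.0
    for seq in itertools.product(range(n), repeat=T):
        p = d[seq[0]]
        for tau in range(1, T):
            p *= B_seq[tau - 1][seq[tau], seq[tau - 1]]
        for tau, o in enumerate(outcomes):
            p *= A[o, seq[tau]]
        total += p
        for tau in range(T):
            marginals[tau, seq[tau]] += p
    return marginals / total


class TestInferStates:
    def test_observed_where_pins_state_for_all_policies(self, maze8):
        model = build_model(maze8, "novel")
        outcome = (int(maze8.cells.flat[maze8.start]), maze8.start)
        beliefs = infer_states(model, model.policy_set.policies, [outcome])
        assert np.all(beliefs.s[:, 0, maze8.start] > 0.99)

    def test_two_state_toy_matches_exact_bayes(self):
        # sharp concentrations so the expected likelihood is effectively known
        A = np.array([[0.7, 0.3], [0.3, 0.7]])
        B = np.eye(2)[None]
        d = np.array([0.5, 0.5])
        model = toy_model(A * 1e6, B, d)
        beliefs = infer_states(
            model, np.array([[0]]), [(0, 0), (0, 0)], n_iter=400, f_tol=0.0
        )
        exact = exact_chain_posterior(A, [np.eye(2)], d, [0, 0])
        assert np.abs(beliefs.s[0] - exact).max() < 1e-3

    def test_three_state_toy_matches_exact_bayes(self):
        A = np.array([[0.6, 0.3, 0.2], [0.4, 0.7, 0.8]])
        perm = np.roll(np.eye(3), 1, axis=0)  # cyclic shift
        d = np.array([0.5, 0.25, 0.25])
        model = toy_model(A * 1e6, perm[None], d)
        beliefs = infer_states(
            model, np.array([[0]]), [(0, 0), (1, 0)], n_iter=400, f_tol=0.0
        )
        exact = exact_chain_posterior(A, [perm], d, [0, 1])
        assert np.abs(beliefs.s[0] - exact).max() < 1e-3

    def test_unobserved_future_is_pure_prediction(self, maze8):
        model = build_model(maze8, "familiar")
        outcome = (int(maze8.cells.flat[maze8.start]), maze8.start)
        beliefs = infer_states(model, np.array([[3, 0]]), [outcome])
        pred1 = model.transitions[3] @ beliefs.s[0, 0]
        pred2 = model.transitions[0] @ beliefs.s[0, 1]
        assert np.abs(beliefs.s[0, 1] - pred1).max() < 1e-6
        assert np.abs(beliefs.s[0, 2] - pred2).max() < 1e-6

    def test_free_energy_non_increasing(self, maze8):
        model = build_model(maze8, "novel")
        outcome = (int(maze8.cells.flat[maze8.start]), maze8.start)
        beliefs = infer_states(model, model.policy_set.policies, [outcome])
        f = beliefs.f_trace
        running_min = np.minimum.accumulate(f)
        assert np.all(f <= running_min + 1e-6)

    def test_posteriors_normalised_every_iteration(self, maze8):
        model = build_model(maze8, "novel")
        outcome = (int(maze8.cells.flat[maze8.start]), maze8.start)
        beliefs = infer_states(
            model, model.policy_set.policies, [outcome], record=True
        )
        sums = beliefs.s_history.sum(axis=-1)
        assert np.allclose(sums, 1.0, atol=1e-8)

    def test_degenerate_prior_raises(self, maze8):
        model = build_model(maze8, "novel")
        outcome = (int(maze8.cells.flat[maze8.start]), maze8.start)
        with pytest.raises(NumericalDegeneracyError):
            infer_states(
                model, model.policy_set.policies, [outcome], d=np.zeros(maze8.n_states)
            )


class TestExpectedFreeEnergy:
    def test_known_maze_novelty_vanishes(self, maze8):
        model = build_model(maze8, "familiar")
        model.likelihood.a_what = model.likelihood.a_what * 1e8
        outcome = (int(maze8.cells.flat[maze8.start]), maze8.start)
        beliefs = infer_states(model, model.policy_set.policies, [outcome])
        efe = expected_free_energy(model, beliefs.s, [1, 2])
        assert np.abs(efe.novelty).max() < 1e-6

    def test_flat_preferences_reduce_to_novelty(self, maze8):
        # deterministic predictions: risk and ambiguity cancel exactly, so the
        # ranking over all 25 policies is the ranking by summed novelty
        model = build_model(maze8, "novel")
        outcome = (int(maze8.cells.flat[maze8.start]), maze8.start)
        beliefs = infer_states(model, model.policy_set.policies, [outcome])
        efe = expected_free_energy(model, beliefs.s, [1, 2])
        assert np.allclose(efe.total, -efe.novelty, atol=1e-6)

    def test_uniform_novel_kernel_value(self):
        w = novelty_kernel(np.full((2, 1), 0.125))
        assert np.allclose(w, 0.5 * (8.0 - 4.0))

    def test_decomposition_identity_and_nonnegative_novelty(self, maze8):
        model = build_model(maze8, "novel")
        outcome = (int(maze8.cells.flat[maze8.start]), maze8.start)
        beliefs = infer_states(model, model.policy_set.policies, [outcome])
        efe = expected_free_energy(model, beliefs.s, [1, 2])
        assert np.allclose(
            efe.total, efe.risk + efe.ambiguity - efe.novelty, atol=1e-9
        )
        assert np.all(efe.novelty >= 0)

    def test_zero_concentration_rejected(self, maze8):
        model = build_model(maze8, "novel")
        outcome = (int(maze8.cells.flat[maze8.start]), maze8.start)
        beliefs = infer_states(model, model.policy_set.policies, [outcome])
        with pytest.raises(InvalidArgumentError):
            expected_free_energy(
                model, beliefs.s, [1], a_what=np.zeros_like(model.likelihood.a_what)
            )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_novelty_kernel_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.01, 200.0, size=(2, 8))
        assert np.all(novelty_kernel(a) >= 0)


class TestPolicyPosterior:
    def test_equal_g_uniform(self):
        pi = policy_posterior(np.zeros(25), 1.0)
        assert np.allclose(pi, 1 / 25)

    def test_shift_invariance(self):
        g = np.array([1.0, 3.0, -2.0])
        assert np.abs(policy_posterior(g, 2.0) - policy_posterior(g + 7.0, 2.0)).max() < 1e-12

    def test_large_gamma_concentrates_on_argmin(self):
        g = np.array([1.0, 0.5, 3.0])
        pi = policy_posterior(g, 1e3)
        assert pi[1] > 0.999

    def test_rejects_bad_gamma(self):
        with pytest.raises(InvalidArgumentError):
            policy_posterior(np.zeros(3), 0.0)


class TestUpdatePrecision:
    def test_no_update_when_distributions_match(self):
        pi = np.array([0.3, 0.7])
        beta, gamma = update_precision(np.array([1.0, 2.0]), pi, pi, beta0=1.0)
        assert beta == pytest.approx(1.0, abs=1e-9)

    def test_confidence_rises_when_posterior_prefers_low_g(self):
        g = np.array([1.0, 3.0])
        pi_prior = softmax(-g)
        pi_post = np.array([1.0, 0.0])
        assert (pi_post - pi_prior) @ g < 0
        beta, gamma = update_precision(g, pi_prior, pi_post, beta0=1.0)
        assert gamma > 1.0

    def test_constant_g_keeps_baseline(self):
        g = np.full(5, 2.0)
        pi_prior = softmax(-g)
        pi_post = softmax(-2 * g)
        beta, gamma = update_precision(g, pi_prior, pi_post, beta0=1.0)
        assert gamma == pytest.approx(1.0, abs=1e-6)

    def test_floor_and_warning_when_driven_nonpositive(self):
        g = np.array([10.0, 0.0])
        with pytest.warns(PrecisionFloorWarning):
            beta, gamma = update_precision(
                g, np.array([1.0, 0.0]), np.array([0.0, 1.0]), beta0=1.0
            )
        assert beta > 0


class TestSelectAction:
    def test_single_policy(self):
        assert select_action(np.ones(1), np.array([[2, 4]]), 0) == 2

    def test_shared_first_action(self):
        pols = np.array([[1, 0], [1, 4]])
        assert select_action(np.array([0.5, 0.5]), pols, 0) == 1

    def test_tie_broken_by_action_order(self):
        pols = np.array([[0, 0], [4, 4]])  # up vs stay, equal mass
        assert select_action(np.array([0.5, 0.5]), pols, 0) == 0


class TestLearnLikelihood:
    def test_single_delta_epoch(self):
        a = np.full((2, 4), 0.125)
        s = np.zeros((1, 4))
        s[0, 2] = 1.0
        out = learn_likelihood(a, [(0, 2)], s, eta=1.0)
        assert out[0, 2] == pytest.approx(1.125)
        assert np.sum(out - a) == pytest.approx(1.0)

    def test_increment_mass_is_eta(self):
        rng = np.random.default_rng(0)
        a = np.full((2, 6), 0.125)
        s = rng.dirichlet(np.ones(6), size=3)
        out = learn_likelihood(a, [(0, 0), (1, 0), (0, 0)], s, eta=0.5)
        assert np.sum(out - a) == pytest.approx(3 * 0.5, abs=1e-9)

    def test_counting_oracle_on_scripted_path(self):
        # visiting cell k N times while open must add exactly N * eta
        a = np.full((2, 5), 0.125)
        path = [0, 1, 2, 1, 0, 1]
        outcomes = [(0, loc) for loc in path]
        s = np.zeros((len(path), 5))
        for t, loc in enumerate(path):
            s[t, loc] = 1.0
        out = learn_likelihood(a, outcomes, s, eta=1.0)
        assert out[0, 1] == pytest.approx(0.125 + 3.0)
        assert out[0, 0] == pytest.approx(0.125 + 2.0)
        assert np.all(out[1] == 0.125)


class TestRunTrial:
    def test_trial_shape(self, maze8, config):
        model = build_model(maze8, "novel")
        res = run_trial(model, maze8, maze8.start, config)
        assert len(res.actions) == config.horizon
        assert len(res.path) == config.horizon + 1
        assert len(res.outcomes) == config.horizon + 1

    def test_learning_accumulates_observations(self, maze8, config):
        model = build_model(maze8, "novel")
        res = run_trial(model, maze8, maze8.start, config)
        added = model.likelihood.a_what.sum() - 0.25 * maze8.n_states
        assert added == pytest.approx(config.eta * (config.horizon + 1), abs=1e-6)

    def test_beliefs_reset_between_trials(self, maze8, config):
        model = build_model(maze8, "novel")
        res1 = run_trial(model, maze8, maze8.start, config)
        res2 = run_trial(model, maze8, res1.path[-1], config)
        assert res2.beliefs.s[:, 0, res1.path[-1]].min() > 0.99
        assert model.d[res1.path[-1]] == 1.0
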