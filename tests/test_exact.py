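"""Exact Markov-chain engine: transition matrices and stationary analysis."""

import numpy as np
import pytest

from cssbn import (
    SSDOptions,
    SizeCapError,
    StateDistribution,
    bn_transition_matrix,
    build_glioma_scaffold,
    enumerate_contexts,
    gap_bits,
    generate_random_network,
    instantaneous_stm,
    joint_transition_matrix,
    marginal_gap_distribution,
    perturbed_transition_matrix,
    steady_state,
    transition_probability,
)
from cssbn.exact import Ordering, OrderingError, TransitionMatrix


class TestSingleContextMatrices:
    def test_bn_matrix_is_deterministic_and_stochastic(self, p53):
        ctx = enumerate_contexts(p53)[0]  # (f1, f1)
        tm = bn_transition_matrix(p53, ctx)
        tm.validate()
        assert set(np.unique(tm.entries)) == {0.0, 1.0}
        # GAP 00 -> GAP 10 with probability 1 under (f1, f1)
        assert tm.entries[0, 2] == 1.0

    def test_identity_functions_give_identity_matrix(self):
        from cssbn.model import PBNModel, PredictorFunction

        model = PBNModel(
            ("a", "b"),
            tuple(
                (PredictorFunction(gene=i, inputs=(i,), table=(0, 1), probability=1.0),)
                for i in range(2)
            ),
        )
        tm = bn_transition_matrix(model, enumerate_contexts(model)[0])
        assert np.array_equal(tm.entries, np.eye(4))

    def test_zero_perturbation_limit(self, p53):
        ctx = enumerate_contexts(p53)[5]
        assert np.allclose(
            perturbed_transition_matrix(p53, ctx, p=0.0).entries,
            bn_transition_matrix(p53, ctx).entries,
        )

    def test_perturbed_row_frozen_values(self, p53):
        """Row 00 of context (f1,f1) at p=0.01, from enumerating flip patterns."""
        ctx = enumerate_contexts(p53)[0]
        tm = perturbed_transition_matrix(p53, ctx, p=0.01)
        assert np.allclose(tm.entries[0], [0.0, 0.0099, 0.99, 0.0001], atol=1e-15)

    @pytest.mark.parametrize("p", [0.0, 0.01, 0.3, 0.9, 1.0])
    def test_rows_sum_to_one_for_any_p(self, p53, p):
        ctx = enumerate_contexts(p53)[3]
        perturbed_transition_matrix(p53, ctx, p=p).validate()


class TestJointChain:
    def test_p53_joint_dimensions(self, p53):
        tm = joint_transition_matrix(p53)
        assert tm.entries.shape == (64, 64)
        tm.validate()

    def test_entrywise_agreement_with_transition_probability(self, random_models):
        """Joint matrix entries obey the per-pair transition law."""
        rng = np.random.default_rng(42)
        checked = 0
        for model in random_models[:3]:
            tm = joint_transition_matrix(model)
            k, m = model.context_count, model.n_states
            for _ in range(70):
                s, r = rng.integers(1, k + 1, size=2)
                y, x = rng.integers(1, m + 1, size=2)
                entry = tm.entries[(s - 1) * m + (y - 1), (r - 1) * m + (x - 1)]
                assert entry == pytest.approx(
                    transition_probability((s, y), (r, x), model), abs=1e-12
                )
                checked += 1
        assert checked >= 200

    def test_switch_keep_probability_example(self, p53):
        """Keeping the context combines 1-q with redrawing it: 1-q+q*C_s."""
        value = transition_probability((1, 1), (1, 3), p53, p=0.0, q=0.5)
        assert value == pytest.approx(0.625, abs=1e-12)

    def test_no_switching_blocks_other_contexts(self, p53):
        assert transition_probability((1, 1), (2, 3), p53, q=0.0) == 0.0

    def test_outgoing_probabilities_sum_to_one(self, p53):
        k, m = p53.context_count, p53.n_states
        total = sum(
            transition_probability((3, 2), (r, x), p53)
            for r in range(1, k + 1)
            for x in range(1, m + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_single_context_reduces_to_perturbed_matrix(self):
        model = generate_random_network(n=3, max_functions=1, seed=9, p=0.05, q=0.7)
        tm = joint_transition_matrix(model)
        ptilde = perturbed_transition_matrix(model, enumerate_contexts(model)[0])
        assert np.allclose(tm.entries, ptilde.entries)

    def test_instantaneous_limit_stationary_structure(self, p53):
        """At q=1 the stationary law factorizes as C_r times the PBN's GAP SSD."""
        model = p53.with_rates(q=1.0)
        joint = steady_state(joint_transition_matrix(model)).distribution
        mix = instantaneous_stm(model)
        mu = steady_state(mix).distribution
        c = np.array([ctx.probability for ctx in enumerate_contexts(model)])
        expected = np.kron(c, mu.probs)
        assert np.allclose(joint.probs, expected, atol=1e-7)

    def test_instantaneous_row_matches_brute_force(self, p53):
        """Row 00 mass on GAP 10 = sum of C_j over contexts mapping 00 -> 10."""
        stm = instantaneous_stm(p53, p=0.0)
        mass = 0.0
        for ctx in enumerate_contexts(p53):
            bits = (
                p53.functions[0][ctx.choice[0]].evaluate((0, 0)),
                p53.functions[1][ctx.choice[1]].evaluate((0, 0)),
            )
            if bits == (1, 0):
                mass += ctx.probability
        assert stm.entries[0, 2] == pytest.approx(mass, abs=1e-12)
        assert mass == pytest.approx(0.9801, abs=1e-12)

    def test_size_cap_guard(self):
        with pytest.raises(SizeCapError, match="stochastic"):
            joint_transition_matrix(build_glioma_scaffold())


class TestSteadyState:
    def test_two_state_closed_form(self):
        tm = TransitionMatrix(np.array([[0.9, 0.1], [0.2, 0.8]]), Ordering(1))
        res = steady_state(tm)
        assert res.converged
        assert np.allclose(res.distribution.probs, [2 / 3, 1 / 3], atol=1e-7)

    def test_identity_matrix_returns_initial(self):
        tm = TransitionMatrix(np.eye(4), Ordering(2))
        init = StateDistribution(np.array([0.7, 0.1, 0.1, 0.1]), Ordering(2))
        res = steady_state(tm, SSDOptions(initial=init))
        assert res.converged and res.iterations == 1
        assert np.allclose(res.distribution.probs, init.probs)

    def test_matches_eigensolver_on_p53(self, p53, eig_oracle):
        tm = joint_transition_matrix(p53)
        res = steady_state(tm, SSDOptions(epsilon=1e-10))
        assert np.abs(res.distribution.probs - eig_oracle(tm.entries)).max() < 1e-6

    def test_ergodic_steady_state_strictly_positive(self, random_models):
        for model in random_models[:3]:
            res = steady_state(joint_transition_matrix(model.with_rates(p=0.01)))
            assert (res.distribution.probs > 0).all()

    def test_initial_distribution_irrelevant_when_ergodic(self, p53):
        tm = joint_transition_matrix(p53)
        init = np.zeros(64)
        init[17] = 1.0
        res_a = steady_state(tm, SSDOptions(initial=StateDistribution(init, tm.ordering)))
        res_b = steady_state(tm)
        assert np.allclose(res_a.distribution.probs, res_b.distribution.probs, atol=1e-7)

    def test_non_convergence_reported(self):
        # period-2 chain never meets the threshold
        tm = TransitionMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), Ordering(1))
        init = StateDistribution(np.array([1.0, 0.0]), Ordering(1))
        with pytest.warns(UserWarning, match="did not converge"):
            res = steady_state(tm, SSDOptions(max_iterations=50, initial=init))
        assert not res.converged and res.residual == pytest.approx(1.0)


class TestMarginals:
    def test_uniform_joint_gives_uniform_gaps(self, p53):
        joint = StateDistribution.uniform(Ordering(2, 16))
        gaps = marginal_gap_distribution(joint)
        assert np.allclose(gaps.probs, 0.25)

    def test_point_mass_maps_to_its_gap(self):
        probs = np.zeros(4 * 4)
        probs[2 * 4 + 1] = 1.0  # (ctx 3, GAP 01)
        gaps = marginal_gap_distribution(StateDistribution(probs, Ordering(2, 4)))
        assert np.allclose(gaps.probs, [0.0, 1.0, 0.0, 0.0])

    def test_mass_conserved(self, p53):
        joint = steady_state(joint_transition_matrix(p53)).distribution
        assert marginal_gap_distribution(joint).probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_context_distribution_passes_through(self):
        dist = StateDistribution(np.array([0.4, 0.1, 0.3, 0.2]), Ordering(2))
        assert np.array_equal(marginal_gap_distribution(dist).probs, dist.probs)


def test_p53_oscillation_visible_in_exact_ssd(p53):
    """At small perturbation the antiphase states 01 and 10 dominate 00 and 11."""
    joint = steady_state(joint_transition_matrix(p53)).distribution
    g = marginal_gap_distribution(joint).probs
    assert min(g[1], g[2]) > max(g[0], g[3])
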