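"""Bit-stream circuit engine: one-step law, STM estimation, time-frame SSD."""

import numpy as np
import pytest

from cssbn import (
    RandomSource,
    SSDOptions,
    build_cssbn,
    build_p53_network,
    enumerate_contexts,
    joint_transition_matrix,
    marginal_gap_distribution,
    parse_network,
    perturbed_transition_matrix,
    steady_state,
    vector_norm_diff,
)
from cssbn.circuit import LaneEnsemble


def lanes_at(circuit, context, gap):
    size = circuit.length
    return LaneEnsemble(np.full(size, context), np.full(size, gap))


class TestStep:
    def test_deterministic_context_trajectory(self):
        """With p=0 and q=0, lanes follow the fixed Boolean network exactly."""
        model = build_p53_network(p=0.0, q=0.0)
        circuit = build_cssbn(model, length=1000, source=1)
        nxt = circuit.step(lanes_at(circuit, 0, 0b00))
        assert (nxt.gaps == 0b10).all()
        assert (nxt.contexts == 0).all()

    def test_full_perturbation_complements_every_lane(self):
        model = build_p53_network(p=1.0, q=0.0)
        circuit = build_cssbn(model, length=500, source=2)
        nxt = circuit.step(lanes_at(circuit, 3, 0b01))
        assert (nxt.gaps == 0b10).all()

    def test_instantaneous_switching_redraws_context_each_step(self):
        model = build_p53_network(p=0.0, q=1.0)
        circuit = build_cssbn(model, length=100_000, source=3)
        nxt = circuit.step(lanes_at(circuit, 0, 0))
        freqs = np.bincount(nxt.contexts, minlength=16) / circuit.length
        # permutation-coded selection realizes the context law to rounding error
        assert np.abs(freqs - circuit.context_probs).max() <= 0.5 / circuit.length + 1e-12

    def test_frozen_context_at_q_zero(self):
        model = build_p53_network(p=0.2, q=0.0)
        circuit = build_cssbn(model, length=1000, source=4)
        nxt = circuit.step(lanes_at(circuit, 7, 2))
        assert (nxt.contexts == 7).all()

    def test_one_step_frequencies_match_exact_row(self, p53):
        """Lane-averaged one-step frequencies reproduce the exact transition row."""
        exact = joint_transition_matrix(p53)
        length = 100_000
        circuit = build_cssbn(p53, length=length, source=5, sequence_mode="bernoulli")
        s, g = 2, 1
        nxt = circuit.step(lanes_at(circuit, s, g))
        freqs = np.bincount(nxt.joint_indices(2), minlength=64) / length
        row = exact.entries[s * 4 + g]
        # 4 sigma plus a Poisson small-count slack: 64 simultaneous comparisons
        tol = 4 * np.sqrt(row * (1 - row) / length) + 4 / length
        assert (np.abs(freqs - row) <= tol).all()

    def test_lane_count_mismatch_rejected(self, p53):
        circuit = build_cssbn(p53, length=100, source=0)
        with pytest.raises(ValueError, match="lanes"):
            circuit.step(LaneEnsemble(np.zeros(5, dtype=int), np.zeros(5, dtype=int)))


class TestEstimateSTM:
    def test_rows_are_empirical_frequencies(self, p53):
        """Rows are integer counts over L lanes, so they sum to 1 to round-off."""
        length = 2000
        stm = build_cssbn(p53, length=length, source=6).estimate_stm()
        counts = stm.entries * length
        assert np.allclose(counts, np.rint(counts), atol=1e-9)
        assert np.rint(counts).sum(axis=1).tolist() == [length] * 64

    def test_deterministic_circuit_recovers_exact_matrix(self):
        model = build_p53_network(p=0.0, q=0.0)
        doc_model = model.with_rates(q=0.0)
        circuit = build_cssbn(doc_model, length=50, source=7)
        stm = circuit.estimate_stm()
        # no randomness at p=0, q=0: estimated matrix is exactly the 0/1 law
        exact = joint_transition_matrix(doc_model)
        assert np.array_equal(stm.entries, exact.entries)

    def test_estimate_approaches_exact_with_length(self, p53):
        exact = joint_transition_matrix(p53)
        errs = []
        for length in (1000, 10_000):
            stm = build_cssbn(p53, length=length, source=8).estimate_stm()
            errs.append(np.abs(stm.entries - exact.entries).max())
        assert errs[1] < errs[0]


class TestTimeFrame:
    def test_absorbing_toy_network_collapses(self):
        doc = {
            "genes": ["g"],
            "p": 0.0,
            "q": 1.0,
            "functions": {"g": [{"inputs": ["g"], "table": "11", "prob": 1.0}]},
        }
        model = parse_network(doc)
        circuit = build_cssbn(model, length=200, source=9)
        result = circuit.estimate_ssd_time_frame(SSDOptions(epsilon=1e-6, max_iterations=50))
        assert result.converged
        assert np.array_equal(result.distribution.probs, [0.0, 1.0])

    def test_distribution_is_normalized_counts(self, p53):
        length = 5000
        circuit = build_cssbn(p53, length=length, source=10)
        result = circuit.estimate_ssd_time_frame(
            SSDOptions(epsilon=5e-3, max_iterations=100)
        )
        counts = result.distribution.probs * length
        assert np.allclose(counts, np.rint(counts), atol=1e-9)
        assert np.rint(counts).sum() == length

    def test_gap_marginals_close_to_exact(self, p53):
        exact_gaps = marginal_gap_distribution(
            steady_state(joint_transition_matrix(p53)).distribution
        )
        circuit = build_cssbn(p53, length=100_000, source=11)
        result = circuit.estimate_ssd_time_frame(
            SSDOptions(epsilon=1e-3, max_iterations=300)
        )
        est_gaps = marginal_gap_distribution(result.distribution)
        assert vector_norm_diff(est_gaps, exact_gaps, "infinity") < 0.01

    def test_two_routes_agree(self, p53):
        """Time-frame SSD and STM-then-power-iteration SSD are estimates of the
        same stationary law and agree within combined Monte-Carlo tolerance."""
        circuit_a = build_cssbn(p53, length=50_000, source=12)
        via_frames = marginal_gap_distribution(
            circuit_a.estimate_ssd_time_frame(
                SSDOptions(epsilon=1e-3, max_iterations=300)
            ).distribution
        )
        circuit_b = build_cssbn(p53, length=10_000, source=13)
        via_stm = marginal_gap_distribution(
            circuit_b.ssd_from_estimated_stm().distribution
        )
        assert vector_norm_diff(via_frames, via_stm, "infinity") < 0.015


class TestSSDFromSTM:
    def test_deterministic_circuit_gives_exact_ssd(self):
        doc = {
            "genes": ["g"],
            "p": 0.0,
            "q": 1.0,
            "functions": {"g": [{"inputs": ["g"], "table": "10", "prob": 1.0}]},
        }
        model = parse_network(doc)  # 0 <-> 1 oscillator has uniform time average
        circuit = build_cssbn(model, length=100, source=14)
        stm = circuit.estimate_stm()
        assert np.array_equal(stm.entries, [[0.0, 1.0], [1.0, 0.0]])

    def test_norm_error_decreases_with_length_on_seed_average(self, p53):
        exact = steady_state(joint_transition_matrix(p53)).distribution
        mean_err = []
        for length in (1000, 10_000):
            errs = [
                vector_norm_diff(
                    build_cssbn(p53, length=length, source=seed)
                    .ssd_from_estimated_stm()
                    .distribution,
                    exact,
                    "one",
                )
                for seed in range(3)
            ]
            mean_err.append(np.mean(errs))
        assert mean_err[1] < mean_err[0]


def test_bounded_switching_influence(p53):
    """Varying q moves the p53 GAP SSD far less than varying p."""

    def gap_ssd(p, q):
        model = build_p53_network(p=p, q=q)
        return marginal_gap_distribution(
            steady_state(joint_transition_matrix(model)).distribution
        ).probs

    over_q = np.ptp([gap_ssd(0.01, q) for q in (0.5, 0.8, 0.9, 1.0)], axis=0).max()
    over_p = np.ptp([gap_ssd(p, 0.9) for p in (0.01, 0.1, 0.3)], axis=0).max()
    assert over_q < over_p
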