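"""Exact steady state of the p53-Mdm2 network.

Builds the 64x64 joint (context, GAP) transition matrix at perturbation
rate p = 0.01 and switching probability q = 0.9, finds the stationary
distribution by power iteration, and collapses it onto the four GAPs.
"""

from cssbn import (
    build_p53_network,
    gap_bits,
    joint_transition_matrix,
    marginal_gap_distribution,
    steady_state,
)

model = build_p53_network(p=0.01, q=0.9)
matrix = joint_transition_matrix(model)
result = steady_state(matrix)
gaps = marginal_gap_distribution(result.distribution)

print(f"joint chain: {matrix.ordering.size} states, "
      f"converged in {result.iterations} iterations (residual {result.residual:.2e})")
print("stationary GAP probabilities (p53 bit first):")
for d, prob in enumerate(gaps.probs, start=1):
    bits = "".join(map(str, gap_bits(d, model.n)))
    print(f"  GAP {bits} (d={d}): {prob:.4f}")
print("-> the antiphase states 01 and 10 dominate: p53 high while Mdm2 is low")
print("   and vice versa, the signature of the p53-Mdm2 oscillation.")
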