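"""Steady state by time-frame expansion.

Instead of materializing a transition matrix, the circuit iterates its
one-step logic over successive time frames; the lane ensemble's empirical
distribution converges to the stationary law.  This is the route that
scales to networks whose joint matrix is infeasible (the 14-gene glioma
chain would need a 6,291,456-dimensional matrix).
"""

from cssbn import (
    SSDOptions,
    build_cssbn,
    build_p53_network,
    joint_transition_matrix,
    marginal_gap_distribution,
    steady_state,
    vector_norm_diff,
)

model = build_p53_network(p=0.01, q=0.9)
exact_gaps = marginal_gap_distribution(
    steady_state(joint_transition_matrix(model)).distribution
)

circuit = build_cssbn(model, length=100_000, source=7)
result = circuit.estimate_ssd_time_frame(SSDOptions(epsilon=1e-3, max_iterations=300))
gaps = marginal_gap_distribution(result.distribution)

print(f"time-frame expansion: {result.frames} frames at L = {circuit.length} lanes, "
      f"residual {result.residual:.2e} (converged: {result.converged})")
print("GAP            simulated   exact")
for d, (sim, ref) in enumerate(zip(gaps.probs, exact_gaps.probs), start=1):
    print(f"  d={d}          {sim:.4f}      {ref:.4f}")
print(f"max abs deviation: {vector_norm_diff(gaps, exact_gaps, 'inf'):.4f}")
print("-> the empirical stationary law tracks the exact one within Monte-Carlo")
print("   noise of order L^-1/2, without ever forming the 64x64 matrix.")
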