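# Methods

## Model and assumptions

`cssbn` analyses context-sensitive probabilistic Boolean networks
(CSPBNs): `n` binary genes, per-gene predictor sets with selection
probabilities, a context (one predictor per gene) held between random
switches, per-gene state perturbation, and optional external intervention.
The update order within one time step is fixed: **function evaluation →
perturbation override → context switch → intervention**.  In particular
the network function is applied in the *source* context and the context
switches afterwards; when a switch occurs the new context is drawn from
the full selection distribution `{C_j}`, so the current context can be
re-selected and the total probability of keeping context `s` is
`1 − q + q·C_s`.

Perturbation follows the standard PBN convention: each gene flips
independently with probability `p`, and any non-empty flip pattern
*replaces* the function update rather than composing with it.  The
single-context matrix with perturbation is therefore

    P̃_s[y, x] = (1−p)^n · 1[f_s(y) = x] + p^h (1−p)^(n−h) · 1[h ≥ 1],

with `h` the Hamming distance between GAPs `y` and `x`.  Rows sum to 1 by
the binomial identity.  For `p > 0` every state communicates with every
other, the joint chain is ergodic, and the steady state is unique and
strictly positive.

State conventions: gene 1 is the most significant bit of the GAP; GAPs are
reported with the 1-based decimal index `d = Σ 2^(n−j) x_j + 1`; joint
states are ordered context-major (`(ctx−1)·2^n + d`).  Matrices are
row-stochastic with rows as sources (a transposed writer exists for the
other convention).

## Exact engine

`joint_transition_matrix` materializes the `(2^n·k) × (2^n·k)` chain in
context blocks `P̃_s · ((1−q)[r=s] + qC_r)`.  A memory guard refuses
matrices above 2^22 entries (≈ 2048×2048) by default and points to the
bit-stream engine; the 14-gene glioma chain (6,291,456 states) is the
canonical case past the cap.  The steady state is computed by power
iteration with defaults `ε = 1e−8`, at most 10,000 iterations, uniform
start.  The iteration count needed in practice is small (about 70 for the
p53-Mdm2 chain at `p = 0.01, q = 0.9`); the tight default threshold costs
little and removes iteration error from downstream comparisons.
Non-convergence (possible only for `p = 0` chains with periodic
structure) is reported, never silently accepted.  Tests cross-check the
power iteration against a dense left-eigenvector solve.

## Bit-stream engine

Each bit position of the stochastic sequences is one independent
Monte-Carlo lane carrying the full joint sample (context label + GAP), so
gene-to-gene correlation within a lane is preserved by construction.
Contexts ride along as integer labels; the behaviour is identical to
decoded select lines but far cheaper.  Control sequences are redrawn at
every time frame.

Two sequence modes:

* `bernoulli` — every control bit (switch `Q`, context selection,
  perturbation `γ_i`) drawn independently.  Estimation error scales as
  `L^(−1/2)` (the regression slope of log error on log `L` is ≈ −0.5 in
  the test suite).
* `permutation` (default) — probability-encoding sequences carry exact
  fixed counts: `Q` has exactly `round(q·L)` ones, context labels are
  realized with largest-remainder counts, and each `γ_i` has exactly
  `round(p·L)` ones.  This removes the count variance of every marginal
  encoding.

**STM estimation.** Each row of the joint matrix is estimated by starting
all `L` lanes in that state and advancing one frame; rows are integer
counts over `L`.  In permutation mode the row generator goes one step
further: since all lanes of a row share one input state, the joint law of
the row's control tuple — perturbation pattern crossed with the
keep/switch outcome — is a known product distribution over
`2^n · (k + 1)` cells, and it is realized with *stratified* fixed counts
(floor of `prob·L` per cell plus unbiased randomized remainders, every
cell within one lane of its expectation).  This is the fixed-count
encoding applied to the whole control bundle instead of to each sequence
separately; it removes the random cross-association between independently
generated sequences and empirically drops the p53-Mdm2 `L = 10k`
steady-state relative error from a mean of ≈ 0.18% to ≈ 0.06% (worst seed
of 40: 0.11%), with convergence faster than `L^(−1/2)`.  Bernoulli mode
keeps the classical independent-draw estimator.

**Steady states.** Two routes: (i) estimate the STM, then run the exact
engine's power iteration on it — the most accurate route at a given `L`
and the one behind the ≤ 0.2% relative-error figure; (ii) time-frame
expansion — iterate the circuit and stop when consecutive empirical joint
distributions differ by less than `ε` in the infinity norm.  The
time-frame default is `ε = 1e−3` with a 500-frame cap: an empirical
distribution cannot beat its own Monte-Carlo noise floor of order
`L^(−1/2)`, so the exact engine's `1e−8` default would never be met.
Lanes are initialized with largest-remainder fixed counts from the initial
distribution (deterministic, zero-variance; a random multinomial draw
would only add noise).

## Intervention

An intervention is a control gene plus a vector `u` over GAPs; `u = 1`
flips the control gene's bit after the transition.  Undesirability is a
property of the GAP across *all* contexts (context is hidden in practice;
expression is observable).  The implemented policy, `flip-on-undesirable`,
marks exactly the GAPs where the target gene is at the undesired level;
user-supplied `u` vectors are accepted for research use.  In the exact
engine the intervention composes onto each context's perturbed matrix as a
deterministic post-transition map (right-multiplication by a 0/1 matrix);
in the circuit it is a stage after the perturbation multiplexer.  Direct
control of the target under this policy confines the stationary support to
desirable GAPs (mass 1); indirect control carries no guarantee and can
even lower the desirable mass, which is why `evaluate_control_genes`
scans candidates against a no-intervention baseline.

## Fixtures and the synthetic generator

* **p53-Mdm2** (2 genes, 4 predictors each, 16 contexts): predictor truth
  tables encode the mutual antagonism driving the p53-Mdm2 oscillation;
  selection probabilities (0.5, 0.4, 0.09, 0.01 per gene) concentrate mass
  on the oscillatory predictors.  Default operating point `p = 0.01`,
  `q = 0.9`, the most-studied setting for this network.
* **Glioma scaffold** (14 genes, 384 contexts, 16,384 GAPs): the published
  per-gene selection probabilities are built in; the Boolean truth tables
  were inferred from expression data and are not public, so they must be
  supplied by the caller.  Without them each predictor defaults to the
  identity function and the model carries a `topology_incomplete` flag:
  context counts and context-mass computations are exact, dynamics are
  placeholders, dynamic APIs log a warning, and the intervention scanner
  refuses the scaffold unless forced.  Defaults `p = 0.001`, `q = 0.99`
  (the intervention-analysis setting).
* **Random networks** (`generate_random_network`): predictor tables drawn
  uniformly over all `2^n` input rows, per-gene predictor counts uniform
  on `1..max_functions`, selection probabilities positive (bounded away
  from 0 by 0.05 before normalization) and summing to 1 exactly.  Defaults
  `p = 0.01`, `q = 0.9` to match the fixture operating point.  Seeded and
  reproducible.  These models emulate the *structure* of inferred PBNs,
  not their biology: random truth tables have no attractor organization,
  canalization or degree sparsity, so tests passing on them demonstrate
  correctness of the probabilistic machinery, not biological fidelity.

## Numerical choices

* Probability validation tolerance `1e−9` throughout (per-gene selection
  probabilities, context totals, row sums); validation errors are raised,
  never silently renormalized.
* Ones-count rounding for fixed-count sequences: round-half-to-even of
  `prob·L`, unbiased over probability grids.
* Ties in context ranking (`top_context_mass`) broken stably by
  enumeration order (lexicographic in per-gene predictor indices).
* Degenerate inputs: `k = 1` joint distributions are accepted as already
  GAP-marginal; `q = 0` freezes each lane's context; `p = 0` makes the
  permutation-mode estimator exact for deterministic circuits.
* Matrix 2-norm is the spectral norm (largest singular value); for
  distributions the 2-norm is Euclidean.  The 1- and infinity norms are
  the maximum column and row sums of the absolute difference.

## Problem sizes

The shipped tests and the reproduction script run the p53-Mdm2 network
(64 joint states) with sequence lengths up to `10^5`, random models up to
4 genes, and the glioma scaffold only through its selection-probability
layer; these sizes exercise every code path while keeping the full suite
in the tens of seconds.  The engines themselves accept any model within
the documented memory guards.

## Known limitations

* The glioma scaffold cannot reproduce published glioma steady-state or
  intervention percentages without the non-public truth tables; nothing in
  the package pretends otherwise.
* Only the function-first-then-switch update order is implemented; the
  switch-first variant is out of scope.
* The intervention policy is the documented heuristic, not an optimal
  finite- or infinite-horizon control; the policy interface accepts
  externally derived `u` vectors.
* Synchronous, binary-valued updates only: no asynchronous schedules, no
  multi-valued gene states.
* The minimum sequence length needed for a target accuracy is left to the
  user (the error-versus-`L` trend is exposed by the metrics module); no
  automatic calibration is provided.
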