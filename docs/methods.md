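# Methods

## Scope and model

`methylnet` analyses the web of linear dependences among the CpG dinucleotides
of an epigenetic clock.  The working assumptions are:

- **Clock transform.**  DNAm age follows the piecewise clock transform with
  adult threshold `a_t` (default 20 years): linear in the weighted methylation
  score above the threshold, exponential below, continuous at the joint.  The
  transform is implemented exactly as stated, with no global intercept; a user
  wanting an extra intercept can add a constant pseudo-CpG to the clock.
- **Network model.**  Each CpG's beta value is a sparse linear combination of
  the others, `m_j = sum_{i != j} beta_ji m_i + beta_0`, fitted per response
  node by cross-validated Lasso.  A non-zero coefficient defines a directed
  link `i -> j` with sign `beta_ji` and weight `|beta_ji|`.
- **Linear response.**  Perturbation propagation treats the fitted
  coefficients as a local linear response: a shift at one CpG moves its
  out-neighbours by `beta * delta_m`, and chains of links contribute products
  of coefficients.  Perturbed values are not clipped to [0, 1] — the model is
  a local linearisation, not a bounded simulator — and the adult (linear)
  branch of the clock is assumed throughout the perturbation analysis.

## Network inference

Per-response Lasso-CV uses scikit-learn's `LassoCV` with a log-spaced penalty
grid of 100 points spanning three decades below the data-driven maximum
(`eps = 1e-3`), 10 folds by default, and a seeded per-sample fold-assignment
array shared across all responses, which makes a network build reproducible
and invariant to sample reordering under a fixed assignment.  Predictors are
**not** standardized: beta values already share the [0, 1] scale, and link
weights are compared across node pairs, which per-feature standardization
would distort.  A `standardize` flag exists for sensitivity analysis.

### What the coefficients can and cannot identify

Neighbourhood regression estimates conditional dependence.  In
unit-variance-scaled coordinates the coefficient of `i` in the model for `j`
and of `j` in the model for `i` have provably equal magnitude (both reduce to
the scaled precision-matrix entry), so the *direction* of an underlying causal
link is not identifiable from the weights, and colliders (two parents of a
common child) induce genuine conditional dependence between unlinked nodes.
Accuracy against a planted directed network is therefore scored on the
*skeleton*: a node pair counts as detected when either direction's inferred
weight reaches a detection threshold.  That threshold (0.15) was calibrated
once on pilot cohorts at the reference conditions to sit between the
attenuated true-edge weights (median ≈ 0.25) and the collider-induced spurious
weights (95th percentile ≈ 0.10); at those conditions mean skeleton precision
and recall over 20 cohorts are ≈ 0.86 and ≈ 0.93.

### Sparsification

The raw graph is dense (the cross-validated penalty is prediction-optimal,
not selection-optimal).  A weight threshold `w*` is chosen to maximise
`J = (E_g + E_l) / rho_L`, where `E_g` is the mean inverse directed
shortest-path length over ordered pairs (unreachable pairs contribute 0),
`E_l` averages `E_g` over each node's neighbour subgraph, and `rho_L` is the
link density.  Numerical choices: shortest paths are unweighted and directed;
the neighbour set is the union of in- and out-neighbours with the centre node
removed (an out-neighbours-only mode is available); subgraphs with fewer than
two nodes contribute zero; the default candidate grid is 200 evenly spaced
values between the smallest and largest observed weight; candidates that
empty the graph are excluded from the argmax; ties break toward the smaller
(denser) threshold.

## Hierarchy

The `m`-reach of a node is the fraction of the *other* `N - 1` nodes reachable
by directed paths of length at most `m` (the denominator excludes the node
itself, consistent with top nodes "reaching ~95% of the other nodes").
`GRC(m)` averages the gap to the maximal reach; `m = 3` is the default
horizon.  Hierarchical levels are assigned greedily down the sorted reach
values: a node joins the current level while its gap to the level's maximum is
below one tenth of the standard deviation (sample convention) of all reach
values.

Significance is judged against a configuration-model null: repeated two-link
end swaps (`a->b, c->d  ->  a->d, c->b`), rejecting swaps that would create
self-loops or duplicate links, so every sample is a simple digraph with both
degree sequences preserved exactly (asserted on every call).  The accepted
swap budget is 10 per link; the default ensemble is 1,000 samples for
desk-scale runs (20,000 is feasible where time allows).  The empirical
upper-tail p-value uses the add-one rule.  For degree sequences that pin the
graph down entirely (e.g. an out-star) no valid swap exists: the standalone
randomizer raises `RigidGraphError`, while the null ensemble treats each
sample as the unchanged graph, yielding a zero-variance null that is flagged
`degenerate` instead of producing a z-score.

## Control

Link weights are irrelevant for structural controllability, so the analysis
is purely combinatorial.  `C(i)` is computed by taking the subgraph reachable
from `i`, attaching an auxiliary external source `s -> i`, mapping every link
`u -> v` to an (out-copy, in-copy) pair of a bipartite graph, and counting the
links of a maximum matching (scipy's augmenting-path matcher, Hopcroft–Karp
complexity class).  The external link participates in the matching — the
inclusive convention, under which a node always at least controls itself
(`C >= 1`) and the head of a directed path controls the whole path; the
exclusive variant sits behind `include_external=False`.  Relative control
centrality divides by the *full* network's `N`, not the reachable subgraph
size.  The sweep average `<c>(i)` is the mean of `c(i)` over 60 evenly spaced
thresholds in [0.04, 0.1] applied to the unthresholded network; all `N` nodes
remain in every thresholded graph, so isolated nodes contribute `1/N`.

## Perturbation propagation

The nested neighbour sums of the age derivative are **walk sums** — the
expansion places no distinctness constraint on indices — so the effective
coefficient of `i` on `j` is `sum_{l=1}^{l_max} (B^l)_{ji}`, computed by
repeated sparse matrix–vector products (never dense powers).  A simple-path
mode (no repeated nodes) exists for sensitivity analysis; the two agree on
DAGs.  Defaults: `l_max = 4`; `l_max = 0` reproduces the isolated-CpG
response `(a_t + 1) H_i`.  The perturbation size is `delta_m = 2 <sigma(m)>`
with the per-CpG standard deviation taken in the sample (n−1) convention —
immaterial at hundreds of samples, fixed for reproducibility.  Signed
`delta_a` and `|delta_a|` are both reported; the sign of `delta_m` that
*reduces* age is exposed alongside.  Displacement geometry projects the
perturbation vector onto the clock direction `H`; a zero displacement (only
possible when the cohort has zero variance) flags the angle as undefined
rather than dividing by zero.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

- ages uniform in [19, 101] (the reference cohort's range);
- a random directed *acyclic* coefficient matrix `B` at the requested density
  — the DAG default guarantees a well-defined solve order and finite walk
  sums; a cyclic mode exists and rejects draws with spectral radius ≥ 1;
- entry magnitudes uniform in [0.5, 1.5] × `coefficient_scale`
  (default scale 0.4, giving planted coefficients of 0.2–0.6, comparable to
  the strong links of fitted networks) with random sign;
- per-CpG baselines uniform in (0.2, 0.8) and age slopes uniform within
  ±5·10⁻⁴ per year, i.e. up to ±0.04 methylation over an 80-year span —
  an individually weak, collectively informative age signal, matching how
  clock CpGs behave;
- Gaussian noise (default sd 0.02), then an affine rescale of each CpG into
  [0.05, 0.95].  Rescaling rather than clipping keeps the model exactly
  linear, so the planted coefficients transform exactly
  (`B'_{ji} = a_j B_{ji} / a_i`) and remain a valid ground truth.

A linear-branch clock is fitted to the adult (> `a_t`) subsample by ridge-
stabilised least squares (`ridge = 1e-10`, minimum-norm behaviour on
rank-deficient designs, which are flagged with a warning); its RMSE against
the true ages is recorded on the cohort object.

What the generator does **not** emulate: array technical artifacts (dye bias,
detection failures, batch effects), non-linear or threshold dependences
between CpGs, cyclic feedback (by default), and realistic age distributions
beyond uniform.  Tests passing on synthetic cohorts therefore validate the
*algorithms* — inference, thresholding, hierarchy, control, propagation —
under the model's own assumptions, not the biological fidelity of any
particular real-data result.

## Problem sizes and defaults

Reference synthetic conditions: 30 CpGs × 600 samples, edge density 0.05,
noise sd 0.02, 10-fold CV; the support-recovery experiment uses 20 cohorts.
Hierarchy nulls default to 1,000 samples; the control sweep to 60 thresholds
in [0.04, 0.1]; ranking to top-20.  These sizes make a full pipeline run plus
the recovery experiment complete in about a minute on one CPU while keeping
all ensemble statistics stable to well under their assertion margins.

## Known limitations

- Directed-edge identification is impossible for the estimator class (see
  above); reported networks should be read as conditional-dependence
  structures with signs, not causal arrows.
- The efficiency-optimal threshold depends on the candidate grid resolution
  near the optimum; the scan object exposes the full `J(w*)` curve so the
  sensitivity is visible.
- The cross-validated penalty is prediction-optimal, so small spurious
  coefficients survive in the unthresholded network by design; downstream
  analyses always operate on the thresholded backbone.
- With few samples per fold the CV curve is noisy and fitted networks vary
  with the fold seed; all seeds are recorded in run manifests.
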