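# Methods

## Model and assumptions

The enhancement model treats a preprocessed scCAS matrix **X** ∈ ℝ^{m×n}
(peaks × cells, non-negative) as jointly explained by (i) a smoothing of each
cell over its similar cells, **X**(**Z**∘**R**), and (ii) a low-rank
non-negative factorization **WH**. The objective

F(**W**,**H**,**Z**) = ‖X(Z∘R) − WH‖² + λ‖Z − HᵀH‖² + γ₁‖W‖² + γ₂‖H‖²,
all factors ≥ 0,

ties the similarity matrix to the embedding (similar cells have similar
embedding vectors, hence large inner products HᵀH) while the random binary
mask **R** keeps the smoothing from making similar cells identical. The
enhanced matrix is **X·Z** with the converged, column-stochastic **Z**.
Assumptions worth keeping in mind: accessibility is treated as strandless and
near-binary; cells are exchangeable (no batch or trajectory structure); and
enhancement is linear in the observed cells, so a population entirely absent
from the data cannot be recovered.

## Optimization

All three factors are updated once per iteration (W, then Z, then H) by
projected gradient descent.

* **W and Z steps.** The loss restricted to a line along the gradient is an
  exact parabola, so the step is computed in closed form as a trace ratio.
  For Z this printed ratio is the exact minimizer. For W the classical
  printed form treats the ridge term γ₁‖W‖² as constant in the step; this
  package includes the term's step-dependence (denominator
  ‖D₁H‖² + γ₁‖D₁‖², plus the anchoring contribution in the reference
  variant), which is the exact 1-D minimizer of the full objective and
  coincides with the classical form at γ₁ = 0. Tests verify both the
  grid-scan optimality and the γ₁ = 0 reduction.
* **Projection.** After each step the factor is clipped at zero. Because the
  projection can break the descent guarantee of an exact line minimizer, the
  post-projection loss is always evaluated and the step halved until the loss
  does not increase; a step size that is non-positive (possible only through
  projection interactions) is skipped for that iteration with a warning.
  The loss trace is therefore non-increasing by construction, and this is the
  invariant the test suite asserts.
* **H step.** The restriction along the H gradient is quartic (H appears in
  HᵀH twice), so no closed form exists; H backtracks from δ₃ = 0.2, halving
  until the loss strictly decreases or the step falls below 10⁻¹⁰, in which
  case H is left unchanged for that iteration.
* **Stopping.** Iterations stop when the relative loss change falls below
  `tol` (default 10⁻⁶; an absolute mode is available) or at `max_iter`
  (default 100). The trace-form loss is evaluated through the cached n×n Gram
  matrix XᵀX so no m×n intermediate is ever formed; one iteration costs
  O(n³ + kmn).

## Initialization and randomness

**Z** starts from the column-normalized Jaccard similarity of the binarized
cells; (**W**, **H**) from scikit-learn's coordinate-descent NMF with NNDSVDa
initialization (deterministic given its seed). The mask **R** is sampled once
per fit — i.i.d. Bernoulli(mask_p), default mask_p = 0.8 — and held fixed so
the objective is stationary during optimization; resampling per iteration
would change the objective under the optimizer. Independent child seeds for
the NMF, the mask and the reference NMF are derived from the user seed via
`numpy.random.SeedSequence`, so the plain and reference fits see identical
streams where their computations coincide. Given identical inputs, parameters
and seed, the fit is bitwise reproducible.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| k | user-supplied (≥ 2) | latent programs; in practice the number of cell types. Small k over-smooths, very large k admits noise. A label count is used when labels are given. |
| λ | 10⁶ | weight of the similarity-consistency term; the model is robust over several orders of magnitude, so the conventional default is kept. |
| γ₁, γ₂ | 1.0 | ridge penalties on W and H; no canonical values exist, so a neutral unit weight is used and exposed. |
| mask_p | 0.8 | Bernoulli rate of R; unspecified by convention, 0.8 retains most similarity signal while still decorrelating near-duplicate cells. |
| tol | 10⁻⁶ | relative loss-change stopping threshold. |
| δ₃ init | 0.2 | initial backtracking step for H. |
| k₁/k₂, α | k₁ = min(s, k−2), α = 1 | anchored/free split and anchoring weight of the reference variant; at least two free components are always kept so target-specific structure can be learned. |

## Reference variant

The reference model splits W into an anchored block W₁ (first k₁ columns,
initialized to and pulled toward P = NMF(reference, k₁)) and a free block W₂.
Internally the two blocks live in one m×k matrix and are updated jointly with
the same exact line search (the anchoring adds α‖D on the anchored block‖² to
the curvature); the explicit complementary-mask formulation (M∘W₁ + N∘W₂) is
kept as a validation surface and tested to equal the concatenation form, and
all four block gradients are checked against finite differences. Because the
plain fit and the reference fit share one engine, the degenerate reference
(no anchored columns, α = 0) reproduces the plain fit bitwise — a wiring
invariant the tests assert.

Reference profiles are TF-IDF transformed (samples as columns) before the
NMF: raw pseudo-bulk sums are orders of magnitude larger than the TF-IDF
target entries, and anchoring across incommensurate scales would make
α meaningless. Initialization detail: the target NMF is run at the full rank
k and its first k₁ columns are then overwritten by P, so H starts consistent
with the free block.

## Synthetic data

The generator emulates a discrete-population scCAS experiment: K clusters
(default 5 × 500 cells) each with a disjoint block of marker peaks (default
3000) open with probability 0.5 in their own cluster and 0.02 elsewhere, plus
2000 shared peaks open everywhere at the marker rate (housekeeping-like, no
cluster signal). Per-cell capture efficiency is lognormal(−0.3, 0.3) clipped
at 1 and applied as binomial thinning of the binary truth; dropout corruption
zeroes surviving non-zeros independently. These rates were chosen once as
plausible for a well-powered discrete simulation — markers detectable but far
from saturated, background at typical noise floor — and are not tuned per
experiment. What the generator does **not** model: continuous trajectories,
batch effects, read-level fragment structure, GC/mappability biases, and
peak-length variation. Passing recovery tests on this generator therefore
demonstrates correctness of the machinery on well-separated discrete
populations, not performance on real tissues.

Differential accessibility on the truth layer uses a group-mean-difference
score (mean within the group minus mean outside), which recovers disjoint
planted marker blocks exactly in the noiseless limit.

## Evaluation choices

Clustering uses Louvain (networkx, seeded) on the symmetrized 15-nearest-
neighbor graph of a 50-component PCA embedding, with the resolution
binary-searched in [0, 3] (≤ 50 probes) until the community count matches the
known type count; ties return the lower resolution and a mismatch is flagged,
never silent. The silhouette uses 1 − Pearson correlation between cells as
the distance, with cell-type labels as the cluster assignment; undefined
correlations from constant profiles become distance 1 with a warning.
auPRC/auROC treat each cell's (or peak's) enhanced values as a ranking of the
binary truth; single-class units are skipped and counted in the report.
The imbalance degree I = 1 + (1/log C) Σ (n_c/N) log(n_c/N) uses natural
logs (base-invariant) and the 0·log 0 = 0 convention; C = 1 requires an
explicit type inventory because the normalization degenerates.

## Numerical and degenerate-input conventions

* Peak filter: keep iff open in ≥ ceil(fraction·n) cells (inclusive
  boundary); "fewer than 1%" default fraction 0.01.
* TF-IDF: natural log; by default the IDF occurrence counts cells with any
  signal (binarized), which guarantees non-negativity as the NMF requires;
  a flag restores the literal count-sum denominator, which can go negative on
  multi-count data and then triggers a warning. Zero entries stay exactly
  zero in either dialect. A peak open in every cell gets IDF 0.
* Z columns: normalized to sum 1 at initialization and at output; during
  iterations Z evolves freely under non-negativity because renormalizing each
  step would invalidate the closed-form Z step. An all-zero output column
  falls back to the identity column.
* Degenerate line-search directions (zero curvature) raise a structured error
  in the public step functions and are skipped with a warning inside a fit,
  which never aborts mid-optimization.
* Loss-trace comparisons use the exact computed values; ties (no accepted
  update) are legal and stop the fit via the tolerance test.

## Problem sizes used in the tests

The recovery benchmarks run at desk scale — 5 clusters × 100 cells, 500
markers per cluster plus 500 shared peaks (3000 × 500 after filtering), 60%
dropout, five seeds — chosen as the smallest design that keeps the planted
clusters well separated under heavy corruption. The simulation-design check
(union of top-3000 DA lists = 15,000) runs at the full default scale of
2500 cells × 17,000 peaks. Oracle checks (finite differences, grid scans)
use 6×5 instances with k = 2 where exhaustive scans are cheap.

## Known limitations

* The optimizer is a block descent to a local minimum; different seeds give
  different (all monotone) traces.
* Z is dense n×n, so memory scales quadratically in cells; the implementation
  targets datasets up to a few thousand cells.
* The closed-form steps assume the mask R fixed; adaptive or per-iteration
  masks are deliberately unsupported.
* Estimating k is the user's problem in principle; k comes from the user or
  the label count. `estimate_k_eigengap` offers a coarse spectral fallback
  (largest eigengap of the normalized Jaccard matrix) and warns that it is a
  heuristic, not a substitute for a dedicated cell-type-number estimator.
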