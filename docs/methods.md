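# Methods

## Model

Given a nonnegative cells × genes matrix X with n cells and a target cluster
count c, the method builds m = 3 kernel views and clusters a learned fusion
of two n × n graphs.

**Views.** V⁽¹⁾ = (γ⟨x_i,x_j⟩ + c₀)^d (polynomial), V⁽²⁾ =
exp(−‖x_i−x_j‖²/2σ²) (Gaussian, unit diagonal), V⁽³⁾ = ⟨x_i,x_j⟩ (linear).
No kernel centering or normalization is applied; each view's geometry is the
kernel-induced metric d²_ij = K_ii + K_jj − 2K_ij (an alternative
`kernel_as_features` mode treats kernel rows as feature vectors).

**Adaptive KNN graphs.** For each cell, the k nearest cells (ties broken by
index) get weights S_ij = (d_{i,k+1} − d_ij) / (k d_{i,k+1} − Σ_{h≤k} d_ih);
rows lie on the probability simplex with ≤ k nonzeros, are scale invariant in
the distances, and degenerate rows (k+1 equal distances) fall back to uniform
1/k. The denominator fixes the per-row regularizer α_i = (k d_{i,k+1} −
Σ_{h≤k} d_ih)/2 reused by stage 1.

**Stage 1 (attribute graph U).** Alternating minimization of

J = Σ_v Σ_ij d^v_ij S^v_ij + Σ_{v,i} α^v_i ‖s^v_i‖² + Σ_v ‖S^v − U‖_F
    + λ Σ_ij ‖f_i − f_j‖² U_ij,

over simplex rows of the S^v (restricted to their initial KNN supports), the
consensus U (support = union of view supports per row), and the orthonormal
embedding F (c smallest Laplacian eigenvectors of (U+Uᵀ)/2). The unsquared
consensus norm is minimized via iterative self-weighting: w_v =
1/(2‖U − S^v‖_F) recomputed at the current iterate turns each weighted
least-squares pass into a majorize–minimize step, so J is non-increasing at
fixed λ. For that reason the weights are refreshed both before the S-update
and before the U-update each iteration; both are evaluations of the same
closed form. Row updates are simplex projections (Duchi et al. 2008) of
(w_v u_i − d^v_i/2)/(α_i + w_v) and (Σ_v w_v s^v_i − (λ/2) p_i)/(Σ_v w_v)
with p_ij = ‖f_i − f_j‖². λ starts at 1 and is doubled while U has fewer
than c connected components, halved while it has more (≤ 30 adaptations).
Iteration stops when the relative objective change drops below `attr_tol`
(default 1e−6) in an iteration where λ was not adapted, or at
`attr_max_iter` (default 30). The reported view weights are the
renormalized (sum-1) version of the raw self-weights.

**Stage 2 (structure graph A).** H = S¹ ∘ … ∘ S^m elementwise on the stage-1
updated graphs, nonzero rows renormalized to the simplex (without this the
sub-stochastic products shrink toward zero and the fidelity term
degenerates); rows with no edge common to all views are reported and
tolerated up to n/2. A is learned by alternating the exact minimizers of

‖A − H‖²_F + γ₁ ‖A‖²_F + γ₂ Σ_ij ‖f_i − f_j‖² A_ij

— F from the c smallest Laplacian eigenvectors of (A+Aᵀ)/2, then row-wise
simplex projection of (h_i − (γ₂/2) q_i)/(1+γ₁) with zero diagonal — so the
objective is non-increasing at fixed γ₂. γ₂ follows the same
doubling/halving component schedule and stops the loop as soon as A has
exactly c components (≤ 50 iterations). When the count equals c, the c
smallest Laplacian eigenvalues of A are numerically zero — each component is
a cluster candidate.

**Fusion and spectral clustering.** W = symmetrized elementwise mean of U
and A (sum/hadamard rules available), D_i = Σ_j W_ij + ε with ε = 1e−10,
T = D^{−1/2} W D^{−1/2}, L = I − T. The eigenvectors of the c smallest
eigenvalues of L (equivalently the c largest of T) are taken with a
deterministic sign convention (largest-magnitude entry positive),
row-normalized to unit L2 norm (all-zero rows map to e₁), and clustered by
k-means with k-means++ seeding, 20 restarts, 300 iterations, all seeded from
the run seed — the only stochastic element of the pipeline.

## Parameters

| name | default | meaning |
|---|---|---|
| `poly_degree` d | 2 | polynomial kernel order |
| `poly_gamma` γ | 1 | inner-product scale |
| `poly_coef0` c₀ | 1 | inhomogeneous constant (0 gives the homogeneous kernel) |
| `gauss_sigma` σ | 10 | Gaussian bandwidth, expression units |
| `knn_k` | 15 | neighbors per cell; controls graph density |
| `attr_lambda_init`, `struct_gamma2_init` | 1 | initial spectral multipliers |
| `struct_gamma1` γ₁ | 1 | ridge weight on A |
| `attr_tol` | 1e−6 | relative objective stop |
| `kmeans_restarts` | 20 | best-of-restarts k-means |

σ and the 2σ² denominator convention, d = 2, and γ₁ = γ₂ = 1 are the
method's stated operating point; k = 15 and c₀ = 1 are package choices
(exposed in `RunConfig`) — k is never printed in the method's description,
and c₀ = 1 is the standard inhomogeneous form. No preprocessing is applied
by default; `preprocess_log_scale=True` enables per-cell total scaling +
log1p for raw-count inputs.

## Synthetic data

The generator plants c populations with mean profiles placed on mutually
orthonormal directions so that centers are pairwise `separation`
within-cluster radii apart (radius = rms point-to-centroid distance,
σ√n_genes in the default Gaussian mode). This multivariate definition makes
`separation` dimension-free: 0 = no signal, ~4 = moderately separated, 8 =
well separated. Values are baseline 1.0 + unit Gaussian noise clipped at 0;
independent Bernoulli dropout masks entries in both modes. The
`negative_binomial` mode draws counts with gamma-mixture dispersion around
exponentiated log-mean profiles, with `separation` interpreted as the L2
distance between log-mean profiles (within-cluster spread is mean-dependent
for counts, so radius units are not well defined there). The generator does
not emulate library-size variation, mean–dropout coupling, or batch
effects: a green recovery test establishes that the pipeline separates
well-separated nonnegative sparse populations, not performance on any real
dataset.

## Numerical choices

* Connected components counted on edges (A+Aᵀ)/2 > 1e−10 via sparse-graph
  traversal; simplex projections produce exact zeros, so the threshold only
  guards round-off.
* Eigen-solves use dense symmetric eigendecomposition; deterministic column
  signs as above. O(n³) per iteration; fine to a few thousand cells.
* Degenerate KNN rows fall back to uniform weights; consensus norms are
  floored at 1e−12 inside the self-weights, which caps a view's raw weight
  when it matches U exactly.
* The traced objectives use the row-form spectral terms (λ Σ p_ij U_ij =
  2λ tr(FᵀLF)); a constant factor relative to the trace form, consistent
  with the row-update closed forms.
* With γ₁ > 0 the structure row update shrinks rows below the simplex and
  the projection can transiently re-add small cross-cluster entries; the γ₂
  schedule compensates within one or two adjustments.

## Known limitations

* The per-view distance terms of the stage-1 objective scale with the raw
  kernel distances (polynomial/linear kernels grow with expression scale),
  so the objective's relative-change stopping rule is dominated by the
  largest view; convergence in practice is fast (≤ 10 iterations on
  separable data) but the absolute objective value is not comparable across
  datasets.
* Exact dense linear algebra bounds practical size (~3–5k cells).
* Ablation and single-view baselines share the seeded k-means stage; at high
  separation all variants saturate, so comparisons are informative mainly at
  moderate separation.
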