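# mvgsc — two-stage multi-view graph spectral clustering for scRNA-seq

Cell-type clustering of single-cell RNA-seq data from a single expression
matrix, using multi-view graph learning. One matrix X (cells × genes) is
turned into three kernel views — polynomial (γ⟨x_i,x_j⟩+c₀)^d, Gaussian
exp(−‖x_i−x_j‖²/2σ²), and linear ⟨x_i,x_j⟩ — each of which induces its own
cell–cell geometry. Per view, a sparse adaptive-KNN similarity graph S^v is
built with row-stochastic weights proportional to the margin between each
neighbor's distance and the (k+1)-th distance. Two complementary graphs are
then learned over the cells:

* **Attribute graph U** (stage 1): a self-weighted consensus of the S^v,
  minimizing per-view adaptive-neighbor costs plus Σ_v ‖S^v − U‖_F plus a
  spectral rank term λ Σ_ij ‖f_i − f_j‖² U_ij, by alternating closed-form
  simplex-projected row updates with view weights w_v = 1/(2‖U − S^v‖_F).
  λ is doubled/halved until U has exactly c connected components.
* **Structure graph A** (stage 2): learned from the Hadamard product
  H = S¹∘S²∘…∘S^m (an edge survives only if present in every view) by
  minimizing ‖A − H‖² + γ₁‖A‖² + γ₂ Σ_ij ‖f_i − f_j‖² A_ij, with the same
  γ₂ doubling/halving schedule until A has exactly c components.

U captures view importance and inconsistency; A captures cross-view
consistency. Their elementwise mean is symmetrized, degree-normalized
(T = D^{−1/2} W D^{−1/2}, L = I − T), and the row-normalized eigenvectors of
the c smallest eigenvalues of L are clustered by seeded k-means. Six
evaluation metrics (ARI, NMI, pair-counting F-score and precision,
optimal-assignment ACC, purity), ablation variants (U alone, A alone,
single-view spectral clustering) and a synthetic clustered scRNA-seq
generator are included. Intended for method developers and analysts working
at moderate scale (exact O(n³) eigendecompositions; hundreds to a few
thousand cells).

## Worked example

```python
from mvgsc import RunConfig, SyntheticSpec, generate, run_mvgsc

em, truth = generate(SyntheticSpec(150, 200, 3, separation=8.0, seed=1))
res = run_mvgsc(em, c=3, cfg=RunConfig(seed=1), truth=truth)
print([f"{w:.3f}" for w in res.w], len(res.attribute_trace),
      res.structure_state.n_components)
print(f"ARI {res.metrics.ari:.3f}  ACC {res.metrics.acc:.3f}")
```

prints

```
['0.022', '0.932', '0.047'] 4 3
ARI 1.000  ACC 1.000
```

The view weights show the Gaussian view agreeing most with the consensus on
this dataset; the attribute stage converged in 4 iterations; the structure
graph ended with exactly c = 3 connected components — each component is a
recovered population, and both ARI and matched accuracy are perfect against
the planted labels. See `examples/` for narrative scripts covering data
generation, graph construction, the full pipeline, ablations, and metric
evaluation/export. Real data is read with
`mvgsc.read_expression` (CSV/TSV with identifiers, or MatrixMarket plus
`.rows`/`.cols` sidecars) and `mvgsc.read_labels`.

## Acceptance script

`scripts/acceptance.py` regenerates the ten-seed synthetic battery
(150 cells × 200 genes, 3 populations, separation 8, dropout 0.3), runs the
full pipeline with default hyperparameters (d=2, σ=10, γ₁=γ₂=1), and reports
the worst-case attribute-stage iteration at which the objective is within
1e−6 relative change of its final value (`t1`) and the worst-case number of
γ₂ adjustments before the structure graph reaches exactly c components
(`t2`):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
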