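# Methods

## Problem and model

The package completes a sparse binary bipartite association matrix
`A ∈ {0,1}^{m×d}` between microbes (rows) and diseases (columns). The
working assumptions are the usual ones for this family of methods:

1. **Low rank.** Associations are driven by a small number of latent
   "community" axes, so `A ≈ XYᵀ` with non-negative `X (m×k)`, `Y (d×k)`
   and `k ≪ min(m, d)`.
2. **Manifold smoothness.** Entities with similar interaction profiles
   should have similar latent features. Similarity is measured by the
   Gaussian interaction profile (GIP) kernel on rows/columns of `A`, with
   the bandwidth normalized by the mean squared profile norm
   (`γ = γ′ / mean_i ‖IP_i‖²`, `γ′ = 1` by default). The kernels are
   sparsified through a K-nearest-neighbour mask (1 for mutual
   neighbours, 0.5 one-sided, 0 otherwise; ties in top-K selection break
   towards the lower index for platform-independent determinism) and
   enter the objective through symmetric normalized Laplacians
   `L̃ = D^{−1/2}(D − Ŵ)D^{−1/2}` (pseudo-inverse convention: zero-degree
   nodes get zero rows, so isolated nodes produced by masking are inert).
3. **Row sparsity.** The L2,1 penalty `Σ_i ‖X_i‖₂` drives entire latent
   rows to zero, selecting discriminative microbes/diseases and damping
   noise.

Because the binary profiles make `‖IP_i − IP_j‖²` a Hamming distance, the
GIP kernel is cheap, dense and exactly reproducible.

## Optimization

The objective is nonconvex and nonsmooth. It is minimized by inertial
PALM: alternating blockwise proximal-linearized steps on extrapolated
points, with the non-negativity constraint entering as the indicator of
the orthant, whose proximal map is the elementwise projection
`max(·, 0)`.

Numerical choices that matter:

- **Gradients.** The data-term gradients are `−(A − XYᵀ)Y` and
  `−(A − XYᵀ)ᵀX`; the graph terms contribute `2λL̃X` (factor 2 from the
  derivative of the quadratic form with symmetric `L̃`).
- **L2,1 smoothing.** The row-norm penalty is handled inside the smooth
  block via a Huber smoothing with knee `eps_row`: gradient
  `row / max(‖row‖, eps_row)`. The smoothed penalty is exactly
  `(1/eps_row)`-smooth, so adding `λ_l / eps_row` to the step constant
  preserves the majorization property. `eps_row = 1e−2` by default: rows
  below that norm are treated as dead, and a much smaller knee would
  inflate the step constant by orders of magnitude and stall the
  iteration. The objective trace records the Huber-smoothed objective —
  the function actually minimized — which makes the monotone-descent
  guarantee (inertia off) exact rather than approximate; the exact-L2,1
  objective is available separately.
- **Step constants.** `c = ‖FᵀF‖_F + 2λ_graph‖L̃‖_F + λ_l/eps_row`
  (`F` the other block's factor), floored at `1e−8` for degenerate
  factors. A `data_step_only` switch drops the graph/L2,1 safeguards
  and uses `‖FᵀF‖_F` alone, trading the descent guarantee for larger
  steps.
- **Inertia.** One schedule `α_i = β_i = (i−1)/(i+2)` is applied to both
  the prox centre and the gradient point (a fixed constant or `none` are
  also accepted). On the planted fixtures the median iterations-to-
  tolerance drops from ~670 to ~175 when the inertia is on; descent is
  then no longer guaranteed per-step, which is the standard trade.
- **Initialization.** Plain NNDSVD (dominant non-negative section of each
  singular pair, zeros kept as zeros, no mean filling), with a fixed sign
  convention — each left singular vector oriented so its
  largest-magnitude entry is positive — making the initializer fully
  deterministic. Dense SVD below 200 rows/columns, seeded Lanczos above.
  The `abs_svd` variant (elementwise |·| of the scaled singular factors)
  exists for the initialization ablation.
- **Stopping.** Relative objective change
  `|ψ_i − ψ_{i−1}| / max(ψ_{i−1}, 1) < tol` (default `1e−6`), cap 500
  iterations.

## Defaults

| parameter | default | why |
|---|---|---|
| `rank` k | `min(m, d, 20)` | latent dimension; small versus both sides |
| `lambda_m`, `lambda_d` | 0.01 | mild manifold smoothing on both graphs |
| `lambda_l` | 0.1 | row sparsity without crushing the fit |
| `n_neighbors` K | 5 | common KNN-graph default; clipped to n−1 per side |
| `gamma'` | 1.0 | standard GIP raw bandwidth |
| `tol`, `max_iter` | 1e−6, 500 | relative-change stop |
| `eps_row` | 1e−2 | Huber knee, see above |

The regularization weights for this model family are dataset-dependent
and no universally published values exist; the defaults above are
deliberately mild and every one is exposed through `RunConfig`, the model
constructor and the CLI.

## Evaluation protocols

- **Global LOOCV**: each known pair is zeroed in turn, the *entire*
  pipeline — GIP kernels, KNN graphs, Laplacians, initialization, solver
  — is retrained on the masked matrix, and the held-out score is pooled
  against the candidate scores of the same run. Candidates are always
  the pairs that are zero in the *original* matrix, never other held-out
  positives. A `fast` flag fits one unmasked model for smoke tests; it is
  not protocol-faithful and is never used for reported numbers.
- **Repeated k-fold CV**: per repetition (seed = master + repetition
  index) the known pairs are shuffled and split into near-equal folds;
  each fold is masked and retrained as above. One AUC/AUPR per
  repetition by pooling all folds; reports carry mean ± sd.
- **Metrics.** AUC is the rank-based Mann–Whitney statistic (ties count
  one half). AUPR is step-wise average precision over descending unique
  score thresholds (tied scores enter as one group, so an all-tied
  scorer gets the prevalence); trapezoidal PR interpolation is avoided as
  optimistically biased.
- **Ablations** run k-fold CV with identical seeds per mode (paired fold
  assignments): `abs_svd_init`, `no_graph_m` (λ_m=0), `no_graph_d`
  (λ_d=0), `no_l21` (λ_l=0), `no_inertia` (α=β=0).
- **New-disease mode**: a disease's column is blanked before similarity
  computation and training. The GIP kernel stays defined (a single
  all-zero profile simply contributes zero to the mean squared norm) and
  all microbes become candidates.

## Synthetic fixtures: what they do and do not show

The generator plants co-clusters: contiguous blocks of microbes and
diseases, within-block association probability `within_block_prob`,
background probability `background_prob`. Exact-count variants reproduce
catalogue shapes (292×39 with exactly 450 ones, density 3.95%; 1052×218
with 4351, density 1.90%) by sampling without replacement from
within-block cells first. The standard evaluation fixtures are 20×10
two-block matrices: a *noisy* one (within 0.6, background 0.02) and a
*dense* one (within 0.9 — blocks with 10% dropout). Tests of block
recovery in top-k ranking use a wider 60×10 matrix so that enough
unassociated within-block microbes exist to fill a top-10 list.

Two calibration facts about these fixtures, both computed by an
independent generative oracle (scoring each pair with its true Bernoulli
probability) and reproduced by `scripts/acceptance.py`:

- On the **dense** fixture the oracle reaches 5-fold/LOOCV AUC ≈ 0.926
  and the fitted model ≈ 0.91–0.95 depending on seed — structure is
  essentially fully recovered.
- On the **noisy** fixture the oracle ceiling is ≈ 0.825: held-out
  within-block positives are statistically exchangeable with the ~40% of
  within-block cells that are zero, and no scorer can separate them. The
  model reaches ≈ 0.78–0.83. This ceiling is a property of the fixture,
  not a deficiency of the method, and any AUC expectation above it on
  this fixture is unsatisfiable.
- With `within == background` (matched marginal density 0.31) the
  pipeline's mean AUC over 20 seeds is 0.5 within three standard errors:
  no signal is invented.

What the fixtures do **not** emulate: real catalogues' heavy-tailed
degree distributions, correlated study/ascertainment biases, taxonomy-
induced similarity between microbes, and their much larger candidate
sets. Passing these tests therefore demonstrates algorithmic
correctness and calibration, not clinical-scale predictive performance;
published headline AUCs on HMDAD/Disbiome depend on those catalogues and
on tuned regularization weights, and are out of scope here.

## Known limitations

- GIP is the only similarity source; semantic/functional similarities
  are not integrated.
- The L2,1 term is smoothed rather than handled by an exact row-wise
  prox; rows shrink to ~`eps_row` rather than exactly zero.
- LOOCV retrains one model per known pair (quadratic in the association
  count overall); it is intended for matrices up to a few hundred
  associations.
- With inertia on, per-iteration monotone descent is not guaranteed
  (standard for extrapolated nonconvex schemes); divergence is detected
  and raised, never silently ignored.
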