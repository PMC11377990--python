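# mdnmf

Microbe–disease association prediction by **graph-dual-regularized,
L2,1-penalized non-negative matrix factorization**, solved with an
**inertial proximal alternating linearized minimization (iPALM)** scheme.

Catalogues of experimentally confirmed microbe–disease associations (such
as HMDAD or Disbiome) are sparse binary bipartite networks: a few hundred
to a few thousand confirmed links between hundreds of microbes and dozens
to hundreds of diseases. Completing that matrix — scoring the unobserved
pairs — proposes candidate disease-associated microbes for experimental
follow-up. This package is aimed at computational biologists who want a
transparent, fully reproducible matrix-factorization baseline for that
task, with the evaluation protocols (global LOOCV, repeated 5-fold CV,
ablations, new-disease ranking) built in.

## Model

Given a binary association matrix `A ∈ {0,1}^{m×d}` (rows microbes,
columns diseases), the model seeks non-negative latent factors
`X ∈ R^{m×k}`, `Y ∈ R^{d×k}` minimizing

```
G(X, Y) = ½‖A − XYᵀ‖²_F
        + λ_m Tr(Xᵀ L̃_m X) + λ_d Tr(Yᵀ L̃_d Y)
        + λ_l (‖X‖₂,₁ + ‖Y‖₂,₁),          X ≥ 0, Y ≥ 0,
```

where

- `L̃_m`, `L̃_d` are symmetric normalized Laplacians of K-nearest-neighbour
  graphs built from **Gaussian interaction profile (GIP) kernel**
  similarities `GM_ij = exp(−γ_m‖IP(m_i) − IP(m_j)‖²)` (bandwidth
  normalized by the mean squared profile norm), sparsified by a
  mutual/one-sided KNN mask with weights {1, 0.5, 0};
- `‖X‖₂,₁ = Σ_i ‖X_i‖₂` is the row-sparsity (L2,1) penalty.

The solver initializes `X, Y` with **NNDSVD** (non-negative double SVD) and
alternates inertial proximal-linearized block updates: extrapolate each
block with a Nesterov-style weight `(i−1)/(i+2)`, take a gradient step of
the smooth part with a majorizing step constant, and project onto the
non-negative orthant. Predicted association scores are `Â = XYᵀ`.

## Worked example

```python
from mdnmf import MicrobeDiseaseNMF, PlantedConfig, planted_blocks
from mdnmf.evaluation import kfold_cv

data = planted_blocks(PlantedConfig(m=20, d=10, n_blocks=2,
                                    within_block_prob=0.9,
                                    background_prob=0.02, seed=0))
res = MicrobeDiseaseNMF(data, rank=2).fit()
print(res.summary())
for i, (name, score) in enumerate(res.rank_microbes("d001", top_k=3), 1):
    print(i, name, f"{score:.3f}")
rep = kfold_cv(data, dict(rank=2), n_folds=5, n_repeats=5, seed=0)
print(f"AUC {rep.mean_auc:.4f} +/- {rep.sd_auc:.4f}, AUPR {rep.mean_aupr:.4f}")
```

prints

```
Graph-regularized L2,1 NMF (inertial PALM)
======================================================
microbes                    20
diseases                    10
known associations          88
density (%)                 44.00
rank k                      2
lambda_m / lambda_d         0.01 / 0.01
lambda_l (L2,1)             0.1
K neighbours                5
init                        nndsvd
inertia                     nesterov
iterations                  102
converged                   True
final objective             7.68323
zero rows X / Y             0 / 0
======================================================
1 m010 0.402
2 m012 0.236
3 m013 0.073
AUC 0.9133 +/- 0.0112, AUPR 0.5571
```

The fixture plants two microbe–disease co-clusters; the model recovers
them: the top-ranked unknown candidates for disease `d001` (first block)
are first-block microbes, and 5-fold cross-validation — which re-derives
the GIP kernels and graphs from each masked training matrix before
refitting — ranks held-out associations far above chance.

The same workflow is available from the shell:

```
mdnmf simulate --preset blocks --within 0.9 --seed 0 --out edges.tsv
mdnmf fit edges.tsv --rank 2 --out scores.tsv
mdnmf cv edges.tsv --rank 2 --folds 5 --repeats 5 --seed 0 --out cv.tsv
mdnmf rank edges.tsv --disease d001 --rank 2 --top 10
```

Every run writes a flat key=value manifest next to its outputs; re-running
with `--config <manifest>` reproduces the outputs byte-for-byte.

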