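"""Model/Results interface tying the pipeline together.

:class:`MicrobeDiseaseNMF` is constructed from association data plus
hyperparameters; :meth:`fit` computes the GIP kernels, builds the KNN-graph
Laplacians, initializes the factors (NNDSVD by default) and runs the
inertial PALM solver, returning a :class:`MicrobeDiseaseNMFResults` that
carries the factors, the objective trace, diagnostics and prediction
helpers.
"""

from __future__ import annotations

import numpy as np

from . import graphs, initialization, similarity, solver
from .exceptions import ParameterError
from .io import AssociationData, density, load_edge_list, write_scores

__all__ = ["MicrobeDiseaseNMF", "MicrobeDiseaseNMFResults"]

_INIT_MODES = ("nndsvd", "abs_svd")


class MicrobeDiseaseNMF:
    """Graph-dual-regularized L2,1-penalized NMF for bipartite link prediction.

    Parameters
    ----------
    data : AssociationData
        Binary microbe x disease association matrix with names.
    rank : int, optional
        Latent dimension k.  Default ``min(m, d, 20)``.
    lambda_m, lambda_d : float
        Weights of the microbe/disease graph-Laplacian penalties.
    lambda_l : float
        Weight of the L2,1 row-sparsity penalty.
    n_neighbors : int
        K of the KNN graphs; clipped to ``n - 1`` on each side so small
        problems remain well defined.
    gamma_m_prime, gamma_d_prime : float
        Raw GIP bandwidths (the effective bandwidth is normalized by the
        mean squared profile norm).
    init : {"nndsvd", "abs_svd"}
        Factor initialization; ``abs_svd`` is the no-NNDSVD ablation.
    inertia : "nesterov" | "none" | float
        Extrapolation schedule of the solver.
    max_iter, tol, eps_row, data_step_only
        Passed to :class:`~mdnmf.solver.SolverParams`.
    seed : int
        Seed for the (only) stochastic component, the truncated-SVD starting
        vector used on large matrices.

    Examples
    --------
    >>> from mdnmf.simulate import planted_blocks, PlantedConfig
    >>> data = planted_blocks(PlantedConfig(m=20, d=10, n_blocks=2, seed=0))
    >>> res = MicrobeDiseaseNMF(data, rank=2).fit()
    >>> res.scores.shape
    (20, 10)
    """

    def __init__(
        self,
        data: AssociationData,
        *,
        rank: int | None = None,
        lambda_m: float = 0.01,
        lambda_d: float = 0.01,
        lambda_l: float = 0.1,
        n_neighbors: int = 5,
        gamma_m_prime: float = 1.0,
        gamma_d_prime: float = 1.0,
        init: str = "nndsvd",
        inertia: str | float = "nesterov",
        max_iter: int = 500,
        tol: float = 1e-6,
        eps_row: float = 1e-2,
        data_step_only: bool = False,
        seed: int = 0,
    ) -> None:
        self.data = data
        m, d = data.A.shape
        self.rank = int(rank) if rank is not None else min(m, d, 20)
        if not 1 <= self.rank <= min(m, d):
            raise ParameterError(f"rank {self.rank} out of range [1, {min(m, d)}]")
        if init not in _INIT_MODES:
            raise ParameterError(f"init must be one of {_INIT_MODES}, got {init!r}")
        if n_neighbors < 1:
            raise ParameterError("n_neighbors must be >= 1")
        self.n_neighbors = int(n_neighbors)
        self.gamma_m_prime = gamma_m_prime
        self.gamma_d_prime = gamma_d_prime
        self.init = init
        self.seed = int(seed)
        self.solver_params = solver.SolverParams(
            lambda_m=lambda_m,
            lambda_d=lambda_d,
            lambda_l=lambda_l,
            max_iter=max_iter,
            tol=tol,
            inertia=inertia,
            eps_row=eps_row,
            data_step_only=data_step_only,
        )

    @classmethod
    def from_edge_list(cls, path, **kwargs) -> "MicrobeDiseaseNMF":
        """Build a model straight from a two-column edge-list file."""
        return cls(load_edge_list(path), **kwargs)

    def fit(self) -> "MicrobeDiseaseNMFResults":
        """Run kernels -> graphs -> init -> iPALM and wrap the results."""
        data = self.data
        kernels = similarity.gip_kernels(data, self.gamma_m_prime, self.gamma_d_prime)
        # clip K per side; a one-entity side has no neighbours -> zero graph
        def _side(S: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
            k_eff = min(self.n_neighbors, S.shape[0] - 1)
            if k_eff < 1:
                z = np.zeros_like(S)
                return z, z, z
            mask = graphs.knn_mask(S, k_eff)
            W = graphs.sparsify(S, mask)
            return mask, W, graphs.normalized_laplacian(W)

        Nm, GM_hat, Lm_tilde = _side(kernels.GM)
        Nd, GD_hat, Ld_tilde = _side(kernels.GD)
        regs = graphs.GraphRegularizers(
            K=self.n_neighbors,
            Nm=Nm,
            Nd=Nd,
            GM_hat=GM_hat,
            GD_hat=GD_hat,
            Lm_tilde=Lm_tilde,
            Ld_tilde=Ld_tilde,
        )
        if self.init == "nndsvd":
            start = initialization.nndsvd_init(data.A, self.rank, self.seed)
        else:
            start = initialization.abs_svd_init(data.A, self.rank, self.seed)
        factors, trace = solver.ipalm_solve(
            data.A, regs.Lm_tilde, regs.Ld_tilde, start, self.solver_params
        )
        return MicrobeDiseaseNMFResults(self, factors, trace, kernels, regs)


class MicrobeDiseaseNMFResults:
    """Fitted factors, objective trace and prediction helpers."""

    def __init__(self, model, factors, trace, kernels, regularizers) -> None:
        self.model = model
        self.factors = factors
        self.trace = trace
        self.kernels = kernels
        self.regularizers = regularizers
        self._scores: np.ndarray | None = None

    @property
    def X(self) -> np.ndarray:
        """Microbe latent features (m x k)."""
        return self.factors.X

    @property
    def Y(self) -> np.ndarray:
        """Disease latent features (d x k)."""
        return self.factors.Y

    @property
    def scores(self) -> np.ndarray:
        """Predicted association scores X Y^T (cached)."""
        if self._scores is None:
            self._scores = solver.predict_scores(self.factors)
        return self._scores

    @property
    def converged(self) -> bool:
        return self.trace.converged

    @property
    def n_iter(self) -> int:
        return self.trace.iterations_run

    @property
    def final_objective(self) -> float:
        return self.trace.objective_values[-1]

    def rank_microbes(
        self, disease: str, top_k: int = 10, exclude_known: bool = True
    ) -> list[tuple[str, float]]:
        """Top-scoring microbes for one disease, ties broken by microbe index.

        With ``exclude_known`` microbes already associated with the disease
        in the training matrix are removed from the candidate list.
        """
        data = self.model.data
        if disease not in data.disease_index:
            raise ParameterError(f"unknown disease: {disease!r}")
        j = data.disease_index[disease]
        col = self.scores[:, j]
        candidates = np.arange(data.n_microbes)
        if exclude_known:
            candidates = candidates[data.A[:, j] == 0]
        # stable sort on -score: ties go to the lower microbe index
        order = candidates[np.argsort(-col[candidates], kind="stable")]
        return [(data.microbes[i], float(col[i])) for i in order[:top_k]]

    def write_scores(self, path) -> None:
        write_scores(self.scores, self.model.data, path)

    def summary(self) -> str:
        """Human-readable fit summary table."""
        m = self.model
        data = m.data
        p = m.solver_params
        row_norms_x = np.sqrt((self.X**2).sum(axis=1))
        row_norms_y = np.sqrt((self.Y**2).sum(axis=1))
        dead_x = int((row_norms_x < p.eps_row).sum())
        dead_y = int((row_norms_y < p.eps_row).sum())
        lines = [
            "Graph-regularized L2,1 NMF (inertial PALM)",
            "=" * 54,
            f"{'microbes':<28}{data.n_microbes}",
            f"{'diseases':<28}{data.n_diseases}",
            f"{'known associations':<28}{data.n_associations}",
            f"{'density (%)':<28}{density(data):.2f}",
            f"{'rank k':<28}{m.rank}",
            f"{'lambda_m / lambda_d':<28}{p.lambda_m:g} / {p.lambda_d:g}",
            f"{'lambda_l (L2,1)':<28}{p.lambda_l:g}",
            f"{'K neighbours':<28}{m.n_neighbors}",
            f"{'init':<28}{m.init}",
            f"{'inertia':<28}{p.inertia}",
            f"{'iterations':<28}{self.n_iter}",
            f"{'converged':<28}{self.converged}",
            f"{'final objective':<28}{self.final_objective:.6g}",
            f"{'zero rows X / Y':<28}{dead_x} / {dead_y}",
            "=" * 54,
        ]
        return "\n".join(lines)
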