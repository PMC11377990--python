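"""Inertial proximal alternating linearized minimization (iPALM) solver.

Minimizes, over non-negative factors X (m x k) and Y (d x k),

    G(X, Y) = 1/2 ||A - X Y^T||_F^2
              + lambda_m Tr(X^T Lm X) + lambda_d Tr(Y^T Ld Y)
              + lambda_l (||X||_{2,1} + ||Y||_{2,1}),

where ||X||_{2,1} is the sum of row 2-norms (row sparsity) and Lm, Ld are
normalized graph Laplacians.  Each outer iteration linearizes the smooth
part around an extrapolated point and applies the proximal map of the
non-negativity indicator (projection onto the orthant):

    d1 = X_i + alpha_i (X_i - X_{i-1})          # prox centre
    m1 = X_i + beta_i  (X_i - X_{i-1})          # gradient point
    X_{i+1} = max(0, d1 - grad_X(m1, Y_i) / c1_i)

then the symmetric update for Y using the fresh X_{i+1}.  The L2,1 term is
handled inside the smooth block through a Huber smoothing of the row norm
with knee ``eps_row``: its gradient is row / max(||row||, eps_row), and its
curvature is bounded by 1 / eps_row, which the step constant accounts for so
that with the inertia off every step is a true majorize-minimize step and
the objective trace is monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DivergenceError, ParameterError
from .initialization import FactorPair

__all__ = [
    "SolverParams",
    "SolveTrace",
    "objective",
    "smoothed_objective",
    "grad_smooth_X",
    "grad_smooth_Y",
    "prox_nonneg",
    "step_constant",
    "ipalm_solve",
    "predict_scores",
]

_C_MIN = 1e-8  # floor for the step constant (degenerate factor guard)


@dataclass
class SolverParams:
    """Objective weights and iteration controls.

    Parameters
    ----------
    lambda_m, lambda_d : float
        Weights of the microbe-side / disease-side graph penalties.
    lambda_l : float
        Weight of the L2,1 row-sparsity penalty on both factors.
    max_iter : int
        Iteration cap.
    tol : float
        Stop when |psi_i - psi_{i-1}| / max(psi_{i-1}, 1) < tol.
    inertia : "nesterov" | "none" | float
        Extrapolation schedule: (i-1)/(i+2), off, or a fixed constant.
    eps_row : float
        Huber knee of the smoothed row norm; rows below this norm are
        effectively dead.  Also sets the L2,1 curvature bound lambda_l/eps_row
        used in the step constants.
    data_step_only : bool
        If True, use only ||Y^T Y||_F (resp. ||X^T X||_F) as step constant,
        dropping the graph/L2,1 curvature safeguards.
    """

    lambda_m: float = 0.01
    lambda_d: float = 0.01
    lambda_l: float = 0.1
    max_iter: int = 500
    tol: float = 1e-6
    inertia: str | float = "nesterov"
    eps_row: float = 1e-2
    data_step_only: bool = False

    def __post_init__(self) -> None:
        if min(self.lambda_m, self.lambda_d, self.lambda_l) < 0:
            raise ParameterError("regularization weights must be non-negative")
        if self.tol <= 0 and self.tol != 0:
            raise ParameterError("tol must be >= 0")
        if self.eps_row <= 0:
            raise ParameterError("eps_row must be positive")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")

    def inertia_coefficient(self, i: int) -> float:
        """Extrapolation weight at outer iteration i (1-based)."""
        if self.inertia == "none":
            return 0.0
        if self.inertia == "nesterov":
            return (i - 1.0) / (i + 2.0)
        return float(self.inertia)


@dataclass
class SolveTrace:
    """Objective values per iteration plus convergence bookkeeping."""

    objective_values: list[float] = field(default_factory=list)
    iterations_run: int = 0
    converged: bool = False


def _row_norms(M: np.ndarray) -> np.ndarray:
    return np.sqrt(np.sum(M * M, axis=1))


def _l21(M: np.ndarray) -> float:
    return float(_row_norms(M).sum())


def _huber_l21(M: np.ndarray, eps: float) -> float:
    r = _row_norms(M)
    return float(np.where(r >= eps, r, r * r / (2 * eps) + eps / 2).sum())


def _check_finite(*mats: np.ndarray) -> None:
    for M in mats:
        if not np.isfinite(M).all():
            raise DivergenceError("non-finite values in solver input")


def objective(
    A: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    Lm: np.ndarray,
    Ld: np.ndarray,
    params: SolverParams,
) -> float:
    """Exact objective G(X, Y) with the true (non-smoothed) L2,1 norms."""
    _check_finite(A, X, Y)
    R = A - X @ Y.T
    val = 0.5 * float(np.sum(R * R))
    if params.lambda_m:
        val += params.lambda_m * float(np.sum(X * (Lm @ X)))
    if params.lambda_d:
        val += params.lambda_d * float(np.sum(Y * (Ld @ Y)))
    if params.lambda_l:
        val += params.lambda_l * (_l21(X) + _l21(Y))
    return val


def smoothed_objective(
    A: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    Lm: np.ndarray,
    Ld: np.ndarray,
    params: SolverParams,
) -> float:
    """Objective with the Huber-smoothed L2,1 terms the solver minimizes."""
    R = A - X @ Y.T
    val = 0.5 * float(np.sum(R * R))
    if params.lambda_m:
        val += params.lambda_m * float(np.sum(X * (Lm @ X)))
    if params.lambda_d:
        val += params.lambda_d * float(np.sum(Y * (Ld @ Y)))
    if params.lambda_l:
        val += params.lambda_l * (_huber_l21(X, params.eps_row) + _huber_l21(Y, params.eps_row))
    return val


def _l21_grad(M: np.ndarray, eps: float) -> np.ndarray:
    r = np.maximum(_row_norms(M), eps)
    return M / r[:, None]


def grad_smooth_X(
    A: np.ndarray, X: np.ndarray, Y: np.ndarray, Lm: np.ndarray, params: SolverParams
) -> np.ndarray:
    """Gradient of the smooth(ed) objective w.r.t. X:
    -(A - X Y^T) Y + 2 lambda_m Lm X + lambda_l X_i/max(||X_i||, eps_row)."""
    G = (X @ Y.T - A) @ Y
    if params.lambda_m:
        G += 2.0 * params.lambda_m * (Lm @ X)
    if params.lambda_l:
        G += params.lambda_l * _l21_grad(X, params.eps_row)
    return G


def grad_smooth_Y(
    A: np.ndarray, X: np.ndarray, Y: np.ndarray, Ld: np.ndarray, params: SolverParams
) -> np.ndarray:
    """Gradient w.r.t. Y: -(A - X Y^T)^T X + 2 lambda_d Ld Y + L2,1 part."""
    G = (X @ Y.T - A).T @ X
    if params.lambda_d:
        G += 2.0 * params.lambda_d * (Ld @ Y)
    if params.lambda_l:
        G += params.lambda_l * _l21_grad(Y, params.eps_row)
    return G


def prox_nonneg(V: np.ndarray, c: float) -> np.ndarray:
    """Proximal map of the non-negativity indicator: elementwise max(V, 0).

    Independent of the step constant ``c`` (projection onto the orthant).
    """
    if c <= 0:
        raise ParameterError("step constant must be positive")
    return np.maximum(V, 0.0)


def step_constant(
    other_factor: np.ndarray,
    L: np.ndarray,
    lambda_graph: float,
    params: SolverParams,
) -> float:
    """Majorizing constant for one block's linearized step.

    ``||F^T F||_F`` bounds the data-term curvature (F the *other* factor);
    ``2 lambda_graph ||L||_F`` the graph term; ``lambda_l / eps_row`` the
    Huber-smoothed L2,1 term.  Floored at a small positive constant so the
    step is defined even for a zero factor.
    """
    F = other_factor
    c = float(np.linalg.norm(F.T @ F))
    if not params.data_step_only:
        if lambda_graph:
            c += 2.0 * lambda_graph * float(np.linalg.norm(L))
        if params.lambda_l:
            c += params.lambda_l / params.eps_row
    return max(c, _C_MIN)


def ipalm_solve(
    A: np.ndarray,
    Lm: np.ndarray,
    Ld: np.ndarray,
    init: FactorPair,
    params: SolverParams,
) -> tuple[FactorPair, SolveTrace]:
    """Run the inertial PALM iteration from ``init``.

    Returns the final non-negative factors and the trace of (smoothed)
    objective values, one entry per iteration after an initial entry.

    Raises
    ------
    DivergenceError
        If the objective becomes non-finite, naming the iteration.
    """
    _check_finite(A, Lm, Ld, init.X, init.Y)
    if (init.X < 0).any() or (init.Y < 0).any():
        raise ParameterError("initial factors must be non-negative")
    X = init.X.copy()
    Y = init.Y.copy()
    X_prev, Y_prev = X.copy(), Y.copy()

    trace = SolveTrace()
    psi = smoothed_objective(A, X, Y, Lm, Ld, params)
    trace.objective_values.append(psi)

    for i in range(1, params.max_iter + 1):
        w = params.inertia_coefficient(i)

        # X block: prox centre d1, gradient point m1 (alpha = beta = w)
        d1 = X + w * (X - X_prev) if w else X
        m1 = d1
        c1 = step_constant(Y, Lm, params.lambda_m, params)
        X_new = prox_nonneg(d1 - grad_smooth_X(A, m1, Y, Lm, params) / c1, c1)

        # Y block, using the fresh X
        d2 = Y + w * (Y - Y_prev) if w else Y
        m2 = d2
        c2 = step_constant(X_new, Ld, params.lambda_d, params)
        Y_new = prox_nonneg(d2 - grad_smooth_Y(A, X_new, m2, Ld, params) / c2, c2)

        X_prev, Y_prev = X, Y
        X, Y = X_new, Y_new

        psi_new = smoothed_objective(A, X, Y, Lm, Ld, params)
        if not np.isfinite(psi_new):
            raise DivergenceError(f"objective became non-finite at iteration {i}")
        trace.objective_values.append(psi_new)
        trace.iterations_run = i
        rel_change = abs(psi_new - psi) / max(psi, 1.0)
        psi = psi_new
        if rel_change < params.tol:
            trace.converged = True
            break

    return FactorPair(X, Y), trace


def predict_scores(factors: FactorPair) -> np.ndarray:
    """Association score matrix X Y^T (non-negative by construction)."""
    return factors.X @ factors.Y.T
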