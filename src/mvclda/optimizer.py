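"""Joint consensus-graph / label-propagation optimizer.

The model learns, from n disease similarity views AD^(v) and m lncRNA
similarity views AL^(u), a row-stochastic disease consensus graph SD, a
row-stochastic lncRNA consensus graph SL, simplex view weights wD and wL,
and a prediction matrix F, by minimizing

    ||SD - sum_v wD_v AD^(v)||_F^2 + 2a Tr(F L_SD F^T)
  + ||SL - sum_u wL_u AL^(u)||_F^2 + 2b Tr(F^T L_SL F)
  + ||F - Y||_F^2

subject to simplex constraints on every row of SD and SL and on wD and wL.
Here L_S = D_S - (S^T + S)/2 is the Laplacian of the symmetrized graph and
a, b are nonnegative smoothness weights. The graph terms keep each
consensus graph close to the weighted view average while the trace terms
smooth the predictions over it: 2a Tr(F L_SD F^T) equals
a * sum_ij SD_ij ||F_:i - F_:j||^2 over prediction COLUMNS, and the SL term
is the analogue over prediction ROWS.

Every block update below solves its subproblem exactly (or monotonically,
for the projected-gradient weight step), so the objective trace is
non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datatypes import AssociationMatrix
from .exceptions import ConfigError, NumericalError
from .similarity import SimilarityView, ViewSet

__all__ = [
    "HyperParams",
    "ConsensusState",
    "build_laplacian",
    "simplex_project",
    "simplex_project_rows",
    "update_consensus_graph",
    "update_view_weights",
    "solve_label_matrix",
    "objective_value",
    "fit",
]


@dataclass(frozen=True)
class HyperParams:
    """Hyperparameters of the joint objective and its solver.

    alpha and beta weight the disease-side and lncRNA-side smoothness terms;
    the tolerances are relative-objective-change thresholds for the inner
    (graph/label) and outer (weight) loops.
    """

    alpha: float = 1e-4
    beta: float = 1e-4
    inner_tol: float = 1e-4
    outer_tol: float = 1e-4
    max_inner: int = 30
    max_outer: int = 50

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ConfigError("alpha and beta must be nonnegative")
        if self.inner_tol <= 0 or self.outer_tol <= 0:
            raise ConfigError("tolerances must be positive")
        if self.max_inner < 1 or self.max_outer < 1:
            raise ConfigError("iteration caps must be at least 1")


@dataclass
class ConsensusState:
    """Learned state: consensus graphs, view weights, predictions, trace."""

    SD: np.ndarray
    SL: np.ndarray
    wD: np.ndarray
    wL: np.ndarray
    F: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    n_outer: int = 0
    converged: bool = False

    def validate(self) -> None:
        for name, S in (("SD", self.SD), ("SL", self.SL)):
            if S.min() < 0:
                raise ValueError(f"{name} has negative entries")
            if not np.allclose(S.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError(f"{name} rows do not sum to 1")
        for name, w in (("wD", self.wD), ("wL", self.wL)):
            if w.min() < 0 or abs(w.sum() - 1.0) > 1e-10:
                raise ValueError(f"{name} is not on the probability simplex")


def build_laplacian(S: np.ndarray) -> np.ndarray:
    """Graph Laplacian L_S = D_S - (S^T + S)/2 of the symmetrized graph.

    D_S is diagonal with entries sum_j (S_ij + S_ji)/2. The result is
    symmetric positive-semidefinite with zero row sums.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"graph matrix must be square, got shape {S.shape}")
    W = (S + S.T) / 2.0
    return np.diag(W.sum(axis=1)) - W


def simplex_project(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex {x >= 0, sum x = 1}.

    Exact sorting/thresholding closed form: sort descending, find the last
    index rho where u_rho > (cumsum(u)_rho - 1)/rho, shift by that threshold
    and clip at zero.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("simplex_project expects a nonempty 1-D vector")
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    ind = np.arange(1, v.size + 1)
    mask = u - css / ind > 0
    rho = ind[mask][-1]
    theta = css[mask][-1] / rho
    return np.maximum(v - theta, 0.0)


def simplex_project_rows(M: np.ndarray) -> np.ndarray:
    """Row-wise simplex projection, vectorized over the rows of M."""
    M = np.asarray(M, dtype=float)
    n, d = M.shape
    u = -np.sort(-M, axis=1)
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, d + 1)
    mask = u - css / ind > 0
    rho = mask.sum(axis=1)  # >= 1 always since u_(1) - (u_(1)-1)/1 > 0
    theta = css[np.arange(n), rho - 1] / rho
    return np.maximum(M - theta[:, None], 0.0)


def _squared_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances between the rows of X."""
    if X.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(X, metric="sqeuclidean"))


def update_consensus_graph(
    views: list[np.ndarray] | list[SimilarityView],
    weights: np.ndarray,
    F: np.ndarray,
    smooth_weight: float,
    side: str,
) -> np.ndarray:
    """Exact row-wise update of one consensus graph.

    Each row i of the result is the simplex projection of
    sum_v weights_v * View^(v)_i - (smooth_weight/2) * h_i, where
    h_i[j] is the squared distance between predictions i and j:
    prediction COLUMNS of F on the disease side, prediction ROWS on the
    lncRNA side (the orientation the trace terms of the objective imply).
    """
    arrays = [v.values if isinstance(v, SimilarityView) else np.asarray(v) for v in views]
    base = sum(w * A for w, A in zip(weights, arrays, strict=True))
    if side == "disease":
        points = F.T
    elif side == "lncrna":
        points = F
    else:
        raise ConfigError(f"side must be 'lncrna' or 'disease', got {side!r}")
    if points.shape[0] != base.shape[0]:
        raise ValueError(
            f"F gives {points.shape[0]} {side} points but views are "
            f"{base.shape[0]}x{base.shape[1]}"
        )
    H = _squared_distance_matrix(points)
    return simplex_project_rows(base - (smooth_weight / 2.0) * H)


def update_view_weights(
    S: np.ndarray,
    views: list[np.ndarray] | list[SimilarityView],
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> np.ndarray:
    """Simplex-constrained least-squares view weights for one side.

    Minimizes ||a - G w||^2 over the probability simplex, where a stacks the
    columns of the consensus graph S and the columns of G stack each view.
    Solved by projected gradient from the uniform vector with step
    1 / ||G^T G||_2, so duplicated (rank-deficient) views share weight
    deterministically.
    """
    arrays = [v.values if isinstance(v, SimilarityView) else np.asarray(v) for v in views]
    if not arrays:
        raise ConfigError("need at least one view to fit weights")
    n = len(arrays)
    if n == 1:
        return np.ones(1)
    a = np.asarray(S, dtype=float).ravel(order="F")
    G = np.column_stack([A.ravel(order="F") for A in arrays])
    GtG = G.T @ G
    Gta = G.T @ a
    lam = float(np.linalg.norm(GtG, 2))
    if lam == 0.0:
        return np.full(n, 1.0 / n)
    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        w_new = simplex_project(w - (GtG @ w - Gta) / lam)
        if np.abs(w_new - w).max() < tol:
            w = w_new
            break
        w = w_new
    return w


def solve_label_matrix(
    L_SL: np.ndarray,
    L_SD: np.ndarray,
    Y: np.ndarray,
    alpha: float,
    beta: float,
) -> np.ndarray:
    """Solve the Sylvester equation (2b L_SL + I) F + 2a F L_SD = Y for F.

    Both operators are symmetric PSD, so the solution is computed in their
    joint eigenbasis: with 2b L_SL + I = U diag(lam) U^T and
    2a L_SD = V diag(mu) V^T, F = U [ (U^T Y V) / (lam_i + mu_j) ] V^T.
    Every denominator is >= 1 (lam >= 1, mu >= 0), so the solution is
    unique and no regularization is needed.
    """
    Y = np.asarray(Y, dtype=float)
    for name, L in (("lncRNA", L_SL), ("disease", L_SD)):
        if not np.allclose(L, L.T, atol=1e-8, rtol=0.0):
            raise NumericalError(f"{name} Laplacian is not symmetric")
    p, q = Y.shape
    A = 2.0 * beta * L_SL + np.eye(p)
    B = 2.0 * alpha * L_SD
    lam, U = np.linalg.eigh((A + A.T) / 2.0)
    mu, V = np.linalg.eigh((B + B.T) / 2.0)
    C = U.T @ Y @ V
    F = U @ (C / (lam[:, None] + mu[None, :])) @ V.T
    return F


def objective_value(
    state: ConsensusState,
    views: ViewSet,
    Y: np.ndarray,
    params: HyperParams,
) -> float:
    """Evaluate the joint objective at the given state."""
    AD = views.disease_arrays()
    AL = views.lncrna_arrays()
    F = state.F
    fit_D = state.SD - sum(w * A for w, A in zip(state.wD, AD, strict=True))
    fit_L = state.SL - sum(w * A for w, A in zip(state.wL, AL, strict=True))
    L_SD = build_laplacian(state.SD)
    L_SL = build_laplacian(state.SL)
    return float(
        np.sum(fit_D**2)
        + 2.0 * params.alpha * np.trace(F @ L_SD @ F.T)
        + np.sum(fit_L**2)
        + 2.0 * params.beta * np.trace(F.T @ L_SL @ F)
        + np.sum((F - Y) ** 2)
    )


def fit(
    Y: AssociationMatrix | np.ndarray,
    views: ViewSet,
    params: HyperParams | None = None,
) -> ConsensusState:
    """Alternating optimization of the joint objective.

    View weights start uniform and F starts at Y. The inner loop cycles
    exact block updates of SD, SL and F until the relative objective change
    drops below ``inner_tol``; the outer loop refits the view weights and
    repeats until the change across outer sweeps drops below ``outer_tol``.
    The objective trace records the value after every block update.
    """
    params = params or HyperParams()
    Yv = Y.values if isinstance(Y, AssociationMatrix) else np.asarray(Y, dtype=float)
    p, q = Yv.shape
    AD = views.disease_arrays()
    AL = views.lncrna_arrays()
    if AD[0].shape[0] != q or AL[0].shape[0] != p:
        raise ValueError(
            f"views ({AL[0].shape[0]} lncRNAs, {AD[0].shape[0]} diseases) do not "
            f"match Y of shape {Yv.shape}"
        )
    n, m = len(AD), len(AL)

    state = ConsensusState(
        SD=simplex_project_rows(sum(AD) / n),
        SL=simplex_project_rows(sum(AL) / m),
        wD=np.full(n, 1.0 / n),
        wL=np.full(m, 1.0 / m),
        F=Yv.copy(),
    )
    trace = state.objective_trace

    def record(block: str) -> float:
        value = objective_value(state, views, Yv, params)
        if not np.isfinite(value):
            raise NumericalError(f"non-finite objective after {block} update")
        trace.append(value)
        return value

    record("initialization")
    outer_prev = trace[-1]
    for outer in range(params.max_outer):
        inner_prev = trace[-1]
        for _ in range(params.max_inner):
            state.SD = update_consensus_graph(AD, state.wD, state.F, params.alpha, "disease")
            record("SD")
            state.SL = update_consensus_graph(AL, state.wL, state.F, params.beta, "lncrna")
            record("SL")
            state.F = solve_label_matrix(
                build_laplacian(state.SL), build_laplacian(state.SD),
                Yv, params.alpha, params.beta,
            )
            current = record("F")
            if _relative_change(inner_prev, current) < params.inner_tol:
                break
            inner_prev = current
        state.wD = update_view_weights(state.SD, AD)
        state.wL = update_view_weights(state.SL, AL)
        current = record("weights")
        state.n_outer = outer + 1
        if _relative_change(outer_prev, current) < params.outer_tol:
            state.converged = True
            break
        outer_prev = current
    return state


def _relative_change(prev: float, current: float) -> float:
    if prev == 0.0:
        return abs(current)
    return abs(prev - current) / abs(prev)
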