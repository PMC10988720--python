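"""L1-penalized sparse precision-matrix estimation (graphical lasso).

Solves

    max_Lambda  log det(Lambda) - trace(S Lambda) - rho * ||Lambda||_1

where the L1 penalty runs over ALL entries of Lambda, diagonal included
(the common off-diagonal-only variant is available behind
``penalize_diagonal=False``).  The solver is the classic block
coordinate descent on the dual covariance estimate W: one row/column at
a time, each solved exactly by a coordinate-descent lasso.  With the
diagonal penalized, stationarity fixes W_ii = S_ii + rho, which is also
the cold start.

Zeros of the estimate are exact (soft-thresholding), so the sparsity
pattern of Lambda is directly the conditional-independence graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .datatypes import PlomconError


class ConvergenceError(PlomconError):
    """Solver failed to converge; carries the objective trace so far."""

    def __init__(self, message: str, objective_trace: list[float]):
        super().__init__(message)
        self.objective_trace = objective_trace


@dataclass
class CovarianceModel:
    """Fitted sparse precision estimate for one sample covariance.

    Attributes
    ----------
    S : (K, K) sample covariance (or correlation) matrix.
    precision : (K, K) estimated precision matrix Lambda (symmetric PD).
    rho : regularization weight used.
    K : dimension.
    objective_trace : penalized log-likelihood after each full sweep.
    """

    S: np.ndarray
    precision: np.ndarray
    rho: float
    K: int
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True

    @property
    def objective(self) -> float:
        return self.objective_trace[-1] if self.objective_trace else float("nan")


def penalized_objective(
    S: np.ndarray, Lam: np.ndarray, rho: float, penalize_diagonal: bool = True
) -> float:
    """log det(Lambda) - tr(S Lambda) - rho ||Lambda||_1 (-inf if not PD)."""
    sign, logdet = np.linalg.slogdet(Lam)
    if sign <= 0:
        return -np.inf
    l1 = np.abs(Lam).sum() if penalize_diagonal else np.abs(Lam).sum() - np.abs(np.diag(Lam)).sum()
    return float(logdet - np.trace(S @ Lam) - rho * l1)


@njit(cache=True)
def _lasso_cd(W11, s12, rho, beta, tol, max_iter):  # pragma: no cover - numba
    """Coordinate descent for min_b 0.5 b'W11 b - s12'b + rho|b|_1."""
    K1 = s12.size
    for _ in range(max_iter):
        dmax = 0.0
        for k in range(K1):
            old = beta[k]
            acc = 0.0
            for j in range(K1):
                acc += W11[k, j] * beta[j]
            r = s12[k] - acc + W11[k, k] * old
            if r > rho:
                b = (r - rho) / W11[k, k]
            elif r < -rho:
                b = (r + rho) / W11[k, k]
            else:
                b = 0.0
            beta[k] = b
            d = abs(b - old)
            if d > dmax:
                dmax = d
        if dmax <= tol:
            break
    return beta


@njit(cache=True)
def _glasso_sweeps(S, W, B, rho, tol, max_iter, inner_tol, inner_max_iter):  # pragma: no cover
    """Full BCD: returns (Lambda, n_sweeps, converged, per-sweep Lambda snapshots)."""
    K = S.shape[0]
    Lam = np.zeros((K, K))
    Lam_prev = np.zeros((K, K))
    snapshots = np.zeros((max_iter, K, K))
    n_sweeps = 0
    converged = False
    idx = np.empty(K - 1, dtype=np.int64)
    for sweep in range(max_iter):
        for j in range(K):
            pos = 0
            for t in range(K):
                if t != j:
                    idx[pos] = t
                    pos += 1
            W11 = np.empty((K - 1, K - 1))
            s12 = np.empty(K - 1)
            beta = np.empty(K - 1)
            for a in range(K - 1):
                s12[a] = S[idx[a], j]
                beta[a] = B[idx[a], j]
                for b in range(K - 1):
                    W11[a, b] = W[idx[a], idx[b]]
            beta = _lasso_cd(W11, s12, rho, beta, inner_tol, inner_max_iter)
            w12 = W11 @ beta
            for a in range(K - 1):
                W[idx[a], j] = w12[a]
                W[j, idx[a]] = w12[a]
                B[idx[a], j] = beta[a]
        # reconstruct Lambda from (W, B)
        for j in range(K):
            pos = 0
            for t in range(K):
                if t != j:
                    idx[pos] = t
                    pos += 1
            dot = 0.0
            for a in range(K - 1):
                dot += W[idx[a], j] * B[idx[a], j]
            ljj = 1.0 / (W[j, j] - dot)
            Lam[j, j] = ljj
            for a in range(K - 1):
                Lam[idx[a], j] = -B[idx[a], j] * ljj
        # symmetrize, preserving exact zeros
        for a in range(K):
            for b in range(a + 1, K):
                if Lam[a, b] == 0.0 or Lam[b, a] == 0.0:
                    Lam[a, b] = 0.0
                    Lam[b, a] = 0.0
                else:
                    m = 0.5 * (Lam[a, b] + Lam[b, a])
                    Lam[a, b] = m
                    Lam[b, a] = m
        snapshots[sweep] = Lam
        n_sweeps = sweep + 1
        delta = np.abs(Lam - Lam_prev).mean()
        Lam_prev = Lam.copy()
        if sweep > 0 and delta <= tol:
            converged = True
            break
    return Lam, n_sweeps, converged, snapshots


def graphical_lasso(
    S: np.ndarray,
    rho: float,
    tol: float = 1e-5,
    max_iter: int = 200,
    penalize_diagonal: bool = True,
) -> CovarianceModel:
    """Estimate the sparse precision matrix of a sample covariance.

    Parameters
    ----------
    S : symmetric positive-semidefinite sample covariance.
    rho : nonnegative penalty weight; must be positive when S is
        singular (fewer samples than variables).
    tol : convergence threshold on the mean absolute update of Lambda
        per sweep.
    max_iter : maximum number of full sweeps; exceeding it raises
        :class:`ConvergenceError` carrying the objective trace.
    penalize_diagonal : penalize all entries (default) or off-diagonal
        entries only.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("S must be symmetric")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    K = S.shape[0]
    if rho == 0 and np.linalg.matrix_rank(S) < K:
        raise ValueError("rho must be > 0 for a singular S")

    diag_shift = rho if penalize_diagonal else 0.0
    if K == 1:
        lam = 1.0 / (S[0, 0] + diag_shift)
        Lam = np.array([[lam]])
        obj = penalized_objective(S, Lam, rho, penalize_diagonal)
        return CovarianceModel(S=S, precision=Lam, rho=rho, K=1,
                               objective_trace=[obj], n_iter=1)
    if rho == 0:
        Lam = np.linalg.inv(S)
        Lam = 0.5 * (Lam + Lam.T)
        obj = penalized_objective(S, Lam, rho, penalize_diagonal)
        return CovarianceModel(S=S, precision=Lam, rho=rho, K=K,
                               objective_trace=[obj], n_iter=1)

    W = S.copy()
    W[np.diag_indices(K)] = np.diag(S) + diag_shift
    B = np.zeros((K, K))
    Lam, n_sweeps, converged, snapshots = _glasso_sweeps(
        S, W, B, rho, tol, max_iter, tol * 1e-2, 1000
    )
    trace = [
        penalized_objective(S, snapshots[i], rho, penalize_diagonal) for i in range(n_sweeps)
    ]
    if not converged:
        raise ConvergenceError(
            f"graphical lasso did not converge in {max_iter} sweeps", trace
        )
    eigmin = float(np.linalg.eigvalsh(Lam).min())
    if eigmin <= 0:
        raise ConvergenceError("estimated precision matrix is not positive definite", trace)
    return CovarianceModel(S=S, precision=Lam, rho=rho, K=K,
                           objective_trace=trace, n_iter=n_sweeps, converged=True)


def kkt_violation(
    S: np.ndarray, Lam: np.ndarray, rho: float, penalize_diagonal: bool = True
) -> float:
    """Maximum violation of the stationarity (subgradient) conditions.

    At the optimum, W = Lambda^{-1} satisfies W_ij - S_ij = rho*sign(Lambda_ij)
    on nonzero entries and |W_ij - S_ij| <= rho on zero entries (diagonal
    included when penalized; otherwise W_ii = S_ii).
    """
    W = np.linalg.inv(Lam)
    G = W - S
    nz = Lam != 0
    viol_nz = np.abs(G - rho * np.sign(Lam))
    viol_z = np.maximum(np.abs(G) - rho, 0.0)
    V = np.where(nz, viol_nz, viol_z)
    if not penalize_diagonal:
        V[np.diag_indices_from(V)] = np.abs(np.diag(G))
    return float(V.max())


def partial_correlation(Lam: np.ndarray) -> np.ndarray:
    """Partial correlations from a precision matrix.

    P_ij = -Lambda_ij / sqrt(Lambda_ii * Lambda_jj) off the diagonal;
    the diagonal is set to 1 by convention.
    """
    Lam = np.asarray(Lam, dtype=float)
    if Lam.ndim != 2 or Lam.shape[0] != Lam.shape[1]:
        raise ValueError("precision matrix must be square")
    if not np.allclose(Lam, Lam.T, atol=1e-8):
        raise ValueError("precision matrix must be symmetric")
    d = np.diag(Lam)
    if np.any(d <= 0):
        raise ValueError("precision matrix must have a strictly positive diagonal")
    P = -Lam / np.sqrt(np.outer(d, d))
    np.fill_diagonal(P, 1.0)
    return P
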