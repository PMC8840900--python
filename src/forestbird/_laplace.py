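"""Structured linear algebra for the Laplace approximation.

The inner (random-effect) Hessian of the joint negative log-likelihood has a
block-arrow layout in the ordering (ε₁, …, ε_T, ω): the ε blocks are
block-tridiagonal in time (AR(1) precision ⊗ R⁻¹ plus a diagonal observation
curvature), and ω couples to every ε_t through a diagonal block.  A block
Cholesky factorization with fill-in confined to the ω row gives solves and the
log-determinant in O(T·x³) instead of O((T·x)³).

Hot path: uses BLAS (trsm/syrk/gemm) and LAPACK (potrf) directly to avoid
wrapper overhead; matrices here are small-to-moderate dense blocks.
"""

from __future__ import annotations

import numpy as np
from numpy.linalg import LinAlgError
from scipy.linalg import solve_triangular
from scipy.linalg.blas import dgemm, dsyrk, dtrsm
from scipy.linalg.lapack import dpotrf, dpotri

__all__ = ["BlockArrowFactor", "factor_block_arrow"]


def _sym_from_tri(a: np.ndarray, lower: bool = True) -> np.ndarray:
    tri = np.tril(a) if lower else np.triu(a)
    return tri + tri.T - np.diag(np.diag(a))


def _rtrsolve(B: np.ndarray, L: np.ndarray) -> np.ndarray:
    """X = B @ inv(L) for lower-triangular L (right-side trsm)."""
    return dtrsm(1.0, L, B, side=1, lower=1, trans_a=0)


def _chol_lower(a: np.ndarray) -> np.ndarray:
    c, info = dpotrf(a, lower=1, clean=0, overwrite_a=0)
    if info != 0:
        raise LinAlgError(f"block not positive-definite (potrf info={info})")
    return c  # lower triangle valid; upper contains stale input


class BlockArrowFactor:
    """Cholesky factor of a symmetric positive-definite block-arrow matrix.

    Blocks (all x × x): diagonal ``D[t]`` for t = 0..T-1, sub-diagonal
    ``A[t]`` (block (t, t-1)), arrow row ``E[t]`` (block (ω, t), diagonal as
    input), and tail ``D_tail`` (block (ω, ω)).
    """

    def __init__(self, L_diag, L_sub, L_arrow, L_tail, x: int, T: int):
        self.L_diag = L_diag
        self.L_sub = L_sub
        self.L_arrow = L_arrow
        self.L_tail = L_tail
        self.x = x
        self.T = T

    @property
    def logdet(self) -> float:
        val = 2.0 * sum(float(np.sum(np.log(np.diag(L)))) for L in self.L_diag)
        val += 2.0 * float(np.sum(np.log(np.diag(self.L_tail))))
        return val

    def solve(self, rhs_eps: np.ndarray, rhs_tail: np.ndarray):
        """Solve H [eps; tail] = [rhs_eps; rhs_tail]; rhs_eps is (T, x)."""
        x, T = self.x, self.T
        y = np.empty((T, x))
        for t in range(T):
            r = rhs_eps[t].copy()
            if t > 0:
                r -= self.L_sub[t - 1] @ y[t - 1]
            y[t] = solve_triangular(self.L_diag[t], r, lower=True, check_finite=False)
        r_tail = rhs_tail - sum(self.L_arrow[t] @ y[t] for t in range(T))
        y_tail = solve_triangular(self.L_tail, r_tail, lower=True, check_finite=False)

        z_tail = solve_triangular(
            self.L_tail, y_tail, trans="T", lower=True, check_finite=False
        )
        z = np.empty((T, x))
        for t in range(T - 1, -1, -1):
            r = y[t] - self.L_arrow[t].T @ z_tail
            if t < T - 1:
                r -= self.L_sub[t].T @ z[t + 1]
            z[t] = solve_triangular(
                self.L_diag[t], r, trans="T", lower=True, check_finite=False
            )
        return z, z_tail

    def selected_inverse(self):
        """Blocks of H⁻¹ on the factor's fill pattern (Takahashi recurrence).

        Returns ``(Z_diag, Z_sub, Z_arrow, Z_tail)``: the diagonal blocks
        [H⁻¹]_{t,t}, the sub-diagonal blocks [H⁻¹]_{t+1,t}, the arrow blocks
        [H⁻¹]_{ω,t}, and the tail block [H⁻¹]_{ω,ω}.  These are exactly the
        entries needed for trace terms against the Hessian's sparsity.
        """
        T = self.T
        Z_tail, info = dpotri(self.L_tail, lower=1)
        if info != 0:
            raise LinAlgError("potri failed on tail block")
        Z_tail = _sym_from_tri(Z_tail)
        Z_diag: list = [None] * T
        Z_sub: list = [None] * max(T - 1, 0)
        Z_arrow: list = [None] * T
        for t in range(T - 1, -1, -1):
            Lt = self.L_diag[t]
            # Z_{ω,t} = -(Z_{ω,t+1} L_{t+1,t} + Z_{ω,ω} L_{ω,t}) L_tt^{-1}
            S = Z_tail @ self.L_arrow[t]
            if t < T - 1:
                S = S + Z_arrow[t + 1] @ self.L_sub[t]
            Z_arrow[t] = -_rtrsolve(S, Lt)
            if t < T - 1:
                # Z_{t+1,t} = -(Z_{t+1,t+1} L_{t+1,t} + Z_{t+1,ω} L_{ω,t}) L_tt^{-1}
                S = Z_diag[t + 1] @ self.L_sub[t] + Z_arrow[t + 1].T @ self.L_arrow[t]
                Z_sub[t] = -_rtrsolve(S, Lt)
            # Z_{t,t} = (L_tt L_tt^T)^{-1} - (Z_{t,t+1} L_{t+1,t} + Z_{t,ω} L_{ω,t}) L_tt^{-1}
            Ainv, info = dpotri(Lt, lower=1)
            if info != 0:
                raise LinAlgError("potri failed on diagonal block")
            Zt = _sym_from_tri(Ainv)
            S = Z_arrow[t].T @ self.L_arrow[t]
            if t < T - 1:
                S = S + Z_sub[t].T @ self.L_sub[t]
            Zt = Zt - _rtrsolve(S, Lt)
            Z_diag[t] = 0.5 * (Zt + Zt.T)
        return Z_diag, Z_sub, Z_arrow, Z_tail


def factor_block_arrow(
    D: list[np.ndarray],
    A: list[np.ndarray],
    E_diag: list[np.ndarray],
    D_tail: np.ndarray,
) -> BlockArrowFactor:
    """Block Cholesky of the arrow matrix; raises LinAlgError if not SPD.

    ``D`` has T dense diagonal blocks, ``A`` has T-1 sub-diagonal blocks,
    ``E_diag`` has T diagonal vectors coupling each ε_t to the tail block,
    ``D_tail`` is the dense tail (ω) block.
    """
    T = len(D)
    x = D[0].shape[0]
    L_diag: list[np.ndarray] = []
    L_sub: list[np.ndarray] = []
    L_arrow: list[np.ndarray] = []
    S_tail = np.array(D_tail, dtype=float, order="F", copy=True)
    C_prev = None  # fill carried into the (tail, t) block
    for t in range(T):
        Dt = D[t]
        Ct = np.zeros((x, x), order="F")
        np.fill_diagonal(Ct, E_diag[t])
        if t > 0:
            # L_sub[t-1] = A[t-1] @ inv(L_diag[t-1]).T  (right-side trsm)
            Lsub = dtrsm(1.0, L_diag[t - 1], A[t - 1], side=1, lower=1, trans_a=1)
            L_sub.append(Lsub)
            # Dt := Dt - Lsub Lsub^T (lower triangle suffices for potrf)
            Dt = dsyrk(-1.0, Lsub, beta=1.0, c=Dt, lower=1, trans=0)
            Ct = dgemm(-1.0, C_prev, Lsub, beta=1.0, c=Ct, trans_b=1)
        Lt = _chol_lower(Dt)
        L_diag.append(Lt)
        Larr = dtrsm(1.0, Lt, Ct, side=1, lower=1, trans_a=1)
        L_arrow.append(Larr)
        S_tail = dsyrk(-1.0, Larr, beta=1.0, c=S_tail, lower=1, trans=0)
        C_prev = Larr
    L_tail = _chol_lower(S_tail)
    return BlockArrowFactor(L_diag, L_sub, L_arrow, L_tail, x=x, T=T)
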