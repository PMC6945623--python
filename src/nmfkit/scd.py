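"""Penalized non-negative least squares by sequential coordinate-wise descent.

Solving H given W under the (halved) square loss with penalties is the
quadratic program

    min_{H >= 0}  tr( H^T V H ) / 2  +  tr( H^T U )

with

    V = W^T W + beta1 * I + beta2 * (E - I)
    U = -W^T A + beta3 * E.

Each coordinate ``h[kbar, j]`` has an exact single-variable minimizer

    h* = max(0, h - (V H + U)[kbar, j] / V[kbar, kbar])

and the running gradient ``G = V H + U`` is patched incrementally after
every accepted change, so a full sweep over the k coordinates costs
O(k^2 m) instead of re-forming the gradient.  Columns j are independent
and are updated in parallel (vectorized across columns).

When the target has missing entries the Gram matrix is restricted, per
column, to the observed rows I_j:

    V_j = W[I_j]^T W[I_j] + beta1 * I + beta2 * (E - I)
    U[:, j] = -W[I_j]^T A[I_j, j] + beta3,

so V depends on j and is stored as a batched (m, k, k) array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .losses import EPS_DEFAULT, RegularizationSpec, TargetMatrix

__all__ = ["QuadraticSystem", "build_system", "scd_solve", "quad_objective"]


@dataclass
class QuadraticSystem:
    """The (V, U) pair of a penalized NNLS subproblem.

    ``V`` has shape (k, k) when shared by all columns, or (m, k, k) when
    the target has missing entries and V depends on the column.  ``U`` is
    always (k, m).
    """

    V: np.ndarray
    U: np.ndarray
    per_column: bool

    @property
    def k(self) -> int:
        return self.U.shape[0]

    @property
    def m(self) -> int:
        return self.U.shape[1]

    def gradient(self, H: np.ndarray) -> np.ndarray:
        """V @ H + U, column by column (the fresh, non-incremental gradient)."""
        if self.per_column:
            return self.U + np.einsum("jkl,lj->kj", self.V, H)
        return self.U + self.V @ H

    def diagonals(self) -> np.ndarray:
        """Diagonal of V per column: shape (k,) shared or (k, m) batched."""
        k = self.k
        if self.per_column:
            return self.V[:, np.arange(k), np.arange(k)].T
        return np.diagonal(self.V).copy()


def _penalty_terms(k: int, b1: float, b2: float) -> np.ndarray:
    """beta1 * I + beta2 * (E - I) as a (k, k) array."""
    P = np.full((k, k), b2, dtype=float)
    np.fill_diagonal(P, b1)
    return P


def masked_gram(W: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Batched column-restricted Gram matrices W[I_j]^T W[I_j], shape (m, k, k).

    Computed as one BLAS product of the (k^2, n) outer-product table with
    the (n, m) observation mask.
    """
    n, k = W.shape
    pairs = (W[:, :, None] * W[:, None, :]).reshape(n, k * k)
    M = observed.astype(float)
    return (M.T @ pairs).reshape(observed.shape[1], k, k)


def build_system(A: TargetMatrix, W: np.ndarray,
                 reg: RegularizationSpec | tuple[float, float, float] | None = None,
                 ) -> QuadraticSystem:
    """Assemble the penalized NNLS system for solving H given W.

    ``reg`` may be a full :class:`RegularizationSpec` (its beta weights are
    used — pass ``reg.transposed()`` when solving the W side) or a bare
    ``(b1, b2, b3)`` triple.  Requires ``b1 > b2`` or ``b2 == 0`` so the
    diagonal of V cannot be driven negative by the penalty.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != A.n_rows:
        raise ValueError(f"W shape {W.shape} does not conform to target "
                         f"with {A.n_rows} rows")
    if W.size and W.min() < 0:
        raise ValueError("W must be non-negative")
    if reg is None:
        b1 = b2 = b3 = 0.0
    elif isinstance(reg, RegularizationSpec):
        b1, b2, b3 = reg.betas
    else:
        b1, b2, b3 = (float(v) for v in reg)
    if not (b1 > b2 or b2 == 0):
        raise ValueError(f"need beta1 > beta2 or beta2 == 0 "
                         f"(got beta1={b1}, beta2={b2})")
    k = W.shape[1]
    # A.filled zeroes unobserved entries, so -W^T A.filled realizes the
    # row-restricted cross product in both the full and missing cases.
    U = -(W.T @ A.filled)
    if b3:
        U = U + b3
    P = _penalty_terms(k, b1, b2)
    if A.fully_observed:
        return QuadraticSystem(V=W.T @ W + P, U=U, per_column=False)
    return QuadraticSystem(V=masked_gram(W, A.observed) + P, U=U,
                           per_column=True)


def scd_solve(system: QuadraticSystem, H0: np.ndarray, n_inner: int,
              fixed: np.ndarray | None = None, early_stop: bool = True,
              inner_rel_tol: float = 1e-9,
              eps: float = EPS_DEFAULT) -> tuple[np.ndarray, int]:
    """Run up to ``n_inner`` full coordinate sweeps from the warm start H0.

    Parameters
    ----------
    H0 : (k, m) non-negative warm start (all zeros for a cold start).
    fixed : (k, m) boolean, optional
        Entries flagged True are held at their H0 value (hard masking);
        the other coordinates account for them through the gradient.
    early_stop : stop sweeping once the largest coordinate change of a
        sweep falls below ``inner_rel_tol`` times the largest entry of H
        (in particular when no coordinate changed at all) — the solve is
        then at a fixed point to working precision and further sweeps
        would only consume epochs.

    Returns
    -------
    (H, sweeps_run)

    Raises
    ------
    ValueError
        If a diagonal entry of V is negative (the penalty positivity
        condition was violated).  An *exactly zero* diagonal — a factor
        column collapsed to zeros, routine when k exceeds the true rank —
        is floored at ``eps`` so the coordinate update takes its
        well-defined limit instead of aborting.
    """
    if n_inner < 1:
        raise ValueError("n_inner must be >= 1")
    H = np.array(H0, dtype=float, copy=True)
    if H.shape != system.U.shape:
        raise ValueError(f"H0 shape {H.shape} does not match system "
                         f"shape {system.U.shape}")
    if H.size and H.min() < 0:
        raise ValueError("H0 must be non-negative")
    k = system.k
    diag = system.diagonals()
    if diag.size and diag.min() < 0:
        raise ValueError("V has a negative diagonal entry; "
                         "require beta1 > beta2 or beta2 == 0")
    diag = np.maximum(diag, eps)
    per_col = system.per_column
    V = system.V
    G = system.gradient(H)
    sweeps = 0
    for _ in range(n_inner):
        sweeps += 1
        max_change = 0.0
        for kk in range(k):
            d = diag[kk]
            hn = H[kk] - G[kk] / d
            np.maximum(hn, 0.0, out=hn)
            if fixed is not None:
                np.copyto(hn, H[kk], where=fixed[kk])
            delta = hn - H[kk]
            idx = np.flatnonzero(delta)
            if idx.size:
                max_change = max(max_change, float(np.abs(delta[idx]).max()))
                H[kk] = hn
                if per_col:
                    G[:, idx] += V[idx, :, kk].T * delta[idx]
                else:
                    G[:, idx] += V[:, kk, None] * delta[idx]
        if early_stop and max_change <= inner_rel_tol * max(float(H.max(initial=0.0)), eps):
            break
    return H, sweeps


def quad_objective(system: QuadraticSystem, H: np.ndarray) -> float:
    """tr(H^T V H)/2 + tr(H^T U) — the quantity each sweep non-increases."""
    H = np.asarray(H, dtype=float)
    if system.per_column:
        vh = np.einsum("jkl,lj->kj", system.V, H)
    else:
        vh = system.V @ H
    return 0.5 * float(np.sum(H * vh)) + float(np.sum(H * system.U))
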