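"""Coordinate descent for the KL-divergence loss by sequential quadratic
approximation.

The generalized KL divergence is not quadratic in a single coordinate, so
each coordinate step minimizes its second-order Taylor model instead.  For
coordinate ``h[kbar, j]`` with current reconstruction ``WH``:

    b = d KL / d h      = sum_l ( w[l,kbar] - a[l,j] w[l,kbar] / (WH)[l,j] )
    a = d^2 KL / d h^2  = sum_l a[l,j] * ( w[l,kbar] / (WH)[l,j] )^2

(sums over the observed rows l of column j), and the clamped Newton step
with the penalty terms folded in is

    h_new = max(0, (a*h - b - beta2*cross - beta3) / (a + beta1))

where ``cross`` is the current column sum of H excluding kbar.  The
reconstruction column is patched incrementally after each accepted change.
All denominators carry an additive eps guard.
"""

from __future__ import annotations

import numpy as np

from .losses import EPS_DEFAULT, TargetMatrix

__all__ = ["kl_coordinate_terms", "kl_coordinate_update", "kl_solve"]


def kl_coordinate_terms(A: TargetMatrix, W: np.ndarray, H: np.ndarray,
                        kbar: int, j: int,
                        eps: float = EPS_DEFAULT) -> tuple[float, float]:
    """First and second derivative (b, a) of the observed-entry KL loss of
    column j with respect to ``H[kbar, j]``.

    Rows with ``a[l, j] == 0`` contribute ``w[l, kbar]`` to b and nothing
    to a.
    """
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    obs = A.observed[:, j]
    w = W[obs, kbar]
    a_col = A.values[obs, j]
    wh = W[obs] @ H[:, j] + eps
    b = float(np.sum(w - a_col * w / wh))
    a = float(np.sum(a_col * (w / wh) ** 2))
    return b, a


def kl_coordinate_update(h_old: float, a: float, b: float, cross: float,
                         betas: tuple[float, float, float],
                         eps: float = EPS_DEFAULT) -> float:
    """Clamped Newton step on the penalized quadratic model.

    ``cross`` is the current sum of the other coordinates of the column
    (feeds the beta2 angle penalty).
    """
    b1, b2, b3 = betas
    return max(0.0, (a * h_old - b - b2 * cross - b3) / (a + b1 + eps))


def kl_solve(A: TargetMatrix, W: np.ndarray, H0: np.ndarray,
             betas: tuple[float, float, float] = (0.0, 0.0, 0.0),
             n_inner: int = 1, eps: float = EPS_DEFAULT,
             fixed: np.ndarray | None = None,
             early_stop: bool = True,
             inner_rel_tol: float = 1e-9) -> tuple[np.ndarray, int]:
    """Sweep all coordinates of H (vectorized across columns) ``n_inner``
    times; returns ``(H, sweeps_run)``.

    The reconstruction ``W @ H`` is maintained incrementally: after each
    accepted coordinate change the affected columns are rank-1 patched, so
    the derivative terms of later coordinates always see the current H.
    """
    if n_inner < 1:
        raise ValueError("n_inner must be >= 1")
    W = np.asarray(W, dtype=float)
    H = np.array(H0, dtype=float, copy=True)
    k, m = H.shape
    if W.shape != (A.n_rows, k) or m != A.n_cols:
        raise ValueError("factor shapes do not conform to the target")
    if (W.size and W.min() < 0) or (H.size and H.min() < 0):
        raise ValueError("factors must be non-negative")
    b1, b2, b3 = betas
    Mf = A.observed.astype(float)
    Af = A.filled
    WH = W @ H
    fully = A.fully_observed
    wsums = W.sum(axis=0)  # used only when fully observed
    sweeps = 0
    for _ in range(n_inner):
        sweeps += 1
        max_change = 0.0
        colsum = H.sum(axis=0)
        for kk in range(k):
            w = W[:, kk]
            denom = WH + eps
            ratio = Af / denom        # zero at unobserved entries
            if fully:
                b = wsums[kk] - w @ ratio
            else:
                b = w @ Mf - w @ ratio
            a = (w * w) @ (ratio / denom)
            cross = colsum - H[kk]
            hn = (a * H[kk] - b - b2 * cross - b3) / (a + b1 + eps)
            np.maximum(hn, 0.0, out=hn)
            if fixed is not None:
                np.copyto(hn, H[kk], where=fixed[kk])
            delta = hn - H[kk]
            idx = np.flatnonzero(delta)
            if idx.size:
                max_change = max(max_change, float(np.abs(delta[idx]).max()))
                H[kk] = hn
                colsum[idx] += delta[idx]
                WH[:, idx] += w[:, None] * delta[idx]
        if early_stop and max_change <= inner_rel_tol * max(float(H.max(initial=0.0)), eps):
            break
    return H, sweeps
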