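"""Generalized Lee multiplicative updates with the unified penalties.

Square loss (entrywise over H):

    h <- h * (W^T A) / ( [W^T W + b1*I + b2*(E-I)] H + b3*E )

KL loss:

    h[kbar,j] <- h[kbar,j] * sum_l( w[l,kbar] a[l,j] / (WH)[l,j] )
                 / ( sum_l w[l,kbar] + (b1-b2) h[kbar,j] + b2 sum_l h[l,j] + b3 )

With all weights zero these are the original multiplicative rules.  With
missing entries, W^T W and W^T A are restricted per column to the observed
rows, exactly as in the coordinate-descent solver.  A multiplicative update
preserves sign: an entry initialized at zero stays zero forever, so the
driver warns when a zero initialization is paired with these rules.
"""

from __future__ import annotations

import numpy as np

from .losses import EPS_DEFAULT, TargetMatrix
from .scd import masked_gram, _penalty_terms

__all__ = ["lee_update_mse", "lee_update_kl"]


def _check(A: TargetMatrix, W, H):
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    if W.shape != (A.n_rows, H.shape[0]) or H.shape[1] != A.n_cols:
        raise ValueError("factor shapes do not conform to the target")
    if (W.size and W.min() < 0) or (H.size and H.min() < 0):
        raise ValueError("factors must be non-negative")
    return W, H


def lee_update_mse(A: TargetMatrix, W, H,
                   betas: tuple[float, float, float] = (0.0, 0.0, 0.0),
                   n_inner: int = 1, eps: float = EPS_DEFAULT,
                   fixed: np.ndarray | None = None) -> np.ndarray:
    """``n_inner`` multiplicative square-loss updates of H given W.

    Looping the update reuses the expensive cross products (they depend
    only on W), which is why the square-loss rule benefits from multiple
    inner iterations.
    """
    if n_inner < 1:
        raise ValueError("n_inner must be >= 1")
    W, H = _check(A, W, H)
    b1, b2, b3 = betas
    k = W.shape[1]
    num = W.T @ A.filled
    P = _penalty_terms(k, b1, b2)
    if A.fully_observed:
        V = W.T @ W + P
        Vb = None
    else:
        Vb = masked_gram(W, A.observed) + P
    H = H.copy()
    for _ in range(n_inner):
        if Vb is None:
            denom = V @ H + b3 + eps
        else:
            denom = np.einsum("jkl,lj->kj", Vb, H) + b3 + eps
        Hn = H * (num / denom)
        if fixed is not None:
            np.copyto(Hn, H, where=fixed)
        H = Hn
    return H


def lee_update_kl(A: TargetMatrix, W, H,
                  betas: tuple[float, float, float] = (0.0, 0.0, 0.0),
                  n_inner: int = 1, eps: float = EPS_DEFAULT,
                  fixed: np.ndarray | None = None) -> np.ndarray:
    """``n_inner`` multiplicative KL updates of H given W.

    Unlike the square-loss rule, each pass must recompute W @ H, so inner
    iterations buy nothing; the default is a single pass.
    """
    if n_inner < 1:
        raise ValueError("n_inner must be >= 1")
    W, H = _check(A, W, H)
    b1, b2, b3 = betas
    if A.fully_observed:
        wsum = W.sum(axis=0)[:, None]
    else:
        wsum = W.T @ A.observed.astype(float)
    H = H.copy()
    for _ in range(n_inner):
        WH = W @ H + eps
        num = W.T @ (A.filled / WH)   # filled zeroes the unobserved terms
        denom = wsum + (b1 - b2) * H + b2 * H.sum(axis=0)[None, :] + b3 + eps
        Hn = H * (num / denom)
        if fixed is not None:
            np.copyto(Hn, H, where=fixed)
        H = Hn
    return H
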