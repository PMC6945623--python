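"""Missing-value imputation by low-rank reconstruction.

Because the factorization uses only the observed entries, the
reconstruction ``W @ H`` extends naturally to the missing positions and
serves as their prediction.  Unlike feature-by-feature imputers, a single
factorization borrows strength from every observed entry at once.  The
procedure assumes the entries are missing completely at random (MCAR):
when missingness correlates with the values themselves the reconstruction
is biased.
"""

from __future__ import annotations

import warnings

import numpy as np

from .driver import FactorizationConfig, FactorizationResult, factorize
from .losses import TargetMatrix

__all__ = ["impute", "median_impute"]


def impute(A: TargetMatrix, config: FactorizationConfig
           ) -> tuple[np.ndarray, FactorizationResult | None]:
    """Complete A by factorizing its observed entries.

    Returns ``(A_completed, result)`` where ``A_completed`` equals A at
    the observed positions (bit-exact pass-through) and the non-negative
    reconstruction ``W @ H`` at the missing ones.  A fully observed input
    is returned unchanged with a warning (and ``result=None``).
    """
    if not isinstance(A, TargetMatrix):
        A = TargetMatrix(A)
    if A.fully_observed:
        warnings.warn("input has no missing entries; nothing to impute",
                      stacklevel=2)
        return A.values.copy(), None
    result = factorize(A, config)
    completed = np.where(A.observed, A.values, result.reconstruction())
    return completed, result


def median_impute(A: TargetMatrix) -> np.ndarray:
    """Baseline imputer: each missing entry gets the median of its
    column's observed values."""
    if not isinstance(A, TargetMatrix):
        A = TargetMatrix(A)
    vals = np.where(A.observed, A.values, np.nan)
    med = np.nanmedian(vals, axis=0)
    return np.where(A.observed, A.values, med[None, :])
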