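"""Shared data types, loss functions and regularization penalties.

Non-negative matrix factorization approximates a non-negative data matrix
``A`` (features x samples) by a low-rank product ``W @ H`` with ``W >= 0``
and ``H >= 0``, minimizing

    sum over observed entries of L(a_ij, (WH)_ij)  +  J_W(W)  +  J_H(H)

where the per-entry loss ``L`` is either halved square error
``(a - y)^2 / 2`` (the deviance of a Gaussian model) or generalized
Kullback-Leibler divergence ``a*log(a/y) - a + y`` (the deviance of a
Poisson model).  The penalties are non-negative combinations of three
functionals applied to ``W`` and to ``H.T``:

* ``J1(X) = ||X||_F^2 / 2`` — a ridge term that controls magnitude and
  stabilizes the numerics,
* ``J2(X) = sum_{i<j} X[:,i] . X[:,j]`` — an angle/independence term that
  discourages correlated columns,
* ``J3(X) = sum |x_ij|`` — a lasso-like term for matrix-wise sparsity.

``J1 + J2`` equals ``tr(X E X^T) / 2`` (``E`` the all-ones matrix), the
column-wise sparsity penalty popular in sparse NMF.

Everything in this module is a pure function of its arguments; the solvers
build on these definitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: Guard added to denominators that may vanish (reconstruction entries under
#: the KL loss, second-derivative terms, multiplicative denominators).
EPS_DEFAULT = 1e-16


class TargetMatrix:
    """A non-negative data matrix with an explicit observed-entry pattern.

    Parameters
    ----------
    values : array-like, shape (n, m)
        The data.  Entries at unobserved positions are ignored by every
        computation in this package (they may hold NaN or garbage).
    observed : array-like of bool, shape (n, m), optional
        True where the entry is present and trusted.  Default: every
        non-NaN entry of ``values``.
    row_names, col_names : sequence of str, optional
        Labels carried through I/O round trips.

    Raises
    ------
    ValueError
        If any observed entry is negative or non-finite, or if some row or
        column has no observed entry at all — reconstruction for such a
        row/column would rest on no data and is unreliable, so the matrix
        is rejected at load time.
    """

    __slots__ = ("values", "observed", "row_names", "col_names", "_filled")

    def __init__(self, values, observed=None, row_names=None, col_names=None):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        if observed is None:
            observed = ~np.isnan(values)
        observed = np.asarray(observed, dtype=bool)
        if observed.shape != values.shape:
            raise ValueError(
                f"observed pattern shape {observed.shape} does not match "
                f"values shape {values.shape}"
            )
        obs_vals = values[observed]
        if not np.all(np.isfinite(obs_vals)):
            raise ValueError("observed entries must be finite")
        if obs_vals.size and obs_vals.min() < 0:
            i, j = np.argwhere(observed & (values < 0))[0]
            raise ValueError(
                f"negative entry {values[i, j]} at row {i + 1}, column {j + 1}: "
                "the target matrix must be non-negative"
            )
        rows_ok = observed.any(axis=1)
        if not rows_ok.all():
            bad = np.flatnonzero(~rows_ok)[:5] + 1
            raise ValueError(
                f"row(s) {list(bad)} have no observed entries; reconstruction "
                "there is not reliable — drop them before factorizing"
            )
        cols_ok = observed.any(axis=0)
        if not cols_ok.all():
            bad = np.flatnonzero(~cols_ok)[:5] + 1
            raise ValueError(
                f"column(s) {list(bad)} have no observed entries; reconstruction "
                "there is not reliable — drop them before factorizing"
            )
        self.values = values
        self.observed = observed
        self.row_names = tuple(row_names) if row_names is not None else None
        self.col_names = tuple(col_names) if col_names is not None else None
        # Unobserved positions zeroed: every downstream computation works on
        # this array, which guarantees unobserved values can never leak in.
        self._filled = np.where(observed, values, 0.0)

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    @property
    def fully_observed(self) -> bool:
        return bool(self.observed.all())

    @property
    def filled(self) -> np.ndarray:
        """The values with unobserved positions set to 0 (read-only view)."""
        return self._filled

    def transposed(self) -> "TargetMatrix":
        """The transposed problem (used to solve W by the H-solver)."""
        return TargetMatrix(
            self.values.T, self.observed.T,
            row_names=self.col_names, col_names=self.row_names,
        )

    def with_observed(self, observed) -> "TargetMatrix":
        """Same values under a different (more restrictive) observed pattern."""
        return TargetMatrix(self.values, observed,
                            row_names=self.row_names, col_names=self.col_names)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.shape
        return (f"TargetMatrix({n}x{m}, "
                f"{self.n_observed}/{n * m} observed)")


@dataclass(frozen=True)
class RegularizationSpec:
    """The six penalty weights: (alpha1, alpha2, alpha3) on W, (beta1,
    beta2, beta3) on H.  Index 1 is the ridge weight (J1), 2 the
    angle/independence weight (J2), 3 the sparsity weight (J3).

    The coordinate-descent solvers additionally require ``beta1 > beta2``
    (or ``beta2 == 0``) — and the same for the alphas — so the diagonal of
    the quadratic system stays strictly positive; see
    :meth:`validate_for_scd`.
    """

    alpha1: float = 0.0
    alpha2: float = 0.0
    alpha3: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0

    def __post_init__(self):
        for name in ("alpha1", "alpha2", "alpha3", "beta1", "beta2", "beta3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative number, got {v}")

    @property
    def alphas(self) -> tuple[float, float, float]:
        return (self.alpha1, self.alpha2, self.alpha3)

    @property
    def betas(self) -> tuple[float, float, float]:
        return (self.beta1, self.beta2, self.beta3)

    def transposed(self) -> "RegularizationSpec":
        """Swap the W- and H-side weights (for solving the transposed problem)."""
        return RegularizationSpec(self.beta1, self.beta2, self.beta3,
                                  self.alpha1, self.alpha2, self.alpha3)

    def validate_for_scd(self) -> None:
        """Enforce the positivity condition on the quadratic diagonal."""
        if not (self.beta1 > self.beta2 or self.beta2 == 0):
            raise ValueError(
                f"coordinate descent requires beta1 > beta2 or beta2 == 0 "
                f"(got beta1={self.beta1}, beta2={self.beta2})"
            )
        if not (self.alpha1 > self.alpha2 or self.alpha2 == 0):
            raise ValueError(
                f"coordinate descent requires alpha1 > alpha2 or alpha2 == 0 "
                f"(got alpha1={self.alpha1}, alpha2={self.alpha2})"
            )

    def penalty_W(self, W: np.ndarray) -> float:
        """J_W(W) = alpha1 J1(W) + alpha2 J2(W) + alpha3 J3(W)."""
        return _combine_penalties(W, self.alphas)

    def penalty_H(self, H: np.ndarray) -> float:
        """J_H(H) = beta1 J1(H.T) + beta2 J2(H.T) + beta3 J3(H.T).

        The penalties act on ``H.T``, i.e. on the *rows* of H, mirroring
        their action on the columns of W.
        """
        return _combine_penalties(np.asarray(H).T, self.betas)

    def total_penalty(self, W: np.ndarray, H: np.ndarray) -> float:
        return self.penalty_W(W) + self.penalty_H(H)


@dataclass(frozen=True)
class LossKind:
    """Which per-entry loss to use: ``"mse"`` (halved square error) or
    ``"mkl"`` (generalized KL divergence), plus the denominator guard used
    under KL."""

    tag: str = "mse"
    eps: float = EPS_DEFAULT

    def __post_init__(self):
        if self.tag not in ("mse", "mkl"):
            raise ValueError(f"loss tag must be 'mse' or 'mkl', got {self.tag!r}")
        if not (0 < self.eps < 1):
            raise ValueError(f"eps must lie in (0, 1), got {self.eps}")

    @property
    def is_kl(self) -> bool:
        return self.tag == "mkl"


MSE = LossKind("mse")
MKL = LossKind("mkl")


def as_loss(loss) -> LossKind:
    """Coerce a string or LossKind to a LossKind."""
    if isinstance(loss, LossKind):
        return loss
    return LossKind(str(loss).lower())


# ---------------------------------------------------------------------------
# penalties
# ---------------------------------------------------------------------------

def _checked(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("penalty input must be finite")
    return X


def penalty_J1(X) -> float:
    """Ridge penalty: half the squared Frobenius norm."""
    X = _checked(X)
    return 0.5 * float(np.sum(X * X))


def penalty_J2(X) -> float:
    """Pairwise column-correlation penalty: sum over column pairs i < j of
    their inner products (equivalently ``tr(X (E - I) X^T) / 2``)."""
    X = _checked(X)
    if X.ndim != 2 or X.shape[1] < 2:
        return 0.0
    r = X.sum(axis=1)
    return 0.5 * (float(r @ r) - float(np.sum(X * X)))


def penalty_J3(X) -> float:
    """Entrywise L1 penalty (plain sum for a non-negative matrix)."""
    X = _checked(X)
    return float(np.sum(np.abs(X)))


def _combine_penalties(X, weights: tuple[float, float, float]) -> float:
    w1, w2, w3 = weights
    total = 0.0
    if w1:
        total += w1 * penalty_J1(X)
    if w2:
        total += w2 * penalty_J2(X)
    if w3:
        total += w3 * penalty_J3(X)
    return total


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _check_factors(A: TargetMatrix, W, H) -> tuple[np.ndarray, np.ndarray]:
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    n, m = A.shape
    if W.ndim != 2 or H.ndim != 2 or W.shape[0] != n or H.shape[1] != m \
            or W.shape[1] != H.shape[0]:
        raise ValueError(
            f"factor shapes {W.shape} x {H.shape} do not conform to "
            f"target shape {(n, m)}"
        )
    if W.size and W.min() < 0 or H.size and H.min() < 0:
        raise ValueError("factor matrices must be entrywise non-negative")
    return W, H


def _observed_losses(A: TargetMatrix, W, H, loss: LossKind) -> np.ndarray:
    """Per-entry losses over the observed entries, halved-MSE convention."""
    W, H = _check_factors(A, W, H)
    obs = A.observed
    a = A.values[obs]
    yhat = (W @ H)[obs]
    if loss.is_kl:
        # 0 * log 0 := 0 ; the reconstruction is floored at eps.
        y = yhat + loss.eps
        terms = np.where(a > 0, a * np.log(np.maximum(a, loss.eps) / y), 0.0)
        return terms - a + yhat
    d = a - yhat
    return 0.5 * d * d


def loss_value(A: TargetMatrix, W, H, loss=MSE) -> float:
    """Mean per-observed-entry loss in the *objective* convention.

    MSE mode keeps the 1/2 factor of the quadratic objective; MKL mode is
    the mean generalized KL divergence.  For the reporting convention used
    in result tables (plain mean square error, no 1/2) see
    :func:`reported_error`.
    """
    loss = as_loss(loss)
    return float(np.mean(_observed_losses(A, W, H, loss)))


def reported_error(A: TargetMatrix, W, H, loss=MSE) -> float:
    """Mean per-observed-entry error in the *reporting* convention:
    plain mean square error (no 1/2 factor) under MSE, mean KL divergence
    under MKL."""
    loss = as_loss(loss)
    v = loss_value(A, W, H, loss)
    return 2.0 * v if not loss.is_kl else v


def penalized_objective(A: TargetMatrix, W, H, loss=MSE,
                        reg: RegularizationSpec | None = None) -> float:
    """The full objective: summed observed-entry loss plus both penalties.

    This is the quantity every solver step is guaranteed not to increase.
    """
    loss = as_loss(loss)
    total = float(np.sum(_observed_losses(A, W, H, loss)))
    if reg is not None:
        total += reg.total_penalty(np.asarray(W, float), np.asarray(H, float))
    return total
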