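"""The alternating outer loop: initialization, W/H alternation, epoch
accounting, convergence testing and mask enforcement.

One *epoch* is a complete scan over all entries of W and H.  Each outer
alternation solves H given W with ``n_inner`` sweeps of the configured
solver, then W given H (by transposing the problem so a single code path
exists), and therefore consumes ``n_inner`` epochs.  The total epoch
budget ``max_epochs`` caps ``n_inner * n_outer``.

Convergence is declared when the relative change of the mean
observed-entry loss between consecutive outer alternations drops below
``rel_tol``:  |loss - loss_prev| / max(loss_prev, tiny) < rel_tol.

Hard masking: entries of W or H flagged fixed in a :class:`MaskSpec` hold
their initial values (or 0 when no initial matrix is supplied) for the
whole run.  The coordinate solvers simply skip those coordinates — the
free coordinates still feel them through the gradient — so the fixed
entries come back bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import kl, multiplicative, scd
from .losses import (EPS_DEFAULT, LossKind, RegularizationSpec, TargetMatrix,
                     as_loss, penalized_objective, reported_error)

__all__ = [
    "MaskSpec", "FactorizationConfig", "FactorizationResult",
    "initialize", "factorize", "epochs_to_reach", "normalize_columns",
]

_ALGORITHMS = ("scd", "lee")


@dataclass
class MaskSpec:
    """Boolean fixed-entry patterns for W (n x k) and/or H (k x m).

    Fixed entries keep their initial values throughout the run — the value
    from ``init_W`` / ``init_H`` when given, else 0.  This is the hard
    regularization used for known-profile deconvolution and for
    marker-gene / pathway-designed factorizations.
    """

    fixed_W: Optional[np.ndarray] = None
    fixed_H: Optional[np.ndarray] = None

    def validate(self, n: int, k: int, m: int) -> None:
        if self.fixed_W is not None and np.shape(self.fixed_W) != (n, k):
            raise ValueError(
                f"fixed_W pattern shape {np.shape(self.fixed_W)} != {(n, k)}")
        if self.fixed_H is not None and np.shape(self.fixed_H) != (k, m):
            raise ValueError(
                f"fixed_H pattern shape {np.shape(self.fixed_H)} != {(k, m)}")


@dataclass
class FactorizationConfig:
    """Everything a factorization run depends on.

    Parameters
    ----------
    k : target rank.
    algorithm : "scd" (coordinate descent) or "lee" (multiplicative).
    loss : "mse" or "mkl" (or a :class:`LossKind`).
    reg : penalty weights; defaults to no regularization.
    n_inner : solver sweeps per factor per alternation (N_i).  Default
        None resolves to 50 under MSE and 1 under KL: only the square
        loss amortizes its cross products over inner sweeps.
    max_epochs : cap on total epochs N_i * N_o.
    rel_tol : relative-change convergence tolerance on the mean loss.
    seed : drives the uniform(0, 1) default initialization; the single
        source of randomness of a run.
    mask : optional hard-masking patterns.
    init_W, init_H : optional explicit starts (override the random draw).
    """

    k: int
    algorithm: str = "scd"
    loss: LossKind | str = "mse"
    reg: RegularizationSpec = field(default_factory=RegularizationSpec)
    n_inner: Optional[int] = None
    max_epochs: int = 500
    rel_tol: float = 1e-6
    seed: int = 0
    mask: Optional[MaskSpec] = None
    init_W: Optional[np.ndarray] = None
    init_H: Optional[np.ndarray] = None
    verbose: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        self.algorithm = str(self.algorithm).lower()
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"algorithm must be one of {_ALGORITHMS}")
        self.loss = as_loss(self.loss)
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.n_inner is not None and self.n_inner < 1:
            raise ValueError("n_inner must be >= 1")
        if self.algorithm == "scd":
            self.reg.validate_for_scd()

    @property
    def inner_iterations(self) -> int:
        if self.n_inner is not None:
            return self.n_inner
        return 1 if self.loss.is_kl else 50

    def to_dict(self) -> dict:
        """Scalar fields only — enough to reproduce a run that used the
        default initialization and no mask."""
        return {
            "k": self.k,
            "algorithm": self.algorithm,
            "loss": self.loss.tag,
            "eps": self.loss.eps,
            "alpha": list(self.reg.alphas),
            "beta": list(self.reg.betas),
            "n_inner": self.inner_iterations,
            "max_epochs": self.max_epochs,
            "rel_tol": self.rel_tol,
            "seed": self.seed,
            "has_mask": self.mask is not None,
            "has_init": self.init_W is not None or self.init_H is not None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FactorizationConfig":
        a1, a2, a3 = d["alpha"]
        b1, b2, b3 = d["beta"]
        return cls(
            k=int(d["k"]), algorithm=d["algorithm"],
            loss=LossKind(d["loss"], d.get("eps", EPS_DEFAULT)),
            reg=RegularizationSpec(a1, a2, a3, b1, b2, b3),
            n_inner=int(d["n_inner"]), max_epochs=int(d["max_epochs"]),
            rel_tol=float(d["rel_tol"]), seed=int(d["seed"]),
        )


@dataclass
class FactorizationResult:
    """Factors plus the per-epoch bookkeeping of a run.

    ``loss_trace[i]`` is the mean observed-entry loss (reporting
    convention: plain MSE or mean KL) after ``i + 1`` epochs;
    ``objective_trace`` tracks the full penalized objective on the same
    grid.  Both are recorded once per outer alternation and assigned to
    the last epoch of that alternation (earlier epochs of the block carry
    the previous value), so the trace is a conservative step function of
    epoch count with length ``epochs_run``.
    """

    W: np.ndarray
    H: np.ndarray
    loss_trace: np.ndarray
    objective_trace: np.ndarray
    epochs_run: int
    converged: bool
    final_rel_change: float

    @property
    def final_loss(self) -> float:
        return float(self.loss_trace[-1])

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H


def initialize(config: FactorizationConfig, n: int, m: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """Draw the starting factors.

    Default: i.i.d. uniform(0, 1) entries for both W and H from the
    config seed (W drawn first).  User-supplied ``init_W`` / ``init_H``
    override the draw; mask-fixed entries are then stamped to their
    initial values, or to 0 where no initial matrix was given.  Pairing a
    zero-containing start with the multiplicative algorithm triggers a
    warning, since multiplicative updates can never move an entry off
    zero.
    """
    k = config.k
    if k > min(n, m):
        warnings.warn(f"k={k} exceeds min(n, m)={min(n, m)}; the "
                      "factorization is over-parameterized", stacklevel=2)
    rng = np.random.default_rng(config.seed)
    W = rng.uniform(size=(n, k))
    H = rng.uniform(size=(k, m))
    if config.init_W is not None:
        iw = np.asarray(config.init_W, dtype=float)
        if iw.shape != (n, k):
            raise ValueError(f"init_W shape {iw.shape} != {(n, k)}")
        if iw.size and iw.min() < 0:
            raise ValueError("init_W must be non-negative")
        W = iw.copy()
    if config.init_H is not None:
        ih = np.asarray(config.init_H, dtype=float)
        if ih.shape != (k, m):
            raise ValueError(f"init_H shape {ih.shape} != {(k, m)}")
        if ih.size and ih.min() < 0:
            raise ValueError("init_H must be non-negative")
        H = ih.copy()
    if config.mask is not None:
        config.mask.validate(n, k, m)
        if config.mask.fixed_W is not None and config.init_W is None:
            W[np.asarray(config.mask.fixed_W, dtype=bool)] = 0.0
        if config.mask.fixed_H is not None and config.init_H is None:
            H[np.asarray(config.mask.fixed_H, dtype=bool)] = 0.0
    if config.algorithm == "lee" and (np.any(W == 0) or np.any(H == 0)):
        warnings.warn(
            "multiplicative updates keep zero entries at zero forever; "
            "found zeros in the initialization", stacklevel=2)
    return W, H


def _solve_factor(A: TargetMatrix, W: np.ndarray, H: np.ndarray,
                  betas: tuple[float, float, float],
                  fixed: Optional[np.ndarray],
                  config: FactorizationConfig) -> tuple[np.ndarray, int]:
    """One n_inner-sweep solve of H given W; returns (H_new, sweeps_run)."""
    n_inner = config.inner_iterations
    eps = config.loss.eps
    if config.algorithm == "scd":
        if config.loss.is_kl:
            return kl.kl_solve(A, W, H, betas, n_inner=n_inner, eps=eps,
                               fixed=fixed)
        system = scd.build_system(A, W, betas)
        return scd.scd_solve(system, H, n_inner=n_inner, fixed=fixed, eps=eps)
    if config.loss.is_kl:
        Hn = multiplicative.lee_update_kl(A, W, H, betas, n_inner=n_inner,
                                          eps=eps, fixed=fixed)
    else:
        Hn = multiplicative.lee_update_mse(A, W, H, betas, n_inner=n_inner,
                                           eps=eps, fixed=fixed)
    return Hn, n_inner


def factorize(A: TargetMatrix, config: FactorizationConfig
              ) -> FactorizationResult:
    """Alternate H- and W-solves until the loss stabilizes.

    H is solved first, then W by transposing the problem (A^T ~ H^T W^T),
    both warm-started from the previous alternation.  Masked entries are
    never touched by the solvers.  Returns a :class:`FactorizationResult`
    with loss and penalized-objective traces on the epoch grid.
    """
    if not isinstance(A, TargetMatrix):
        A = TargetMatrix(A)
    n, m = A.shape
    W, H = initialize(config, n, m)
    fixed_W = fixed_H = None
    if config.mask is not None:
        if config.mask.fixed_W is not None:
            fixed_W = np.asarray(config.mask.fixed_W, dtype=bool)
        if config.mask.fixed_H is not None:
            fixed_H = np.asarray(config.mask.fixed_H, dtype=bool)
    At = A.transposed()
    betas = config.reg.betas
    alphas = config.reg.alphas
    loss_trace: list[float] = []
    obj_trace: list[float] = []
    prev_loss = reported_error(A, W, H, config.loss)
    epochs = 0
    converged = False
    rel = np.inf
    while epochs < config.max_epochs and not converged:
        H, s_h = _solve_factor(A, W, H, betas, fixed_H, config)
        Wt, s_w = _solve_factor(
            At, np.ascontiguousarray(H.T), np.ascontiguousarray(W.T),
            alphas, None if fixed_W is None else fixed_W.T, config)
        W = np.ascontiguousarray(Wt.T)
        block = max(s_h, s_w)
        epochs += block
        cur_loss = reported_error(A, W, H, config.loss)
        cur_obj = penalized_objective(A, W, H, config.loss, config.reg)
        # conservative step-function trace: the new value lands on the
        # last epoch of the block
        fill = loss_trace[-1] if loss_trace else prev_loss
        fill_obj = obj_trace[-1] if obj_trace else cur_obj
        loss_trace.extend([fill] * (block - 1))
        loss_trace.append(cur_loss)
        obj_trace.extend([fill_obj] * (block - 1))
        obj_trace.append(cur_obj)
        rel = abs(cur_loss - prev_loss) / max(prev_loss, 1e-300)
        if config.verbose:
            print(f"[nmfkit] epoch {epochs:6d}  loss {cur_loss:.6g}  "
                  f"rel.change {rel:.3g}")
        converged = rel < config.rel_tol
        prev_loss = cur_loss
    return FactorizationResult(
        W=W, H=H,
        loss_trace=np.asarray(loss_trace),
        objective_trace=np.asarray(obj_trace),
        epochs_run=epochs, converged=converged,
        final_rel_change=float(rel),
    )


def epochs_to_reach(result: FactorizationResult, target: float) -> Optional[int]:
    """Smallest epoch count at which the recorded loss is <= target
    (None if never reached)."""
    idx = np.flatnonzero(result.loss_trace <= target)
    return int(idx[0]) + 1 if idx.size else None


def normalize_columns(W: np.ndarray, H: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Optional post-hoc rescaling: scale W columns to unit sum and
    compensate in H, resolving the W/H scale indeterminacy.  Zero columns
    are left untouched.  Never applied automatically."""
    W = np.asarray(W, dtype=float).copy()
    H = np.asarray(H, dtype=float).copy()
    s = W.sum(axis=0)
    nz = s > 0
    W[:, nz] /= s[nz]
    H[nz, :] *= s[nz, None]
    return W, H
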