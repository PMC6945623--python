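"""Rank selection by holdout imputation.

The decomposition rank k is the one hyper-parameter of NMF.  The selection
protocol mirrors a training/validation split over matrix *entries*:

1. randomly delete a portion (default 30%) of the observed entries;
2. impute the deleted entries by NMF at each candidate rank;
3. compare imputations with the held-back values and pick the rank with
   the smallest error.

An under-sized rank cannot express the signal (high held-out error); an
over-sized rank fits noise in the surviving entries and generalizes worse
to the deleted ones, so the held-out error is U-shaped while the training
error only decreases with k.  Several independent deletions are averaged;
ties break toward the smaller rank for parsimony.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .driver import FactorizationConfig, factorize
from .losses import TargetMatrix, as_loss, LossKind
from .synthetic import mcar_deletion

__all__ = ["RankSearchResult", "select_rank"]

_SEED_CAP = 2**31 - 1


@dataclass
class RankSearchResult:
    """The full error surface of a rank search.

    ``holdout_errors[r, i]`` is the mean square (or mean KL) error between
    the imputed and held-back values of run r at rank ``k_grid[i]`` —
    computed on the deleted entries only.  ``train_errors`` is the same
    statistic on the entries that stayed observed.  ``k_selected``
    minimizes the run-averaged held-out error; ``per_run_selected`` holds
    each run's own argmin for a consistency check.
    """

    k_grid: tuple[int, ...]
    holdout_errors: np.ndarray
    train_errors: np.ndarray
    k_selected: int
    per_run_selected: tuple[int, ...]
    n_runs: int
    holdout_frac: float

    @property
    def mean_holdout_errors(self) -> np.ndarray:
        return self.holdout_errors.mean(axis=0)


def _entry_error(truth: np.ndarray, pred: np.ndarray, mask: np.ndarray,
                 loss: LossKind) -> float:
    a = truth[mask]
    y = pred[mask]
    if loss.is_kl:
        yg = y + loss.eps
        terms = np.where(a > 0, a * np.log(np.maximum(a, loss.eps) / yg), 0.0)
        return float(np.mean(terms - a + y))
    return float(np.mean((a - y) ** 2))


def select_rank(A: TargetMatrix, k_grid: Sequence[int],
                holdout_frac: float = 0.3, n_runs: int = 5,
                config: Optional[FactorizationConfig] = None,
                seed: int = 0, disjoint_folds: bool = False,
                max_retries: int = 50) -> RankSearchResult:
    """Choose the rank minimizing held-out imputation error.

    Parameters
    ----------
    A : target; deletion only ever touches its *observed* entries.
    k_grid : candidate ranks (sorted ascending internally so argmin ties
        resolve to the smallest rank).
    holdout_frac : fraction of observed entries deleted per run, in
        (0, 0.5].
    n_runs : independent deletion patterns to average over.
    config : template for the inner factorizations (its ``k`` and ``seed``
        are overridden); defaults to SCD/MSE with default settings.
    seed : master seed; drives the deletion patterns and the per-run,
        per-rank factorization seeds.
    disjoint_folds : partition the observed entries into ``n_runs``
        disjoint folds instead of independent draws (cross-validation
        style; ``holdout_frac`` is then ignored and each fold holds
        1/n_runs of the entries).
    """
    if not isinstance(A, TargetMatrix):
        A = TargetMatrix(A)
    if not disjoint_folds and not (0 < holdout_frac <= 0.5):
        raise ValueError("holdout_frac must be in (0, 0.5]")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    k_grid = tuple(sorted(int(k) for k in k_grid))
    if not k_grid or k_grid[0] < 1:
        raise ValueError("k_grid must contain positive integers")
    if config is None:
        config = FactorizationConfig(k=1)
    rng = np.random.default_rng(seed)
    loss = as_loss(config.loss)

    patterns: list[np.ndarray] = []
    if disjoint_folds:
        obs_idx = np.flatnonzero(A.observed)
        perm = rng.permutation(obs_idx.size)
        folds = np.array_split(perm, n_runs)
        for fold in folds:
            new = A.observed.copy()
            new.flat[obs_idx[fold]] = False
            if not (new.any(axis=1).all() and new.any(axis=0).all()):
                raise ValueError("a fold empties a row or column; "
                                 "use fewer folds or random deletion")
            patterns.append(new)
    else:
        for _ in range(n_runs):
            patterns.append(mcar_deletion(A.observed, holdout_frac, rng,
                                          max_retries=max_retries))

    holdout = np.empty((n_runs, len(k_grid)))
    train = np.empty((n_runs, len(k_grid)))
    for r, kept in enumerate(patterns):
        deleted = A.observed & ~kept
        A_train = A.with_observed(kept)
        for i, k in enumerate(k_grid):
            run_seed = int(rng.integers(_SEED_CAP))
            cfg = replace(config, k=k, seed=run_seed)
            res = factorize(A_train, cfg)
            recon = res.reconstruction()
            holdout[r, i] = _entry_error(A.values, recon, deleted, loss)
            train[r, i] = _entry_error(A.values, recon, kept, loss)

    mean_err = holdout.mean(axis=0)
    k_selected = k_grid[int(np.argmin(mean_err))]
    per_run = tuple(k_grid[int(np.argmin(row))] for row in holdout)
    return RankSearchResult(
        k_grid=k_grid, holdout_errors=holdout, train_errors=train,
        k_selected=k_selected, per_run_selected=per_run,
        n_runs=n_runs, holdout_frac=holdout_frac,
    )
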