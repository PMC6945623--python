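"""Seeded synthetic-data generators.

Three generators cover the package's test surfaces:

* :func:`gen_rank_sim` — the rank-selection simulation design: a 400x3
  uniform(0,1) basis times a 3x50 uniform(0,10) loading matrix plus
  standard-normal noise, negatives clipped to zero.
* :func:`gen_lowrank` — the same recipe at arbitrary size/rank/noise with
  optional completely-at-random entry deletion.
* :func:`gen_mixture` — known-profile mixtures for deconvolution, with
  per-sample tumour fractions recorded exactly.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .losses import TargetMatrix

__all__ = ["LowRankSample", "MixtureSample", "mcar_deletion",
           "gen_rank_sim", "gen_lowrank", "gen_mixture"]


@dataclass
class LowRankSample:
    """A generated target with its ground-truth factors."""
    A: TargetMatrix
    W: np.ndarray
    H: np.ndarray

    @property
    def truth(self) -> np.ndarray:
        return self.W @ self.H


@dataclass
class MixtureSample:
    """A tumour/normal mixture with its generative bookkeeping.

    ``A = W_cancer @ H_cancer + W0 @ H_normal`` exactly (before optional
    noise); ``purity[j]`` is the exact fraction of column j's total mass
    contributed by the cancer component.
    """
    A: TargetMatrix
    W0: np.ndarray
    purity: np.ndarray
    W_cancer: np.ndarray
    H_cancer: np.ndarray
    H_normal: np.ndarray


def mcar_deletion(observed: np.ndarray, frac: float,
                  rng: np.random.Generator,
                  max_retries: int = 50) -> np.ndarray:
    """Delete ``frac`` of the currently observed entries uniformly at
    random (missing completely at random), redrawing up to ``max_retries``
    times if a draw would empty some row or column.

    Returns the new observed pattern (a fresh boolean array).
    """
    if not (0 <= frac < 1):
        raise ValueError(f"deletion fraction must be in [0, 1), got {frac}")
    obs_idx = np.flatnonzero(observed)
    n_del = int(round(frac * obs_idx.size))
    if n_del == 0:
        return observed.copy()
    for _ in range(max_retries):
        sel = rng.choice(obs_idx.size, size=n_del, replace=False)
        new = observed.copy()
        new.flat[obs_idx[sel]] = False
        if new.any(axis=1).all() and new.any(axis=0).all():
            return new
    raise ValueError(
        f"could not delete {frac:.0%} of entries without emptying a row or "
        f"column after {max_retries} attempts; the matrix is too small or "
        "too sparse for this holdout fraction")


def gen_rank_sim(seed: int = 0) -> LowRankSample:
    """The rank-selection simulation: W 400x3 ~ U(0,1), H 3x50 ~ U(0,10),
    A = WH + standard-normal noise with negatives clipped to 0, fully
    observed."""
    return gen_lowrank(400, 50, 3, noise_sd=1.0, missing_frac=0.0, seed=seed)


def gen_lowrank(n: int, m: int, k: int, noise_sd: float = 1.0,
                missing_frac: float = 0.0, seed: int = 0) -> LowRankSample:
    """Noisy low-rank target with optional MCAR deletion.

    W entries are i.i.d. uniform(0, 1) and H entries uniform(0, 10), so a
    target entry has mean k*5/2 — comfortably above the default unit noise,
    which keeps the fraction of clipped (negative) entries tiny.  Noise is
    added *before* clipping at zero.
    """
    if not (0 <= missing_frac <= 0.5):
        raise ValueError("missing_frac must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.0, 1.0, size=(n, k))
    H = rng.uniform(0.0, 10.0, size=(k, m))
    A = W @ H
    if noise_sd > 0:
        A = A + noise_sd * rng.standard_normal(size=(n, m))
    np.maximum(A, 0.0, out=A)
    observed = np.ones((n, m), dtype=bool)
    if missing_frac > 0:
        observed = mcar_deletion(observed, missing_frac, rng)
    return LowRankSample(A=TargetMatrix(A, observed), W=W, H=H)


def gen_mixture(n: int, m: int, L: int = 2, k_unknown: int = 1,
                purity_range: tuple[float, float] = (0.3, 0.9),
                noise_sd: float = 0.0, seed: int = 0) -> MixtureSample:
    """Per-sample mixtures of unknown (cancer) and known (normal) profiles.

    Profiles (columns of W_cancer and W0) are uniform(0, 1) vectors
    normalized so each sample column has total mass ``n``; the cancer
    share of that mass is the drawn purity, so the recorded purity matches
    the generative mixing weight exactly.
    """
    lo, hi = purity_range
    if not (0 <= lo <= hi <= 1):
        raise ValueError("purity_range must satisfy 0 <= lo <= hi <= 1")
    rng = np.random.default_rng(seed)
    Wc = rng.uniform(size=(n, k_unknown))
    W0 = rng.uniform(size=(n, L))
    G = rng.uniform(0.1, 1.0, size=(k_unknown, m))   # raw cancer loadings
    F = rng.uniform(0.1, 1.0, size=(L, m))           # raw normal loadings
    purity = rng.uniform(lo, hi, size=m)
    total = float(n)
    cancer_mass = (Wc @ G).sum(axis=0)
    normal_mass = (W0 @ F).sum(axis=0)
    Hc = G * (purity * total / cancer_mass)
    Hn = F * ((1.0 - purity) * total / normal_mass)
    A = Wc @ Hc + W0 @ Hn
    if noise_sd > 0:
        A = A + noise_sd * rng.standard_normal(size=(n, m))
        np.maximum(A, 0.0, out=A)
    return MixtureSample(A=TargetMatrix(A), W0=W0, purity=purity,
                         W_cancer=Wc, H_cancer=Hc, H_normal=Hn)
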