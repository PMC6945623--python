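"""Shared fixtures and independent reference implementations used as
oracles: brute-force active-set NNLS, and the textbook multiplicative
update rules."""

import itertools

import numpy as np
import pytest

from nmfkit import TargetMatrix


def nnls_oracle(V: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Global minimizer of 1/2 h'Vh + u'h over h >= 0 by enumerating all
    active sets (V symmetric positive definite, small k only)."""
    k = len(u)
    best, best_obj = np.zeros(k), 0.0
    for r in range(1, k + 1):
        for S in itertools.combinations(range(k), r):
            S = list(S)
            h = np.zeros(k)
            try:
                h[S] = np.linalg.solve(V[np.ix_(S, S)], -u[S])
            except np.linalg.LinAlgError:
                continue
            if (h[S] < -1e-12).any():
                continue
            h = np.maximum(h, 0.0)
            obj = 0.5 * h @ V @ h + u @ h
            if obj < best_obj:
                best, best_obj = h, obj
    return best


def textbook_lee_mse(A: np.ndarray, W: np.ndarray, H: np.ndarray):
    """One unregularized multiplicative square-loss alternation (H then W)."""
    H = H * (W.T @ A) / (W.T @ W @ H)
    W = W * (A @ H.T) / (W @ H @ H.T)
    return W, H


def textbook_lee_kl(A: np.ndarray, W: np.ndarray, H: np.ndarray):
    """One unregularized multiplicative KL alternation (H then W)."""
    H = H * (W.T @ (A / (W @ H))) / W.sum(axis=0)[:, None]
    W = W * ((A / (W @ H)) @ H.T) / H.sum(axis=1)[None, :]
    return W, H


def random_spd_system(rng: np.random.Generator, k: int):
    """A random diagonally-regularized SPD quadratic system (V, u) with
    penalty weights satisfying the b1 > b2 positivity condition."""
    B = rng.uniform(-1.0, 1.0, size=(k + 2, k))
    b1 = rng.uniform(0.01, 1.0)
    b2 = rng.uniform(0.0, b1 * 0.99)
    V = B.T @ B + b1 * np.eye(k) + b2 * (np.ones((k, k)) - np.eye(k))
    u = rng.uniform(-2.0, 2.0, size=k)
    return V, u


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_target(rng):
    """A fully observed 12x8 strictly positive target."""
    return TargetMatrix(rng.uniform(0.5, 3.0, size=(12, 8)))


@pytest.fixture
def partial_target(rng):
    """A 12x8 target with ~25% of entries missing."""
    values = rng.uniform(0.5, 3.0, size=(12, 8))
    observed = rng.uniform(size=(12, 8)) > 0.25
    observed[:, 0] = True  # keep every row/column populated
    observed[0, :] = True
    return TargetMatrix(values, observed)
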