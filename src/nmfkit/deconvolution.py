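"""Mask-guided factorization: tumour-content deconvolution and designable
decompositions.

A measured tumour expression profile is a mixture of cancerous and healthy
signal.  Given known healthy profiles ``W0`` (n x L), the guided model

    A  ~  W H + W0 H1

solves for the unknown cancer profiles W and both loading blocks, realized
here as one ordinary factorization of A over the horizontally stacked
basis ``[W | W0]`` whose last L columns are hard-masked to W0 — no special
solver path exists.  The estimated tumour fraction of sample j is the
share of its reconstruction carried by the unknown block:

    r_j = sum_i (W H)_ij / sum_i (W H + W0 H1)_ij ,

a ratio of non-negative reconstructed masses, hence in [0, 1] and
insensitive to the overall W/H scale indeterminacy.

The same masking builds marker-gene or pathway-constrained designs (zeroed
entries of W outside each gene set) and multi-dataset layouts where
dataset-specific basis columns are forbidden from loading on the other
dataset's samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .driver import (FactorizationConfig, FactorizationResult, MaskSpec,
                     factorize)
from .losses import TargetMatrix

__all__ = [
    "DeconvolutionSpec", "DeconvolutionResult", "deconvolve",
    "build_marker_mask", "build_shared_profile_layout", "match_columns",
]


@dataclass
class DeconvolutionSpec:
    """Known profiles ``W0`` (rows aligned with the target's rows) and the
    number of unknown profile columns to learn alongside them."""

    W0: np.ndarray
    k_unknown: int = 1

    def __post_init__(self):
        self.W0 = np.asarray(self.W0, dtype=float)
        if self.W0.ndim != 2:
            raise ValueError("W0 must be 2-D (features x profiles)")
        if self.W0.size and self.W0.min() < 0:
            raise ValueError("W0 must be non-negative")
        if self.k_unknown < 1:
            raise ValueError("k_unknown must be >= 1")


@dataclass
class DeconvolutionResult:
    """Unknown profiles, both loading blocks, and per-sample purity.

    ``purity[j]`` is NaN when sample j's reconstruction is identically
    zero (the ratio is then undefined).
    """

    W: np.ndarray       # n x k_unknown, learned cancer profiles
    H: np.ndarray       # k_unknown x m, cancer loadings
    H1: np.ndarray      # L x m, loadings on the known profiles
    purity: np.ndarray  # m, estimated tumour fractions in [0, 1] (or NaN)
    result: FactorizationResult


def deconvolve(A: TargetMatrix, spec: DeconvolutionSpec,
               config: Optional[FactorizationConfig] = None
               ) -> DeconvolutionResult:
    """Known-profile deconvolution of A.

    ``config`` is a template (its ``k``, ``mask`` and ``init_W`` are
    owned by this routine); defaults to SCD/MSE.  The returned stacked
    factorization keeps the W0 block bit-identical to the input.
    """
    if not isinstance(A, TargetMatrix):
        A = TargetMatrix(A)
    if config is None:
        config = FactorizationConfig(k=1)
    if config.mask is not None and config.mask.fixed_W is not None:
        raise ValueError("deconvolve owns the W mask; pass extra "
                         "constraints through fixed_H only")
    n, m = A.shape
    if spec.W0.shape[0] != n:
        raise ValueError(f"W0 has {spec.W0.shape[0]} rows but the target "
                         f"has {n}")
    L = spec.W0.shape[1]
    ku = spec.k_unknown
    k_total = ku + L
    fixed_W = np.zeros((n, k_total), dtype=bool)
    fixed_W[:, ku:] = True
    mask = MaskSpec(fixed_W=fixed_W,
                    fixed_H=None if config.mask is None else config.mask.fixed_H)
    rng = np.random.default_rng(config.seed)
    init_W = rng.uniform(size=(n, k_total))
    init_W[:, ku:] = spec.W0
    cfg = replace(config, k=k_total, mask=mask, init_W=init_W)
    res = factorize(A, cfg)
    W = res.W[:, :ku]
    H = res.H[:ku]
    H1 = res.H[ku:]
    cancer_mass = (W @ H).sum(axis=0)
    total_mass = cancer_mass + (spec.W0 @ H1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        purity = np.where(total_mass > 0, cancer_mass / total_mass, np.nan)
    return DeconvolutionResult(W=W, H=H, H1=H1, purity=purity, result=res)


def build_marker_mask(gene_sets: Sequence[Sequence[int]], K: int, n: int,
                      mode: str = "pathway") -> MaskSpec:
    """Fix entries of W to zero according to gene sets S_1..S_L.

    mode="pathway": column l may load only on genes *in* S_l
    (``w[i, l] = 0`` for i not in S_l) — each column models one pathway or
    sub-network.  mode="marker": column l is zeroed on the markers of
    *other* sets (``w[i, l] = 0`` for i in the union of S_q, q != l``) —
    marker genes pin their own tissue's column.  Columns L..K-1 are left
    fully free for unknown components.
    """
    L = len(gene_sets)
    if K < L:
        raise ValueError(f"K={K} must be >= number of gene sets L={L}")
    if mode not in ("pathway", "marker"):
        raise ValueError("mode must be 'pathway' or 'marker'")
    sets = []
    for l, s in enumerate(gene_sets):
        idx = np.asarray(sorted(set(int(i) for i in s)), dtype=int)
        if idx.size == 0:
            raise ValueError(f"gene set {l} is empty")
        if idx.min() < 0 or idx.max() >= n:
            raise ValueError(f"gene set {l} has indices outside [0, {n})")
        sets.append(idx)
    fixed_W = np.zeros((n, K), dtype=bool)
    for l, idx in enumerate(sets):
        if mode == "pathway":
            col = np.ones(n, dtype=bool)
            col[idx] = False
        else:
            col = np.zeros(n, dtype=bool)
            for q, other in enumerate(sets):
                if q != l:
                    col[other] = True
        fixed_W[:, l] = col
    return MaskSpec(fixed_W=fixed_W)


def build_shared_profile_layout(samples_per_dataset: Sequence[int],
                                k_shared: int,
                                k_specific: Sequence[int]) -> MaskSpec:
    """H-mask for a multi-dataset factorization with shared profiles.

    The datasets' sample blocks are concatenated column-wise; the basis
    has ``k_shared`` leading columns free everywhere, followed by one
    block of ``k_specific[d]`` columns per dataset whose loadings are
    fixed to zero on every *other* dataset's samples.  A single dataset
    degenerates to an all-free (empty) mask.
    """
    samples = [int(s) for s in samples_per_dataset]
    spec = [int(s) for s in k_specific]
    if len(spec) != len(samples):
        raise ValueError("need one k_specific per dataset")
    if k_shared < 0 or any(s < 0 for s in spec) or any(s < 1 for s in samples):
        raise ValueError("block sizes must be positive")
    m = sum(samples)
    k_total = k_shared + sum(spec)
    fixed_H = np.zeros((k_total, m), dtype=bool)
    row = k_shared
    col_edges = np.concatenate([[0], np.cumsum(samples)])
    for d, kd in enumerate(spec):
        lo, hi = col_edges[d], col_edges[d + 1]
        fixed_H[row:row + kd, :lo] = True
        fixed_H[row:row + kd, hi:] = True
        row += kd
    return MaskSpec(fixed_H=fixed_H)


def match_columns(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Permutation ``p`` maximizing the total Pearson correlation between
    columns ``X[:, p[i]]`` and ``Y[:, i]`` (Hungarian assignment).  NMF is
    invariant to column permutation, so recovered and planted profiles
    must be aligned before comparing."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("X and Y must have the same shape")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    xn = np.linalg.norm(Xc, axis=0)
    yn = np.linalg.norm(Yc, axis=0)
    C = (Xc.T @ Yc) / np.maximum(np.outer(xn, yn), 1e-300)
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(X.shape[1], dtype=int)
    perm[cols] = rows
    return perm
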