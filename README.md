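# nmfkit

Regularized non-negative matrix factorization (NMF) for expression-style
data, built around a sequential coordinate-wise descent solver with native
support for missing entries.  On top of the core factorization the package
provides missing-value imputation, a holdout-imputation method for choosing
the decomposition rank, and mask-guided ("designable") factorizations for
tumour-content deconvolution and cross-dataset metagene discovery.

## Who this is for

Anyone decomposing a non-negative matrix — bulk or single-cell expression,
mutational signature counts, any features x samples table — who needs one or
more of: fast convergence per epoch, matrices with missing or untrusted
entries, a principled way to pick the rank `k`, or the ability to pin parts
of the factorization to known biology (reference profiles, marker genes,
pathway memberships).

## The model

NMF approximates a non-negative matrix `A` (n features x m samples) by a
rank-`k` product of non-negative factors, minimizing

```
min_{W>=0, H>=0}   sum_{(i,j) observed} L(a_ij, (WH)_ij)  +  J_W(W)  +  J_H(H)
```

where the per-entry loss `L` is either halved square error `(a-y)^2/2`
(Gaussian deviance, "MSE") or generalized Kullback–Leibler divergence
`a log(a/y) - a + y` (Poisson deviance, "MKL").  The penalties are weighted
combinations, applied to `W` and to `H^T`, of

* `J1(X) = ||X||_F^2 / 2` — ridge (magnitude control, numerical stability),
* `J2(X) = sum_{i<j} X_i . X_j` — angle penalty (column independence),
* `J3(X) = sum |x_ij|` — L1 (matrix-wise sparsity),

with `J1 + J2 = tr(X E X^T)/2`, the classic column-wise sparsity penalty.

Two solver families share this objective:

* **SCD** — alternating penalized non-negative least squares, each solve
  done by exact sequential coordinate-wise descent (a second-order method;
  under KL the coordinate step minimizes a local quadratic model);
* **LEE** — generalized multiplicative updates (a first-order method),
  extended to carry the same penalties.

Sums over entries run over the *observed* entries only, so matrices with
missing values factorize naturally: the per-column Gram matrices are
restricted to each column's observed rows.  The reconstruction `W @ H` then
predicts the missing entries (imputation), and deliberately deleting
entries and scoring their reconstruction across a grid of ranks selects `k`
(holdout rank selection).  Hard masks fix chosen entries of `W` or `H` at
their initial values throughout the run, which yields guided decompositions
such as `A ≈ W H + W0 H1` with known reference profiles `W0`, and the
per-sample tumour fraction

```
r_j = sum_i (W H)_ij / sum_i (W H + W0 H1)_ij .
```

## Worked example: choosing the rank

`examples/choose_rank.py` generates a 400x50 matrix as a rank-3 product of
uniform factors plus clipped standard-normal noise, then five times deletes
30% of the entries and imputes them by NMF at each candidate rank:

```
$ python examples/choose_rank.py
k    mean held-out MSE
1    2.1872
2    1.4630
3    1.0853   <- selected
4    1.1262
5    1.1856
6    1.2361
per-run argmin ranks : [3, 3, 3, 3, 3]
```

Reading the numbers: at `k = 1, 2` the model underfits — held-out error far
above the noise variance of 1.  At the planted rank 3 the error bottoms out
near the noise floor (1.09: noise variance plus a small imputation excess).
Past 3, extra components fit noise in the surviving entries and generalize
*worse* to the deleted ones, so the curve turns back up — the U-shape that
makes the argmin a rank estimate.  All five independent deletions agree.

The other examples are one capability each and print similarly annotated
numbers: `factorize_basic.py` (fit quality and denoising on noisy low-rank
data), `impute_missing.py` (NMF vs column-median imputation — 0.13 vs 13.6
MSE, about 100x better), `tumour_purity.py` (purity estimates within 0.003
of planted mixing fractions on noiseless mixtures), `shared_metagenes.py`
(a cross-dataset shared profile recovered at correlation 0.9999 under a
block mask).

## Command line

A thin CLI wraps the same functions:

```bash
nmfkit factorize A.tsv --k 15 --method scd --loss mse --inner 50 \
       --max-epochs 5000 --tol 1e-6 --seed 42
nmfkit impute A.tsv --k 2
nmfkit rank A.tsv --k-min 1 --k-max 6 --holdout 0.3 --runs 5
nmfkit deconvolve A.tsv --profiles W0.tsv --k-unknown 1
nmfkit simulate --preset rank-sim --seed 1
```

Files are 1-based and labeled (labels auto-detected and preserved); empty
cells and `NA`/`NaN` mark unobserved entries; in-memory indices are
0-based.

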