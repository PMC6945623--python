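# Methods

This note documents the models and procedures implemented in nmfkit, the
parameter defaults and why they were chosen, the numerical safeguards, and
what the synthetic benchmarks do and do not demonstrate.

## Objective and conventions

The factorization minimizes the observed-entry loss plus penalties

```
F(W, H) = sum_{(i,j) in Omega} L(a_ij, (WH)_ij) + J_W(W) + J_H(H)
```

over `W >= 0` (n x k) and `H >= 0` (k x m), with `Omega` the observed-entry
set.  `L` is `(a-y)^2/2` (MSE) or `a log(a/y) - a + y` (MKL, with
`0·log 0 := 0`).  `J_W = a1 J1(W) + a2 J2(W) + a3 J3(W)` and
`J_H = b1 J1(H^T) + b2 J2(H^T) + b3 J3(H^T)`, so the penalties act on the
columns of `W` and the rows of `H` symmetrically.

Two error conventions coexist and both are exposed:

* the **objective** convention (`loss_value`, `penalized_objective`) keeps
  the 1/2 factor of the quadratic loss — this is what the solvers are
  guaranteed not to increase;
* the **reporting** convention (`reported_error`, `loss_trace`,
  rank-selection errors) is the plain mean square error without the 1/2
  (identical to the objective convention under KL).

## Solvers

### Sequential coordinate-wise descent (SCD), square loss

Solving `H` given `W` is the quadratic program
`min_{H>=0} tr(H'VH)/2 + tr(H'U)` with
`V = W'W + b1 I + b2 (E - I)` and `U = -W'A + b3 E`.  Each coordinate has
the exact minimizer `h <- max(0, h - (VH + U)_kj / V_kk)`; the running
gradient is rank-1 patched after every accepted change, so a sweep costs
`O(k^2 m)`.  Columns are independent and the implementation updates one
coordinate across all columns simultaneously (vectorized).  `W` is solved
by transposing the problem (`A' ~ H'W'`), so one code path exists.
Alternations are warm-started from the previous iterate.

With missing entries, `V` and `U` are built from each column's observed
rows, making `V` column-dependent.  The per-column Gram matrices are
computed as one BLAS product of the `(k^2, n)` outer-product table with the
observation mask and held as an `(m, k, k)` array.  This batched layout
was chosen over a lazy per-column loop deliberately: it keeps the
coordinate updates vectorized across columns, and at the matrix sizes this
package targets (up to tens of thousands of entries per factor) the
`k^2 m` memory is negligible.  Very wide matrices with large `k` would
need a chunked variant.

The penalty condition `b1 > b2` or `b2 = 0` (and the same for the alphas)
keeps the diagonal of `V` positive and is enforced at configuration time.
A *negative* diagonal raises an error.  An *exactly zero* diagonal is
floored at `eps`: it arises routinely when a factor column collapses to
all zeros mid-run (over-specified `k`), where the coordinate update's
well-defined limit is "move to zero unless the linear term is zero" —
aborting there would make over-parameterized fits impossible.

Inner sweeps stop early once the largest coordinate change in a sweep
falls below `1e-9` times the largest entry of the iterate: the solve is
then at a fixed point to working precision, and counting further no-op
sweeps as epochs would misstate the work done.

### KL loss by sequential quadratic approximation

The KL loss is not quadratic per coordinate, so each coordinate step
minimizes the second-order Taylor model.  With `b` and `a` the first and
second derivatives of the observed-entry KL of the column with respect to
`h_kj` (sums over observed rows only), the clamped step is

```
h <- max(0, (a·h - b - b2·cross - b3) / (a + b1))
```

where `cross` is the column sum of the other coordinates.  The
reconstruction `WH` is patched incrementally after each accepted change,
so later coordinates in the same sweep see the current iterate.  Because
the quadratic model is local, per-sweep descent of the true objective is a
property checked empirically (tests allow a `1e-10` slack), not a theorem;
no violation has been observed on random instances.  A recompute-once-
per-sweep variant would be faster but weakens this behaviour, and was not
implemented.

### Generalized multiplicative updates

The classic multiplicative rules extended with the same penalties:
under MSE, `h <- h · (W'A) / ([W'W + b1 I + b2(E-I)]H + b3 E)`; under KL
the analogous ratio with `sum_l w_lk` in the denominator.  With all
weights zero these reduce exactly to the original rules (verified against
an independent textbook implementation to 1e-12 over five alternations).
Missing entries restrict the cross products per column exactly as in SCD.
Multiplicative updates preserve sign — a zero entry stays zero forever —
so the driver warns when a zero-containing initialization meets this
algorithm.  The MSE rule may loop `n_inner` times per alternation,
reusing the cross products; the KL rule must recompute `WH` each pass, so
its inner loop buys nothing and defaults to one.

## Driver, epochs and convergence

One *epoch* is a complete scan over all entries of `W` and `H`; an outer
alternation with `n_inner` sweeps per factor consumes `n_inner` epochs
(taken as the max of the two factors' actual sweep counts when early
stopping trims them).  `max_epochs` caps the total and may be overshot by
at most one alternation's worth.

Defaults: `n_inner = 50` under MSE (amortizes the `O(nmk)` cross products,
which dominate the `O(k^2 m)` sweeps when `k << n, m`) and `1` under KL;
`max_epochs = 500`; `rel_tol = 1e-6`.  Convergence is declared when the
relative change of mean observed loss between consecutive alternations,
`|loss - prev| / max(prev, tiny)`, drops below `rel_tol` — the reported
"relative tolerance" of a finished run is exactly this quantity.

The loss trace is recorded once per alternation and laid out on the epoch
grid conservatively: the new value lands on the *last* epoch of its
alternation block, earlier epochs keep the previous value.  `epochs_to_
reach` therefore never credits a run with progress before the alternation
that achieved it.

Initialization draws `W` then `H` i.i.d. uniform(0, 1) from a single
seeded generator owned by the config — the only randomness in a run.
Alternation order is `H` first, then `W` (fixed for reproducibility).  No
column normalization is applied by default: the `W`/`H` scale
indeterminacy is left to the caller, with `normalize_columns` available
(unit column sums in `W`, compensated in `H`).  Purity estimates are scale
ratios and do not depend on it.

Masking: entries flagged fixed hold their initial value (or 0 when no
initial matrix is given).  The coordinate solvers *skip* fixed
coordinates — the free ones feel them through the gradient — and the
multiplicative updates copy them back, so fixed entries are bit-identical
in the output, not merely close.

## Missing entries, imputation, rank selection

All computations read a zero-filled copy of the data (unobserved
positions hard-zeroed at construction), which makes "unobserved values
cannot influence results" a structural guarantee; a metamorphic test
scrambles the unobserved values and requires bit-identical outputs.
Rows or columns with *no* observed entry are rejected at load time:
reconstruction there would rest on no data.

Imputation completes the matrix with `W @ H` at missing positions
(observed entries pass through bit-exact; imputed values are non-negative
by construction).  It assumes entries are missing completely at random —
missingness correlated with the values biases the reconstruction, and the
same caveat applies to rank selection.

Rank selection deletes a fraction (default 30%) of the observed entries
uniformly without replacement (redrawing, boundedly, if a draw would
empty a row or column), imputes at each candidate rank, and scores only
the deleted entries.  The selected rank minimizes the run-averaged error;
ties break to the smaller rank for parsimony, and each run's own argmin
is reported alongside for a consistency check.  A disjoint-folds
(cross-validation) mode is available.  Default loss is MSE; inner
factorization seeds derive deterministically from the master seed.

## Deconvolution and designable factorization

`A ≈ W H + W0 H1` is realized as a single factorization over the stacked
basis `[W | W0]` with the `W0` block mask-fixed — no special solver path.
The tumour fraction `r_j` is the unknown block's share of sample j's
reconstructed mass, hence in [0, 1] whenever the denominator is positive
(reported as NaN otherwise).  The same regularization weights apply to
both loading blocks; nothing in the model forces a distinction.  On exact
mixtures the split is identifiable only up to loadings that keep both
blocks non-negative; in practice random-start coordinate descent recovers
planted fractions to well under 0.05 absolute error (tested), but heavily
collinear `W0` and cancer profiles would widen that.

Mask builders cover the standard designs: pathway-constrained `W` columns
(zero outside each gene set), marker-gene designs (each column zeroed on
the *other* sets' markers), and multi-dataset layouts where
dataset-specific basis columns are forbidden from loading on other
datasets' samples.  Recovered-vs-planted comparisons in the tests align
columns by maximal-correlation Hungarian assignment, since the
factorization is invariant to column permutation.

## Synthetic data

The generators are pure functions of their seed.  `gen_rank_sim` is the
reference rank-selection design: `W` 400x3 uniform(0,1), `H` 3x50
uniform(0,10), unit-normal noise added *before* clipping negatives to
zero (a mean entry of ~7.5 against unit noise keeps clipping below 5% of
entries).  `gen_lowrank` generalizes it to arbitrary size/rank/noise with
MCAR deletion; `gen_mixture` builds purity-controlled tumour/normal
mixtures whose recorded fractions match the generative weights exactly.

What these fixtures do not emulate: heavy-tailed expression distributions,
correlated (structured) missingness, batch effects, or dependence between
mixing fraction and profile shape.  Passing tests demonstrate correctness
of the optimization and of the procedures' logic under their stated
assumptions (low-rank signal, MCAR), not performance on any real platform.

## Benchmark problem sizes

The packaged checks run at desk scale, chosen to finish in seconds while
leaving the tested orderings unambiguous: rank selection on the 400x50
design with 5 runs over ranks 1..6; convergence-speed and imputation
comparisons on 200x100 rank-5 matrices over 10 seeds; deconvolution on
150x40 noiseless mixtures.  The convergence-speed check asks the
coordinate solver to reach, within 250 epochs, the loss the
one-inner-iteration multiplicative solver attains at epoch 500 (median
over seeds) — a scaled form of the second-order-vs-first-order ordering,
measured with the conservative trace accounting above.

## Numerical choices

* `eps = 1e-16` guards every denominator that can vanish: reconstruction
  entries under KL, `a + b1` in the quadratic step, multiplicative
  denominators, zero diagonals of `V`.
* The "did the coordinate change" test for gradient patching is exact
  inequality on the clamped values — cheap, and keeps the incremental
  gradient consistent with recomputation to float accuracy.
* Monotonicity assertions use a relative slack of `1e-12` (the objective
  is a sum over ~1e4 entries, where absolute 1e-12 is below the rounding
  of the sum itself).
* Factor outputs are exactly non-negative (clamping at 0, no negative
  zeros).

## Known limitations

* `J2`'s `E - I` term is only positive semidefinite jointly with the data
  Gram; the `b1 > b2` condition is required, not merely advised.
* KL per-sweep descent is empirical (local quadratic model), as noted.
* The batched per-column Gram trades memory for speed and would need
  chunking for very large `m · k^2`.
* Alternating NMF converges to a stationary point, not a global optimum;
  tail convergence on exactly factorizable data is slow (hundreds to
  thousands of epochs to drive the loss toward machine precision), which
  is inherent to alternating schemes rather than to this implementation.
* No uncertainty quantification for imputed values or purity estimates.
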