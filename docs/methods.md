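# Methods

## Observation model

Each count is a two-part mixture: with probability `phi_ij` the entry is
a structural zero; otherwise it is a generalized Poisson (GP) draw with
mean `T_i * lam_ij` and dispersion `alpha`.  The GP is used in its mean
parameterization,

    p(y; mu, alpha) = (1/y!) (mu/(1+alpha*mu))^y (1+alpha*y)^(y-1)
                      exp(-mu(1+alpha*y)/(1+alpha*mu)),

with variance `mu (1+alpha*mu)^2`.  Only `alpha >= 0` (over-dispersion)
is supported; negative values truncate the support and are rejected, and
`alpha` is boxed to `[0, 5]`, far beyond anything sequencing data
require.  `T_i` is the relative library size — row sum divided by the
median row sum (even n: midpoint of the two central order statistics) —
treated as a known offset, not a parameter.

Two latent structures connect the entries.  First, `log(Lambda) = F L^T`
with rank K: `F` (n×K) holds per-sample scores, `L` (m×K) per-taxon
loadings.  Second, the zero link `logit(phi) = -tau * log(lam)` with one
global shape `tau`: the smaller the rate, the likelier the dropout.
Global `tau` and `alpha` are shared by all entries.

## Estimation

Direct maximization over (F, L, tau, alpha) is impractical, but the
model is a GLM in each row and in each column separately.  The
alternating algorithm therefore cycles:

1. **Column step.**  With F fixed, each column j of Y is a ZIGP
   regression of y_j on design F with offset log T and coefficient row
   l_(j).  All m columns share (tau, alpha).
2. **Row step.**  Symmetrically, each row i regresses on the new L with
   scalar offset log T_i, giving f_(i).
3. **Re-identification.**  (F, L) are replaced by the SVD factors of
   F L^T (computed via thin QR, so the product is preserved to float
   round-off).  This fixes the rotational ambiguity; the likelihood is
   unchanged.

The outer loop stops when the relative change of the total
log-likelihood falls below `tol` (default 1e-4; default cap 30
iterations — in practice well-behaved fits stop after a handful).

Each step is itself fitted by EM over the latent indicator "this zero is
structural".  The E-step posterior has the closed form
`z = sigmoid(-tau*eta + mu/(1+alpha*mu))` at observed zeros (zero
elsewhere), with `eta = log lam`.  Because `phi` depends on `eta` and
`tau`, the M-step does not split into a logistic part and a count part;
the expected complete-data log-likelihood is maximized jointly by
L-BFGS-B with analytic gradients.  Three structural facts keep this
fast:

- all regressions in a step share one design matrix, so the coefficient
  blocks separate and one joint L-BFGS call (on the K×m or K×n stacked
  coefficients) updates them all at once;
- `(tau, alpha)` are updated by a bounded 2-D ascent on the
  observed-data likelihood, with the score obtained from Fisher's
  identity (posterior-weighted complete-data score);
- per step only a few EM cycles are run (default 3): the outer
  alternation supplies the remaining iterations, and every cycle is an
  ascent step, so monotonicity of the total likelihood is preserved
  (each M-step is additionally guarded: a line-search failure keeps the
  previous iterate).

Numerical choices: all pmf evaluations are in log space with `gammaln`
for the factorial; `(1+alpha*y)^(y-1)` is computed as
`(y-1)*log1p(alpha*y)`, exactly 0 at y = 0; linear predictors are
clamped to ±30 before exponentiation, which keeps all-zero response
blocks (whose rate is unidentifiable downward) finite; the zero-link
terms use `log_expit` throughout.  Initialization is the SVD of
`log((Y+1)/T)` — the pseudo-count handles zeros and the division
matches the offset — with F absorbing the singular values.  Optional
Gaussian jitter on the initialization exists but is off by default, so
fits are deterministic.  Coefficient warm starts come from least squares
of `log(y+1) - offset`.

`library_size` selects the offset: `"estimate"` (default, the right
choice on real data) computes T from the observed row sums; `"ones"` or
an explicit vector fixes T.  Benchmarks on simulated data fix T to the
generating values, because the estimand `log Lambda` is only defined
relative to a normalization: with estimated T, the rank-K factorization
would have to absorb the rank-one `log T` row effect and the comparison
with the simulated truth would mostly measure that mismatch rather than
recovery.

## Rank selection

Entry-wise N-fold cross-validation (default N = 10, candidate ranks
1–6): the n·m cells are partitioned uniformly at random into N folds
(sizes within one of each other; a fold is re-drawn if its removal would
empty a row or column of training cells).  For each fold the model is
fitted with the held-out cells masked out of every regression and of the
likelihood, and the ZIGP log-likelihood of the held-out cells is
evaluated at the fitted parameters.  The rank with the largest summed
held-out likelihood wins; ties go to the smaller rank.  Per-fold fits
warm-start from the full-data fit of the same rank and run a reduced
number of outer iterations (default 8), which cuts the cost of the
search by an order of magnitude without changing selections in practice.

## Synthetic data generator

The generator produces the benchmark design the package is validated
on: block-structured true factors (F 200×3, L 100×3; break points scale
proportionally for other sizes) with N(0, 0.06²) jitter on F and
N(0, 0.05²) on L, `Lambda = exp(F L^T)`, T = 1, alpha = 0.2, and counts
from one of six scenarios — the model itself (1), two misspecified zero
links (2: log–log, 3: complementary log–log), fixed per-taxon zero
probabilities (4), zero-inflated Poisson (5) and zero-inflated negative
binomial (6).

The published description of this block design assigns column 3 of both
factor matrices twice, inconsistently.  The default here resolves the
conflict so that the third column of F mirrors the loading pattern (1.7
on the first block, 0.9 everywhere else).  This is not cosmetic: under
the alternative reading, about half the matrix has `log lam ≈ 0`, where
the logit link pins `phi` at 1/2 regardless of `tau`, and no `tau` can
produce fewer than ~42% zeros — the light-inflation setting would be
unreachable.  The literal assignments remain available
(`blocks="literal"`) for comparison.

A scenario's zero level is a target *total* zero fraction.  The link
shape `tau` (scenario 4: the center of the per-taxon Uniform(c−0.1,
c+0.1)) is calibrated per dataset by scanning for a sign change of the
expected-zero-fraction curve and refining with Brent's method; an
unattainable target raises `CalibrationError` rather than silently
generating off-target data.  `zero_mode="phi"` instead targets the mean
structural-zero probability.  The scenario-6 NB size defaults to
matching the NB variance to the GP variance at the geometric grand mean
of the rates (the arithmetic mean is dominated by the largest block and
implies an NB so over-dispersed that light inflation is unreachable);
it can be overridden.

GP sampling uses the exact Lagrangian-Poisson representation: with
`theta = mu/(1+alpha*mu)` and `delta = alpha*mu/(1+alpha*mu) < 1`, a GP
variate is the total progeny of a subcritical branching process with
Poisson(theta) ancestors and Poisson(delta) offspring.  This is exact to
the pmf, fully vectorized over the matrix, and seed-reproducible — a
whole 200×100 dataset generates in well under a second.

What the generator does *not* emulate: taxonomic correlation beyond the
rank-3 structure, compositionality, phylogenetic signal, or variable
sequencing depth (T = 1 by default).  Tests passing on these data show
that the estimation machinery recovers the generating structure under
the stated conditions; they do not certify behavior on real tables with
those extra features.

## Benchmarks and evaluation

`run_benchmark_cell` measures a method's mean ± SD Frobenius loss
`||log Lambda_hat − log Lambda||_F` over replicate simulations (seeds
`base_seed + r`, so results are independent of the worker count), at the
generating rank 3.  Methods: the ZIGP factor fit and log-PCA (zeros →
pseudo value 0.5, log, column-centered rank-K PCA with means restored;
pseudo value and centering are flags).  The acceptance script runs 10
replicates per cell and one 10-fold CV rank search — problem sizes
chosen so the whole study reruns in a few minutes on one CPU.

## Known limitations

- Under strong over-dispersion the log-rate is weakly identified at
  high rates: the GP Fisher information per entry for `eta` is
  `mu/(1+alpha*mu)^2 ≈ 1/(alpha^2 mu)`, which vanishes as rates grow.
  With `alpha = 0.2` and rates in the hundreds, even the exact MLE
  recovers those entries with large and heavy-tailed error, and pushing
  the optimizer harder can *increase* the Frobenius loss while still
  increasing the likelihood.  The default stopping rule (relative
  likelihood change < 1e-4) is therefore also a mild regularizer; the
  loss numbers the benchmark reports should be read with this in mind.
- `alpha` may sit on the boundary 0 (e.g. on Poisson data); its
  asymptotic distribution is then non-standard.  No standard errors for
  F or L are provided.
- Entry-wise CV refits the model N × |ranks| times; warm starts make it
  tractable but it remains the most expensive operation in the package.
- The EM objective is non-concave; different initializations can reach
  different local maxima.  The SVD warm start has been reliable on the
  benchmark designs, but pathological matrices may need several
  `init_jitter` restarts.
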