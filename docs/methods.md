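# Methods

## The generalized elastic net

`gelnetx` fits linear models under the regularizer

    R(w) = lambda1 * sum_j d_j |w_j|  +  (lambda2 / 2) * w' P w

where `d >= 0` carries per-feature L1 weights and `P` is a positive
semi-definite feature-pair penalty. With `d = 1` and `P = I` this is the
classical elastic net; the point of the generalization is to let `P`
encode domain knowledge about feature relationships — typically a gene
interaction network — so that the L2 term penalizes *dissimilar* feature
pairs and steers selection toward mechanistically connected genes.

The regression objective is the weighted squared error

    (1/2n) * sum_i a_i (y_i - w'x_i - b)^2 + R(w),

with nonnegative per-sample weights `a_i` (all 1 by default). Because `P`
is PSD and `d` nonnegative the problem is convex.

### Penalty constructions

* **Graph Laplacian** `L = Diag(deg) - A`. Its quadratic form is
  `w'Lw = 1/2 * sum_ij A_ij (w_i - w_j)^2`, an edge-wise smoothness
  penalty. The **normalized Laplacian** divides each off-diagonal entry by
  `sqrt(d_i d_j)` and has unit diagonal; isolated nodes get diagonal 1 so
  that an edgeless node set always sees an identity submatrix.
* **Diffusion penalty** `P = I - expm(-t L)`. The matrix exponential is
  the heat/diffusion kernel; its eigenvalues lie in (0, 1], so `P` is PSD.
  The diffusion time `t` (default 0.1, dimensionless) controls how far
  similarity spreads beyond immediate neighbours; it is exposed as a
  parameter because no canonical value exists. The exponential is
  evaluated through the eigendecomposition of the symmetric `L`.
* **Ridge/Laplacian blend** `P = I + beta*L` (`beta >= 0`), strictly
  positive definite; the network-induced classification-kernel
  regularizer.
* **Kernel pseudo-inverse**: any PSD similarity kernel can be turned into
  a dissimilarity penalty by Moore-Penrose pseudo-inversion (the Laplacian
  itself is the pseudo-inverse of the graph's reproducing kernel;
  `(L^+)^+ = L`).

Symmetry is enforced at construction (tolerance 1e-10 relative);
`validate()` checks the smallest eigenvalue against `-1e-8 * ||P||` and
raises on violation — eigenvalues are never clipped silently.

## Optimization

Cyclic coordinate descent with closed-form updates: for coordinate `k`,

    w_k <- S( (1/n) sum_i a_i x_ik (y_i - y_i^(k)) - lambda2 * sum_{j != k} P_kj w_j ,
              lambda1 * d_k )
           / ( (1/n) sum_i a_i x_ik^2 + lambda2 * P_kk )

where `y^(k)` is the partial fit excluding feature `k` and `S` is the
soft-threshold operator, followed by the bias update
`b <- sum_i a_i (y_i - w'x_i) / sum_i a_i`. Residuals are maintained
incrementally; coordinates currently at zero whose soft-threshold argument
stays inside `lambda1 * d_k` skip the residual update entirely. The
skip changes no floating-point values — a `skip_zero=False` switch runs
the same kernel without the shortcut and tests assert exact (`==`)
equality of the resulting weights.

* **Initialization**: `w = 0`, `b` = weighted mean of `y`; warm starts
  accepted (and used heavily by the path/cross-validation code).
* **Sweep order**: fixed ascending feature index; no randomization, so
  fits are bit-reproducible.
* **Convergence**: a fit is declared converged when the per-sweep
  objective change falls below `tol` (default 1e-5, absolute; a relative
  mode is available) *and* the subgradient optimality residual is below
  `10 * tol`. The objective-change criterion alone can stop a coordinate
  method while gradients are still O(sqrt(tol)); folding the KKT check
  into the stopping rule makes "converged" mean what the diagnostics
  claim. `max_iter` (default 100 sweeps) caps the loop with
  `converged=False`.
* **Degenerate coordinates**: an all-zero column with `lambda2 * P_kk = 0`
  has no curvature; such weights are frozen at 0 with a logged warning
  rather than raising, since constant columns are common in filtered
  genomic matrices.
* `lambda1_max` (the smallest L1 level at which the zero vector is a
  fixed point) uses the absolute inner product
  `max_j |(1/n) sum_i a_i x_ij (y_i - b)| / d_j`; without the absolute
  value the bound fails for negatively correlated features.

The inner loops are JIT-compiled (numba) and the penalty is consumed in
CSR form, so a sparse Laplacian costs O(degree) per coordinate; dense
penalties are converted and give identical results.

## Reductions

**Logistic regression** (binary 0/1 response) is solved by iteratively
reweighted least squares: at each outer step the working response
`z_i = eta_i + (y_i - p_i)/v_i` and weights `v_i = p_i(1 - p_i)` define a
weighted regression subproblem handed to the penalized solver with a warm
start. `v_i` is clipped below at `prob_clip` (default 1e-5) to keep the
coordinate denominators positive. The outer loop tracks the penalized
average negative log-likelihood and stops on changes below `outer_tol`
(default 1e-5, at most 25 outer steps); three consecutive increases flag
the fit as not converged.

**Penalized principal components** maximize `v'(X'X/n)v` under the same
regularizer via the linearize–solve–normalize scheme for penalized ratios
of quadratic forms: iterate `g = (X'X/n) v`, solve the convex surrogate
`min_w -g'w + lambda1 sum d|w| + (lambda2/2) w'Pw` by coordinate descent,
and renormalize to unit length, stopping when the loading vector moves by
less than `tol` in the max norm. Columns are centered defensively. Two
structural notes: the surrogate requires `lambda2 * P_kk > 0` on active
coordinates, and because the surrogate solution scales exactly as
`1/lambda2`, the *normalized* component depends on `lambda2` only through
the shape of `P` — sparsity is controlled by `lambda1` relative to the
scale of `g`. The loading sign is fixed so the largest-magnitude entry is
positive. Subsequent components are obtained by data-space deflation
`X <- X - (Xv)v'`; no orthogonality constraint is imposed beyond that.

## Synthetic benchmark

The simulation study asks when a supplied network actually helps
prediction. One dataset is generated as follows (defaults in
parentheses):

1. **Graph**: Barabasi-Albert preferential attachment over `p` features
   (p = 5000, 2 edges per new node) — connected and heavy-tailed, a
   standard stand-in for gene-network topology.
2. **Pathway**: a simple random walk from a uniform start collects
   distinct nodes until a fixed fraction (10%) is reached; `w_true` is 1
   on this connected set, 0 elsewhere.
3. **Expression**: `X ~ N(0, S)` with n = 50 samples. In the *GGM*
   scenarios the precision matrix is the ridge-shifted graph Laplacian
   `S^-1 = Diag(deg) - A + delta*I` (delta = 0.1), so the
   conditional-independence graph of the data equals the feature network
   exactly and neighbours are positively partially correlated. In the
   *Rand* scenarios `S = GG'/p + 1e-3 I` (Wishart-style) is independent
   of the network. The Laplacian precision was chosen over a shifted
   adjacency (`A + (|lambda_min|+delta)I`) because the latter requires a
   diagonal shift so large that features become essentially independent
   and no method can predict the response at all; the Laplacian variant
   preserves the same off-diagonal support while producing network-driven
   co-expression.
4. **Response**: `y = X w_true`, noiseless by default (a `noise_sd` knob
   exists because noiseless p >> n regression can be degenerate for other
   solvers).
5. **Network handed to the learner**: the true graph ("+" scenarios) or a
   scrambled one ("-"): `ceil(f * p)` node indices are permuted
   symmetrically in rows and columns, preserving the degree multiset
   while destroying individual relationships; f = 1 for the "-"
   scenarios, intermediate f for the scramble-factor sweep.

What this generator does *not* emulate: count noise and
mean-variance relationships of sequencing assays, multi-omic structure,
hub-specific expression variance, or partially overlapping pathway
annotations. Passing benchmarks here show that the method exploits
network-aligned covariance structure when it exists — not that any
particular curated network is correct for a given dataset.

## Evaluation protocol

Three metrics, all "lower is better":

* **Reconstruction error** `1 - (w'w_hat)^2 / (||w||^2 ||w_hat||^2)`
  (one minus squared cosine; scale-invariant; the zero estimate scores 1
  by convention so degenerate models are not rewarded).
* **RMSE** via leave-pair-out cross-validation: pairs of samples are held
  out, the model is refit on the rest, and errors are pooled. All
  C(n, 2) pairs are used when that count is within the pair budget,
  otherwise pairs are sampled uniformly without replacement
  (seed-controlled). The library default budget is 200 pairs; the
  benchmark battery uses 100 to keep the full grid affordable.
* **Dispersion** `sum_{i,j in Z} Lnorm_ij / |Z|` over the selected
  (nonzero-weight) features `Z`, computed on the network given to the
  learner: exactly 1 when `Z` has no internal edges, lower the more `Z`
  clusters; an empty `Z` is an error.

Rather than tuning penalties, metrics are *marginalized* over the grid
`lambda2 in {10000, 1000, 100, 10, 1}` by
`lambda1 in {1/27, 1/9, 1/3} * lambda1_max` (15 cells). The elastic net
uses this grid directly; the network-penalized model's `lambda1` is
chosen per cell so its nonzero count matches the elastic net's
("matched sparsity"): the elastic net's own `lambda1` is used when it
already matches, otherwise a 30-step bisection on
`(0, lambda1_max]` picks the closest achievable count, preferring exact
matches and breaking ties toward the larger `lambda1`. Both arms share
the LPOCV pair sample and per-cell warm starts.

The decision rule for "the network is relevant to this task" flags
marginal improvements of at least 2.5% in RMSE or 5% in dispersion
(`conservative=True` requires both).

### Problem sizes used by the shipped battery

The test suite and the reproduction script run the study at p = 500,
n = 50 with 10 independent runs per condition and 100 LPOCV pairs — a
tenfold feature-space reduction of the reference design that preserves
all qualitative behaviour (dispersion control, scramble robustness,
reconstruction ordering between true- and scrambled-network conditions).
The scramble sweep reuses one dataset per run across fractions, pairing
the comparisons so the fraction effect is not confounded with simulation
noise.

## Numerical conventions and edge cases

* All randomness flows through `numpy.random.SeedSequence` spawns of a
  single seed; every simulated battery is bit-reproducible.
* PSD validation tolerance: smallest eigenvalue >= -1e-8 * spectral norm.
* `t = 0` diffusion gives the zero penalty; `beta = 0` gives ridge.
* Scrambling with `fraction = 0` is the identity; `fraction = 1` permutes
  all nodes (an isomorphic graph with relabelled nodes).
* Matched-sparsity targets can be unreachable when the sparsity path
  jumps; the closest achievable count is used and logged.
* Dispersion of an all-zero model is undefined; comparison tables record
  it as missing rather than inventing a value.

## Known limitations

* The solver is dense in the sample dimension; it targets the
  p >> n regime (thousands of features, tens-to-hundreds of samples),
  not n in the millions.
* Only binary logistic and single-component PCA reductions are shipped;
  multi-class models, survival losses and hinge-loss training are out of
  scope (the NICK penalty construction is provided, the SVM itself is
  not).
* The PCA components are deflated, not jointly orthogonalized.
* Directed, signed or typed interaction networks are not modelled; edge
  weights must be nonnegative.
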