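# Methods note

## Model

Drug sensitivity is modeled linearly in log-transformed spectral counts.
For one drug with responses y (−log10 GI50 over n cell lines) and predictor
matrix X (cell lines × proteins, values log10(count + 1)):

    minimize over (b0, b):
        (1/2n) Σ_i (y_i − b0 − x_i'b)²  +  λ ( α‖b‖₁ + (1−α)/2 ‖b‖₂² )

with α ∈ [0, 1] the L1/L2 mixing weight (α = 1 is the lasso) and λ ≥ 0 the
penalty amplitude. Predictors are standardized internally (population sd,
ddof = 0) and the response centered; the reported coefficients are
back-transformed to the original predictor scale and the intercept is
unpenalized. Zero-variance predictors are frozen at coefficient zero.

### Solver

Cyclic coordinate descent with residual updates and an active-set strategy:
after each full sweep, sweeps are restricted to the current nonzero set until
convergence, then one full sweep verifies stationarity. The per-coordinate
update is the standard soft-thresholding step

    b_j ← S(⟨x_j, r⟩/n + g_jj b_j, λα) / (g_jj + λ(1−α)),   S(z, γ) = sign(z)·max(|z|−γ, 0)

with g_jj = ‖x_j‖²/n (= 1 after standardization). Convergence is declared
when the largest coefficient change in a sweep (standardized scale) falls
below `tol` (default 1e-7). Regularization paths are computed warm-started
along a geometric grid of 100 λ values from λ_max = max_j |⟨x_j, y_c⟩|/(nα)
down to λ_max/100. The kernels are numba-compiled; the optional
`check_objective` mode verifies monotone descent of the penalized objective
every sweep. Correctness is pinned by closed-form solutions on orthonormal
designs, OLS at λ = 0, the exact zero solution at λ ≥ λ_max, KKT residual
checks, and agreement with scikit-learn's solver to < 1e-6 on matched
objectives (scikit-learn is used only as an oracle, never at runtime).

### Model selection

- **λ**: K-fold CV (default 10 folds, balanced random assignment). The grid
  is built on the full data; each fold refits the path on its training part
  and scores held-out MSE on the common grid. λ_min is the grid value with
  minimal fold-averaged MSE; ties resolve to the largest λ (sparser model).
- **α**: grid 0.1, 0.2, …, 1.0. Because the CV minimum is noisy at n ≈ 20,
  the minimum mean MSE is recorded for each of `n_repeats` (default 10)
  independent CV runs — fold assignments shared across α within a repeat —
  and the α with the lowest repeat-averaged minimum wins; ties resolve to
  the smaller α.
- **Stability selection**: the α = 1 CV + refit procedure is repeated
  `n_runs` times (study setting: 1000) under re-randomized folds; each
  protein's selection frequency is tabulated and `core_predictors(t)`
  returns those with frequency ≥ t.
- **Best subsets**: the exact minimum-RSS subset of size k is found over a
  candidate pool via the centered Gram matrix (RSS(S) = y'y − c_S' G_SS⁻¹ c_S),
  either by exhaustive enumeration (≤ 1e5 combinations) or by
  depth-first branch-and-bound whose lower bound is the RSS of the OLS fit
  on "chosen ∪ all remaining candidates". Ties resolve to the
  lexicographically smallest id tuple, making results order-invariant. The
  winner is refit by OLS; R² = 1 − RSS/TSS on the training data.

### Cross-validation of the whole procedure

Leave-pair-out: all C(n,2) pairs are held out once, organized by the circle
method into n−1 rounds of n/2 disjoint pairs (odd n: n rounds with one bye
each). Every training split re-runs the full α/λ selection; each round
yields a complete predicted vector and one Pearson correlation with the
observed sensitivities; the mean over rounds is the headline number. A
pooled mode (single correlation over all two-point predictions) is also
provided.

## Normalization

Counts from the second instrument are mapped to the reference scale as
follows: a least-squares line through 99 matched empirical quantiles
(probabilities k/100) of the pooled shared-cell-line counts checks the
affine relation between instruments; cell lines measured only on the second
instrument are rescaled by the ratio of Euclidean norms of the household-
protein counts (the k = 7 proteins with the lowest coefficient of variation,
sd/mean with ddof = 1) computed over the shared cell lines, then appended.
Proteins whose total count across cell lines is below 100 are dropped
(boundary kept), then values become log10(count + 1) and the matrix is
transposed to cell lines × features.

## Synthetic-data generator (scope)

The generator reproduces the statistical structure needed to test the
pipeline, not the biology: household proteins draw one log-normal mean
(log-mean log 200, sd 0.3) shared across cell lines with Poisson sampling
(CV ≈ 0.07); other proteins draw one log-normal mean per protein (median 8
counts, log-sd 1.2) with negative-binomial sampling (dispersion r = 2);
instruments apply an affine distortion (scale·x + offset, clipped at 0,
rounded). Responses are y = 6.0 + X_std β + N(0, σ²) with exactly k nonzero
coefficients of equal magnitude and random signs at uniform positions.
With `target_r2` set, the magnitude is calibrated on the realized design so
Var(X_std β)/(Var(X_std β) + σ²) equals the requested signal fraction — with
a fixed magnitude the realized fraction drifts by ~±0.08 across replicate
designs because of sampled predictor correlations.

## Numerical choices

- Standardization uses ddof = 0 throughout the solver (matches the λ_max
  convention); the household CV uses ddof = 1 (sample CV).
- All randomness flows through `derive_seed(*parts)` (SeedSequence over
  integer parts and CRC-32 of string parts), so every stage, fold
  assignment, and repeat is independently reproducible from one root seed.
- TSV artifacts are written with `%.10g` floats; manifests record SHA-256
  checksums, and pipeline reruns are byte-identical.
- Exact ties (λ grid MSE, subset RSS within 1e-12, cluster-merge distances
  within 1e-12) have deterministic documented resolutions: largest λ,
  lexicographic id tuple, lexicographic label pair.

## Limitations

- **Small-sample lasso instability.** At n ≈ 22 and p ≈ 130 with a signal
  fraction of 0.85 split over three predictors, each true predictor's
  marginal correlation (~√(0.85/3) ≈ 0.53) sits at the noise floor of the
  maximum null correlation. The CV-min lasso therefore fails to select all
  three truths in ~90% of runs in roughly a third of replicate datasets; an
  independently implemented reference lasso (R glmnet, cv.glmnet at
  lambda.min) shows the same rate on identical data. The stability-selection
  machinery reports this honestly rather than hiding it; the corresponding
  acceptance test is expected red at its 80% bar.
- **Negative leave-pair-out null.** When the inner CV correctly selects the
  all-zero model (e.g., on permuted responses), each held-out prediction is
  its training mean (S − y_i − y_j)/(n−2). Within a round the total S is
  constant, so predictions are an affine function of −(y_i + y_j) and the
  per-round correlation converges to −1/√2 ≈ −0.707 regardless of n. The
  permutation-null mean of the LPOCV correlation is therefore ≈ −0.4 (a
  mixture of null-model rounds and noise fits), not 0; negative CV
  correlations for uninformative predictors are expected output, not error.
- The same sign-cancellation effect makes even noiseless recovery
  seed-sensitive: across generator seeds the noiseless leave-pair-out mean
  correlation ranges from ~0.5 (adversarial sign/correlation configurations)
  to 1.0 (typical ones).
- The generator does not model shared abundance programs across proteins
  (counts are independent across proteins given their means), batch/run
  order effects, or missing-at-acquisition patterns.
- Best-subset search is exact but exponential in the worst case; it is
  intended for the small stability pools the workflow produces (tens of
  candidates), not for p in the hundreds.
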