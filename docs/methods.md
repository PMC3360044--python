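# Methods

## The measurement problem

One-colour miRNA arrays report, per probe, a signal intensity, a background
intensity, and a quality flag.  Most miRNAs are weakly expressed, so the
per-miRNA summaries on both the treated and the control side are
contaminated by measurement error that does not vanish with expression
level.  The package models a probe's net (background-subtracted) intensity
with a two-component error model,

    y = mu * exp(eta) + eps,    eta ~ N(0, sigma_eta^2),  eps ~ N(0, sigma_eps^2),

whose SD is proportional to `mu` at high abundance (the multiplicative
component) and bounded below by `sigma_eps` near zero (the additive
component).  After log transformation and per-miRNA averaging over
technical replicates, the control summary is `W_i = x_i + U_i` with
`x_i = ln mu_i` and heteroscedastic normal error `U_i ~ N(0, sigma_{U,i}^2)`,
where `sigma_{U,i}` is estimated by the per-miRNA standard error; the
treated summary is `Y_i`.  Detecting differential expression becomes an
errors-in-variables regression problem: estimate `g(x) = E[Y | X = x]` from
the contaminated pairs `(W_i, Y_i)` and ask which observations deviate from
it.  Under the null of no differential expression (and common
normalization) `g` is the identity, so the procedure needs no prior
normalization of the treated-versus-control pair: a common shift is simply
absorbed into the curve.

## Local-linear deconvolution estimator

The fit is a local-linear regression whose kernels correct for the noise in
`W`.  With base kernel `K` whose characteristic function
`phi_K(t) = (1 - t^2)^3` is supported on [-1, 1], the order-k deconvolution
kernel is

    K_{U,k}(z) = i^{-k} (1/2 pi) \int e^{-itz} phi_K^{(k)}(t) / phi_bar_U(t/h) dt,

with the pooled error CF `phi_bar_U(s) = (1/n) sum_j exp(-sigma_{U,j}^2 s^2/2)`
(arithmetic mean of the individual normal CFs — the standard
heteroscedastic-deconvolution convention).  In the error-free limit
`K_{U,k}(z) = z^k K(z)`, so the estimator

    g_hat(x) = (S2 T0 - S1 T1) / (S0 S2 - S1^2)

collapses to ordinary local-linear regression, reproduces constants for
any error level, and reproduces lines exactly when `sigma_u = 0` (both are
enforced by tests against brute-force weighted-least-squares oracles).
The fit is linear in Y, `g_hat(x) = sum_j l_j(x) Y_j`; the equivalent
weights and their norms `||l(x)||` drive the confidence bands.

Numerics.  Kernel integrals use fixed Gauss-Legendre quadrature (257 nodes
on the half range), which is exact to near machine precision for these
smooth compactly supported integrands; `1/phi_bar_U` is capped at 1e8 with
a warning when the bandwidth is too small for the error level.  All kernel
sums are evaluated through the substitution `u = t/h_j`, which makes the
oscillatory factor separable in the evaluation point and the data and turns
each weight matrix into two dense matrix products; with a common quadrature
grid this is algebraically identical to pairwise kernel evaluation, and it
is what makes cross-validation and the 200-replicate coverage study run in
seconds.  With per-observation bandwidths the order-k kernel terms are
rescaled by `h_j^k` so that every observation enters one weighted
least-squares system in the original units of W (the factors cancel for a
constant bandwidth).  Near-degenerate local-linear denominators receive a
relative 1e-10 ridge; if still degenerate the point falls back to the
local-constant estimate with a warning.  The evaluation grid is 256 equally
spaced points spanning [min W, max W].

## Adaptive bandwidth and cross-validation

Log-intensity designs are skewed, so a single bandwidth over-smooths the
dense region or under-smooths the tails.  Following the classical
variable-bandwidth recipe: a pilot deconvolution density estimate
`f~(W_i)` (same kernel machinery, bandwidth `h0`, floored at a small
positive constant) gives local factors

    lambda_i = (f~(W_i) / g)^(-alpha),   g = geometric mean of f~(W_i),

with geometric mean one, and per-observation bandwidths `h_i = h0 lambda_i`
(the bandwidth travels with the observation, not the evaluation point).
The pair `(h0, alpha)` minimizes the exact leave-one-out cross-validation
score `sum_i (Y_i - g_hat_{-i}(W_i))^2`, computed by removing each
observation from the kernel sums rather than refitting (algebraically
identical, O(n^2) total).  Default grids: 10 log-spaced `h0` values within
a factor 3 of the normal-reference rule for W, and
`alpha in {0, 0.25, 0.5, 0.75, 1}`.  Ties prefer the larger (smoother)
`h0`.  The CV surface is typically shallow, so the selected `h0` can sit
low; the band machinery below is calibrated to tolerate that.

## Variance function

Two estimators of the residual variance `sigma^2(x)`:

- `variance_simple` (default): smooth `Z_i = ln (Y_i - g_hat(W_i))^2` on
  `W` by local-linear regression and exponentiate.  Because
  `E[ln chi^2_1] = psi(1/2) + ln 2 ~ -1.2704`, the raw exponential
  underestimates `sigma^2` by the factor 0.28; the default applies the
  log-moment correction (`bias_correct=True`) so the band widths are on
  the right scale.  The log-squared residuals carry chi-square(1) noise
  with variance `pi^2/2`, so the variance smoother uses its own, heavier
  bandwidth — twice the normal-reference rule by default — rather than the
  regression bandwidth; an under-smoothed variance estimate translates
  directly into locally under-covering bands.
- `variance_deconv` (opt-in): `theta(x) = E[Y^2|X=x]` fitted by the same
  deconvolution machinery, `sigma^2 = theta - g_hat^2`, stabilized by a
  bagging correction (average of positive parts over 50 bootstrap refits,
  floored).  Preferable when measurement error is large enough to bias the
  residual-based estimate; noisier otherwise.

## Simultaneous confidence bands and detection

The band for the curve is `g_hat(x) ± c sigma_hat(x) ||l(x)||`, with `c`
solving the volume-of-tubes equation

    (kappa0 / pi) exp(-c^2/2) + 2 (1 - Phi(c)) = alpha,

where `kappa0 = \int ||d/dx ( l(x)/||l(x)|| )|| dx` is computed by centred
finite differences and trapezoid integration on the fit grid (refining the
grid changes it by well under 1%), and the root is found by bisection on
[0, 10] to 1e-6.  At `kappa0 = 0` this reduces to the pointwise normal
quantile (1.95996 at the 95% level).

Detection distinguishes two regions.  The curve band above answers "where
could the true regression curve be"; its simultaneous coverage is the
package's headline validation (below).  An individual observation,
however, scatters around the curve with SD `sigma(x)` *in addition to* the
curve-estimate uncertainty `sigma(x) ||l(x)||`; comparing single points
against the curve band alone would flag most perfectly null miRNAs,
because `||l(x)|| << 1` for any smooth fit.  The exclusion region for
observation-level calls therefore has half width

    c * sigma_hat(x) * sqrt(1 + ||l(x)||^2),

which under the null leaves only a handful of points outside at the 95%
level.  A point exactly on the boundary counts as inside.  A call is
UP/DOWN only if the observation additionally clears the basal reference
level, `mean(ln background) + 2 SD(ln background)` of the control array —
the screen against noise-driven calls among weakly expressed miRNAs.
Everything else is ND.

## Quality control and summarization

Probe SNR is net intensity over background (> 1 means signal exceeds
noise); array-level QC reports the flagged fraction and the mean and
maximum SNR.  The weak-signal rule flags probes with
`signal < background + 2 SD(background)` (array-level background SD; the
per-probe background of a one-colour export has no replicate SD), never
unsetting an existing flag.  Outlier-flagged probes are always excluded
from summaries; POOR/NEGATIVE/EMPTY probes are excluded unless
`keep_weak=True`.  Probes with non-positive net intensity cannot enter a
log summary and are dropped.  Natural logs are used throughout the model
layer; fold-change reporting converts through ln 2.  When a miRNA retains
a single probe, its measurement-error SD is borrowed from the 50 miRNAs
nearest in mean log intensity (degrees-of-freedom-weighted pooling,
rank-symmetric, truncated at the boundaries).

With replicate arrays per condition, W and Y are across-array means of the
per-array per-miRNA mean logs, and `sigma_u` is the standard error across
control arrays; the treated-side error is absorbed into the regression
residual.

## Normalization

- Normalizer-probe ML normalization (replicate arrays): unflagged
  normalizer probes (snoRNA/U6 controls) give one mean log value per
  (normalizer, array) cell; the two-way additive model
  `v_ja = beta_j + delta_a` is fitted by maximum likelihood (alternating
  means, sum-zero offsets), and each normalizer's residual variance is
  tested one-vs-rest against an F distribution, dropping the worst
  offender per iteration (max 10) until none is significant or three
  normalizers remain.  Arrays are then divided by `exp(delta_a)`.  The
  exact dispersion test of the original iterative algorithm is not
  published; the F-ratio rule is a documented stand-in.
- Benchmarks: global median scaling (each array scaled to the median of
  per-array medians — the "global median" convention adopted here),
  quantile normalization (mean order statistics, average ranks for ties,
  idempotent), and MA-plot LOESS via statsmodels lowess (tricube local
  linear, span 0.75, 3 robustness iterations), splitting the log-ratio
  correction symmetrically between the two arrays.  LOESS-M removes the
  intensity-dependent trend and then re-centres the corrected log-ratios
  so their median equals the original median M exactly (subtracting
  `fit - median(M)` would restore it only approximately).

## Concordance

Three-way calls (DOWN/ND/UP) from two platforms are tallied into a 3x3
table and scored with Cohen's weighted kappa under the Fleiss-Cohen
quadratic weights `w_ij = 1 - (i-j)^2/4` (1 on the diagonal, 0.75 for
adjacent categories, 0 for opposite trends), interpreted on the
Landis-Koch bands with exact boundary values assigned to the lower band.
Fold-change (cutoff 2 by default) and t-test callers (two-sided, equal
variances, paired variant available; fold-change fallback below two
replicates) are provided for benchmarking.  miRNAs missing on either
platform are excluded from the table rather than counted as ND.

## Synthetic data

The generator emits probe tables in the same dialect the reader consumes,
with flags assigned by the same rules an image-processing pipeline applies
(outliers, negative nets, the weak-signal rule), per-array multiplicative
offsets `exp(delta_a)`, twelve stable highly expressed normalizer species,
and a truth table of true classes.  Default conditions: 560 miRNAs, 4
technical replicate probes, `sigma_eta = 0.15`, `sigma_eps = 20` (a.u.),
background 100 ± 35 (a.u., floored at half the mean — a local-median
background statistic never approaches zero), 75% of miRNAs log-uniform on
[0.02, 1]x background and the rest on [1, 20]x background.  These values
were calibrated once so that simulated arrays reproduce the QC regime such
profiles typically report — roughly two thirds of probes flagged, mean SNR
well under 10, maximum SNR of order 100 — and are exposed in the config.
One master seed drives deterministic per-array substreams, so identical
seeds give byte-identical outputs.

What the generator does not emulate: spatial artifacts, print-tip or dye
effects, correlated probe noise within a miRNA, biological between-sample
variability beyond the per-array offsets, and cross-hybridization.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated error model, not robustness to every artifact
of real arrays.

## Validation studies (experiments module)

- Simultaneous coverage: 200 null datasets (500 miRNAs, concentrations
  10-100x background so the identity is the exact regression curve, four
  technical replicates supplying `sigma_{U,i}`), bandwidth cross-validated
  on the first dataset and fixed, local factors recomputed per dataset.
  The fraction of datasets whose true curve stays inside the 95% band at
  every grid point is the package's headline number (93-95% across seeds);
  `scripts/acceptance.py` recomputes it from scratch.
- Deconvolution gain: X ~ N(0,1), g(x) = 2 sin x, predictor noise at half
  the predictor SD, n = 500; the deconvolution fit beats the naive
  local-linear fit that ignores the errors in median RMISE over 20
  replicates (about 0.22 vs 0.32 on the central 90% of the design).
- t-test caller type-I error ≈ 0.05 within binomial error over 1000 null
  replicates; an over-dispersed normalizer (10x residual SD) is discarded
  in ≥ 90% of replicates.

Problem sizes were chosen so the full validation suite completes in a few
minutes on a single CPU.

## Known limitations

- The tube formula accounts for the variance of the curve estimate, not
  for smoothing or deconvolution ratio bias; coverage can dip when
  cross-validation selects a very small bandwidth.  The heavier default
  variance-smoother bandwidth compensates for most of this in practice.
- The leave-one-out CV surface is shallow in `h0`; selections should be
  treated as order-of-magnitude choices, and the emitted run log records
  the selected values for scrutiny.
- `sigma_{U,i}` from 4 technical replicates is itself noisy (3 degrees of
  freedom); only its pooled effect enters the deconvolution CF, which is
  why the method remains stable despite noisy per-miRNA SEs.
- The observation-level exclusion region treats the n discrete test points
  through the continuum tube constant; this is slightly liberal relative
  to a Bonferroni bound over the observed points.
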