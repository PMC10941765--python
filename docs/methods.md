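# Methods

## The outbreak index

The NDOI condenses a monthly notifiable-disease register into one number
per month and stratum. Within a stratum (all diseases, or one transmission
route), the month's case total `n_i` and its count of disease types present
`t_i` (diseases with ≥ 1 case) are min–max normalized over the analysis
window and combined as `NDOI_i = α·N_i + β·T_i` with `α + β = 1`. Two
modelling assumptions are implicit and worth stating:

* **Sum-then-normalize.** Counts (and type counts) are first summed across
  the stratum's diseases, then normalized once, then weighted. This is the
  only reading under which the index is guaranteed to lie in [0, 1] with
  convex weights; normalizing per disease and summing would scale with the
  number of diseases.
* **Window-relative scale.** "Outbreak intensity" is relative to the
  min/max observed in the configured window (default: the full table),
  computed separately per stratum. An `EntropyWeightNDOI` estimator fitted
  on one window scores new months on that window's scale, which is the
  behaviour an early-warning deployment needs; values can then exceed [0, 1]
  if a later month breaks the historical record, by design.
* **Degenerate range.** If an indicator is constant over the window
  (max = min) it carries no outbreak signal; the normalized component is set
  to 0 and a `DegenerateSeriesWarning` is emitted so the choice is auditable.

### Entropy weights

Weights are data-derived by the standard entropy-weight recipe applied to
the min–max-normalized indicator columns `x` (m months × 2 indicators):
shares `p_ij = x_ij / Σ_i x_ij`, entropy `e_j = −(1/ln m) Σ_i p_ij ln p_ij`
with `0·ln 0 := 0`, divergence `d_j = 1 − e_j`, weights `w_j = d_j / Σ d_j`.
Exchangeable indicators receive (0.5, 0.5) exactly; an indicator that is
constant after normalization has undefined entropy and raises `WeightError`
rather than silently producing a weight. The recipe is applied to
normalized rather than raw columns because the raw case and type counts
live on incomparable scales; this is surfaced as a config choice
(`weights="auto"` vs a fixed pair) since published calibrations (e.g.
α = 0.51, β = 0.49 for Shanghai 2017–2020, available as
`SHANGHAI_WEIGHTS`) may rest on a different input matrix.

## Change summaries

The pandemic-impact summary is the signed rate of change
`100·(post − mean(pre))/mean(pre)` per disease, per route aggregate
(cases and NDOI) and overall. Computation always uses unrounded annual
totals; one-decimal rounding happens only at report rendering — this is what
lets the packaged annual summary reproduce every printed disease-level rate
within 0.1 pp (printed rounding). A zero pre-period mean with a positive
post value has no defined rate and is reported NA (a disease first appearing
in the post year). As a transparent forecasting baseline the package ships a
seasonal-naive forecaster (each month repeats its value 12 months earlier)
with MAD/MAPE/RMSE error metrics; model-based forecasting is out of scope.

## Screening statistics

Normality screening uses the one-sample Kolmogorov–Smirnov test against a
normal with the sample's own mean and SD. This moment-matched flavour is
the convention of mainstream desktop statistics software and is documented
as slightly anti-conservative compared to Lilliefors-corrected p-values; it
is a screen for choosing a transform, not an inferential endpoint. Series
failing the screen at α = 0.05 are log10(x+1)-transformed — base 10 for
readability of count magnitudes, +1 to admit the zeros that surveillance
counts contain. Period contrasts use classical one-way ANOVA (between/within
F with (k−1, N−k) df; infinite F with p = 0 when within-group variance is
exactly zero and means differ). Disease–factor association matrices use
pairwise Pearson r with two-sided p; no multiple-testing correction is
applied by default (matching common practice in this literature), with a
Benjamini–Hochberg option behind a flag.

## Constrained ordination

RDA is implemented directly: standardize the environment matrix, center and
standardize the species (disease) matrix, regress species on environment by
least squares, and take the PCA of the fitted values; residual axes are the
PCA of the residuals. The constrained fraction is
`trace(fitted covariance)/trace(total covariance)`; constrained plus
residual eigenvalues reconstruct the total variance to 1e−8. The
implementation reproduces R vegan's `rda()` eigenvalues on a toy matrix to
nine decimals (frozen in the test suite) and collapses to plain PCA when the
environment spans the site space.

Numerical choices:

* **Correlation-scale species.** Disease counts span four orders of
  magnitude; without standardization the most common disease would own the
  ordination. Constant species columns (possible after aggressive
  filtering) are left at zero with a warning rather than erroring.
* **Collinear covariates** are dropped greedily left-to-right on the
  centered matrix (a later column dependent on earlier ones is removed,
  with a warning) — covariate panels routinely contain near-duplicates such
  as an air-quality index alongside its constituent pollutants. Requesting
  more covariates than sites − 1 is a hard error.
* **Axis signs** are fixed by making the largest-magnitude species loading
  on each axis positive, so outputs are byte-reproducible.
* **Rare-disease filter:** diseases present in strictly fewer than 5% of
  months (default) are removed before ordination, the customary
  rare-species screen.

Significance uses a Monte Carlo permutation test: environment rows are
permuted jointly, the statistic is the constrained fraction (monotone in
the pseudo-F at fixed dimensions, hence an equivalent test with a simpler
contract), and `p = (1 + #{permuted ≥ observed})/(1 + permutations)` —
bounded below by 1/(permutations+1), e.g. 0.002 at the conventional 499
permutations. Months enter as independent exchangeable sites; no
time-series-restricted permutation schemes are offered, so serial
correlation in real monthly data will make these p-values somewhat liberal.
Detrended correspondence analysis is deliberately not implemented: the
linear method is appropriate for short compositional gradients (the source
data's first DCA axis had gradient length 0.5) and the choice is hard-coded.

## Synthetic surveillance data

The generator emulates the features of a metropolitan register that the
analysis actually consumes: counts are negative-binomial
(`Var = μ + μ²/k`, Poisson in the k → ∞ limit) because surveillance counts
are overdispersed; means follow a sinusoidal seasonal profile; a step
intervention multiplies each route's mean by a factor in (0, 1] from a given
month onward; covariates are level + sinusoid + intervention step + Gaussian
noise; planted covariate–disease effects act multiplicatively on the
log-mean with covariates standardized inside the generator, so coefficients
are effect sizes per covariate SD. Variation in the "types present"
indicator arises naturally from low-baseline diseases dropping in and out of
the register, not from a separate mechanism.

The default configuration mirrors the Shanghai study design: 9/10/9/4
diseases across the four routes, 48 months starting January 2017,
intervention at month 37 (January 2020), route multipliers (0.35, 0.47,
0.90, 0.36) near the published per-route case declines, log-spaced baselines
within each route (a few diseases dominate, the rarest report ~0 most
months), seasonal amplitude 0.4, overdispersion k = 5, and a 14-factor
covariate panel (meteorology with opposing temperature/pressure phases,
pollutants with winter peaks and pandemic step-downs, mobility indicators
with large step-downs, freight/consumption with step-ups).

What the generator does **not** emulate: mechanistic transmission dynamics
(no SIR structure, no dependence between months beyond seasonality),
spatial structure, reporting artifacts (delays, backfills, case-definition
changes), or surveillance-capacity suppression during the pandemic. Tests
passing on synthetic data therefore demonstrate that the pipeline recovers
the structure it assumes — multiplicative interventions and log-linear
covariate effects — not that real registers satisfy those assumptions.

## Problem sizes and determinism

The test suite and the acceptance script run everything at the study's own
scale (48 months, 32 diseases, 14 covariates) except where a property needs
replication: law-of-large-numbers checks use 1200 simulated months,
planted-driver recovery sweeps 20 seeds, and permutation-p uniformity under
the null uses 200 replicates of a 12-site problem at 99 permutations (the
null distribution of the p-value does not depend on the permutation count,
so the smaller count is a pure speed choice). All randomness flows through
explicit integer seeds (`numpy.random.default_rng`); identical config and
seed give byte-identical pipeline outputs, which the manifest's checksums
make checkable.

## Known limitations

* The entropy-weight calibration depends on the exact indicator matrix; the
  published (0.51, 0.49) pair is reproducible only with the original
  supplementary monthly data, so the package treats it as a fixed
  replication mode rather than a derivable constant.
* Published per-route annual NDOI values are treated as means of monthly
  route NDOIs; with printed three-decimal inputs one route aggregate's
  recomputed rate differs from print by 0.1 pp.
* The moment-matched KS screen is anti-conservative; with 48-month series
  this mainly means some near-normal series get log-transformed.
* The permutation test assumes exchangeable months (see above).
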