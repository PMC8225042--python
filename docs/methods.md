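# Methods

## Sample entropy and its conventions

For a series U = {u₁, …, u_N}, the length-m embedding vectors are
vᵢ(m) = [uᵢ, …, u_{i+m−1}].  SampEn(U; m, r) = −log(A/B), where B is
the number of ordered pairs (i, j), i ≠ j, whose m-vectors are within
Chebyshev distance r, and A the same count for (m+1)-vectors.
Conventions fixed in this package, chosen so integer counts are
bit-reproducible:

* Both orders are counted over start positions i, j ∈ {1, …, N−m}
  (the last m-template, which has no (m+1)-extension, is dropped).
  An (m+1)-match therefore always implies an m-match and
  `a_count ≤ b_count` holds combinatorially.
* A distance exactly equal to r counts as a match (θ(0) = 1).
  Measure-zero for continuous data, but it pins down exact counts on
  discrete fixtures.
* Counts are stored raw (ordered pairs, no normalizers): the
  (N−m)(N−m−1) factors cancel in the ratio, and raw counts allow
  pooling across realizations (see "Estimator behavior" below).
* Zero counts yield a flagged NaN result, not an exception: at large
  scales a short coarse-grained series can legitimately contain no
  matches, and a multi-scale curve must carry such gaps.
* The tolerance is absolute inside the entropy kernels; all "r × SD"
  policy lives in the multiscale driver, so the bias logic exists in
  exactly one place.

ApEn is provided for contrast: Φ^m(r) − Φ^{m+1}(r) with self-matches
included and templates over all N−m+1 positions.  Note that for short
periodic series the self-match artifact can make ApEn slightly
*negative* (e.g. −0.0164 for [1,2,3,1,2,3,1,2,3], m = 1, r = 0.5)
while SampEn is exactly 0 there.

The compiled kernel (numba) is validated against a deliberately
literal pure-Python double-loop oracle that shares no code with it;
agreement is exact at the integer-count level.

## Coarse-graining and the threshold bias

Coarse-graining at scale τ replaces non-overlapping blocks of τ
consecutive samples by their block mean (remainder samples discarded;
length ⌊N/τ⌋).  "Moving average" in the MSE literature refers to this
block operation, not a sliding window.

For iid input with SD σ, the block mean has SD σ/√τ.  The classic MSE
algorithm evaluates every scale with r = r_factor × SD(original), so
the *effective* tolerance in units of the per-scale SD grows as √τ and
entropy is dragged down by construction.  For unit Gaussian noise the
pairwise difference of two independent N(0, 1/τ) variables has SD
√(2/τ), and because iid input makes the conditional match probability
independent of m, the biased entropy has the closed form

    SampEn(τ, r) = −log erf(r√τ / 2),

with predicted bias(τ) = SampEn(1, r) − SampEn(τ, r), zero at τ = 1
and increasing.  The closed form is the erf reduction of the joint
Gaussian probability integral; the package keeps an adaptive 2-D
quadrature of that integral, written with no erf shortcut, as an
independent oracle, and the two agree to better than 10⁻⁶ over the
test grid (τ ∈ {1, 2, 4, 9, 16, 25} × r ∈ {0.1, 0.15, 0.2, 0.5}).
Shannon differential entropy of the Gaussian at scale τ,
½log(2π/τ) + ½, gives the same monotone picture.  All entropies are in
nats; `entropy_in_base` converts.

Correction strategies, as exposed in `MSEParams.threshold_mode`:

* `adaptive` — r from the SD of each coarse-grained series.  Correct
  for any signal, including ones whose variance changes across scales
  for genuine (correlated) reasons.
* `analytic_gaussian` — r × SD(original)/√τ.  Exact for iid input
  only; included because it is the theoretically derived form and as a
  cross-check of the adaptive mode on Gaussian data (their per-scale
  tolerances agree within 10% there).

`normalize_input` (default true) rescales the input to mean 0, SD 1
first, making the scale-1 tolerance exactly `r_factor` in fixed mode
and the two modes identical at τ = 1.

The comparison driver coarse-grains once per scale and evaluates both
modes on the identical series; its `bias` column is reported as
adaptive-minus-fixed, i.e. the positive entropy deficit caused by the
fixed threshold, so that it lines up with the analytic `predicted_bias`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| m | 2 | embedding window length (samples); 2 is the standard choice for physiological series |
| r_factor | 0.15 | tolerance as a multiple of SD (dimensionless); 0.15 is the conventional value |
| scales | 1…20 | coarse-graining levels τ (block length in samples) |
| threshold_mode | fixed | which SD the tolerance is tied to (see above) |
| normalize_input | true | standardize input before analysis |

Guideline: the largest scale should keep ⌊N/τ⌋ ≥ m + 2 points or the
curve will carry gap records (gaps are recorded, never fatal).

## Synthetic signals

The generators define the validation conditions; all are seeded and
bit-reproducible (one private RNG stream per call).

* **Gaussian noise** — iid N(μ, σ²); the zero-complexity reference.
* **1/f noise** — spectral synthesis: complex Gaussian spectrum shaped
  by f^(−β/2), DC forced to zero, inverse FFT, rescaled to the target
  SD exactly.  β defaults to 1 (pink noise) and is supported on
  [0, 2].  The periodogram slope is −β within ±0.1 when averaged over
  8 seeds at N = 2×10⁴.
* **Random walk** — cumulative sum of iid N(0, σ²) increments,
  deliberately not re-standardized: the nonstationarity is the point.
* **ARIMA(p, d, q)** — stationary ARMA core simulated with a burn-in
  of 10(p+q+1) samples discarded, then integrated d times.  AR
  stationarity is enforced when d = 0.

What these do *not* emulate: real physiological data with trends,
artifacts, missing samples, quantization, or nonlinear dynamics.
Passing tests show the algorithms behave as derived on signals with
known structure; they do not certify entropy estimates on arbitrary
recordings.

The demonstration pipeline (`mse figure1`) runs the fixed/adaptive
comparison on the three reference signals at N = 2×10⁴: Gaussian noise
shows the full predicted decay and its correction to a flat curve;
1/f noise and the random walk are nearly indifferent to the correction
because their coarse-grained SD barely shrinks (temporally correlated
processes do not average out), which is exactly why the fixed-threshold
artifact passed for signal "complexity" ordering.

## Estimator behavior and validation sizes

SampEn estimates are reliable when match counts are large.  The
validation suite uses N = 2×10⁴ (scales 1–20, so ≥ 1000 points per
scale) for the headline curves, averaging the biased Gaussian curve
over 5 seeds against the closed form (agreement within 0.1 for
τ ≤ 10, 0.2 up to τ = 20), and checking per-seed flatness of the
corrected curve within 0.15.

The parameter-grid check (m ∈ {1,2,3} × r ∈ {0.1, 0.15, 0.2}) runs at
N = 10⁴ over 30 seeds.  At the grid's extreme cell (m = 3, r = 0.1)
the expected (m+1)-match count per series at the largest scales is of
order 1; there, per-seed −log(a/b) is structurally biased (Jensen on
the log at small counts, plus survivorship when a = 0 realizations are
dropped), so per-scale entropies are estimated by pooling raw counts
across realizations before taking the log.  Even pooled, that cell's
log-ratio standard error is ≈ 0.15 because template matches cluster in
time, and its per-scale scatter (max ≈ 0.29 around the correct flat
value, with no trend) exceeds a ±0.2 band that the other eight cells
meet comfortably; pinning it down further would take an order of
magnitude more replicates.  This is a small-sample property of the
statistic, not of the correction.

Numerical choices: sample SD uses the n−1 denominator everywhere;
quadrature uses adaptive `dblquad` with absolute/relative targets of
10⁻¹²/10⁻¹¹ and verifies its own error estimate against the requested
tolerance; degenerate (constant) input produces gap records or exact
zeros depending on whether the SD is exactly zero.

## Limitations

* No refined-composite or overlapping-window MSE variants, no
  multivariate MSE, no fuzzy/permutation/dispersion entropies.
* The analytic oracles cover iid Gaussian input only; no closed forms
  for correlated processes are provided.
* Input formats are plain text / single-column CSV only.
* ApEn is included for comparison, not recommended for inference.
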