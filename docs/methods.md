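# Methods

## Model and scope

Observed event counts for a provider are modelled as X ~ Poisson(λ), λ > 0
the expected count from indirect standardisation (generically non-integer,
taken as known). The SMR is X/λ with target 1. Everything here is exact
Poisson/chi-square arithmetic: no overdispersion adjustment, no
multiple-testing correction across providers, no estimation of λ or of a
random-effects target. Two nominal two-sided levels are treated as first
class, 0.95 ("alarm") and 0.998 ("action"), with per-tail nominal
probability α/2 = 0.025 and 0.001; any level in (0, 1) is accepted.

## Limit constructions

For level 1 − α and mean λ, on the count scale:

| method | lower | upper |
|---|---|---|
| wald | λ − z₁₋α/₂√λ | λ + z₁₋α/₂√λ |
| exact | ½·χ²(α/2; 2λ) | ½·χ²(1−α/2; 2λ+2) |
| prediction | smallest integer L with F(L) ≥ α/2 | largest integer U with P(X ≥ U) ≥ α/2 |

with F the Poisson(λ) CDF. Quantiles are evaluated at full floating
precision (z₀.₉₇₅ = 1.959964…, never the textbook 1.96). Chi-square
quantiles with non-integer degrees of freedom 2λ are well defined through
the gamma equivalence (χ²_c ≡ Gamma(c/2, scale 2)), which is how scipy
evaluates them. Wald lower limits may be negative and are stored
unclamped — the probability below a non-positive limit is automatically
zero; figures clamp the displayed curve at 0 only. Exact lower limits are
strictly positive for every λ > 0, which is what makes X = 0 a "low
outlier" under exact limits at small λ.

### Outside convention

"Falling outside" means **strictly** beyond a limit; an observation exactly
on a limit is inside. This is the only convention under which the
conservative prediction limits satisfy their defining guarantee
P(X < L) < α/2 and P(X > U) < α/2, and it reproduces the reference value
P(X = 0) = e⁻¹ = 0.3679 for the exact lower tail at λ = 1 (limit 0.0253).
Classification of a provider is performed on the count scale at λ equal to
the provider's own (continuous) expected count; dividing by λ > 0 preserves
strict inequalities, so SMR-scale classification is identical, and binning
λ to a grid would distort flags.

### Tail rules for the prediction limits

Discreteness forces a choice between two adjacent integers in each tail:
the outer one leaves at most α/2 strictly outside, the inner one at least
α/2. The **conservative** rule (default, and the primary definition) takes
the outer integer in both tails; the **liberal** rule takes the inner
integer in both tails, so each tail probability is ≥ α/2; the
**asymmetric FUNNELCOMPAR** rule mimics the Stata convention — conservative
below, liberal above. At λ = 10, level 0.95, the upper candidates are 16
(tail 0.027) and 17 (tail 0.014): conservative picks 17, liberal 16. All
stored limits use the strict-outside convention, so a rule stated elsewhere
as "flag X ≥ x_U with P(X ≥ x_U) ≥ α/2" appears here as the stored limit
x_U − 1. At very small λ the two inward steps can cross (e.g. λ = 0.1 at
95%), leaving no liberal interval; that is reported as an error rather than
an arbitrary pair.

### Display smoothing

The integer prediction limits produce step-function funnel curves. For
plotting only, the steps are smoothed by interpolating linearly in the
exceeded tail probability between adjacent integers: with T(x) = P(X ≥ x),

    upper* = x_U + (α/2 − T(x_U+1)) / (T(x_U) − T(x_U+1))  ∈ [x_U, x_U+1)
    lower* = x_L − (F(x_L) − α/2) / (F(x_L) − F(x_L−1))    ∈ (x_L−1, x_L]

The smoothed values bracket the integer limits and are strictly
quarantined from classification and coverage — toggling the smoothing can
never change a flag, and the test suite asserts this.

## True coverage and its summaries

For any limit pair the true outside-probabilities are read directly off
the Poisson CDF: p_below = F(⌈lower⌉ − 1) (zero when lower ≤ 0) and
p_above = 1 − F(⌊upper⌋). Both are sawtooth functions of λ: they jump
wherever a limit crosses an integer and drift monotonically in between,
approaching α/2 as λ → ∞ for all three methods.

Summaries report the median, minimum and maximum per λ range, with the
ranges 1–50, >50–100, >100–500, >500–1000, >1000–10000 (left-open, the
first closed at 1; the bins are exhaustive and disjoint). Medians use the
standard mean-of-central-pair convention; table output is rounded to 4 dp.

**Grid resolution.** Because the summarised curves are sawtooths, the bin
statistics depend on how finely λ is sampled. An integer-step sweep is too
coarse for the small-λ bin: it under-samples the teeth and shifts the 1–50
medians by up to 7 in the 4th decimal place. The default grid is therefore
graded — step 0.001 on [1, 50], 0.01 on (50, 1000], 0.1 on (1000, 10000] —
chosen so that each bin's median is stable at 4 dp under further
refinement while the full 60-cell table still computes in a few seconds on
one CPU. The integer grid remains available (`integer_lambda_grid`,
`--grid integer`); for the 501–1000 bin the two grids agree at 4 dp on
every 95% median. Residual instability at the fourth decimal survives only
in a handful of min/max cells (suprema approached at the sawtooth jump
points) and in 99.8%-level cells whose probabilities are O(10⁻³); those
cells are regression-tracked against this package's own frozen output
rather than treated as exact.

## Monte-Carlo cross-check and the synthetic cohort generator

`empirical_coverage` draws n Poisson(λ) counts with numpy's PCG64
generator (explicit integer seed, no silent default) and classifies them
with the same strict-outside rule; the suite checks agreement with the
analytic tails within 3 binomial standard errors at n = 200,000.

`simulate_providers` emulates a cross-sectional provider cohort:
in-control providers draw X ~ Poisson(λᵢ), out-of-control providers
X ~ Poisson(θλᵢ) with rate ratio θ ≠ 1; λᵢ is fixed, uniform over a range,
or an explicit list. Truth labels are written only to the simulation
sidecar columns (`true_status, theta`), never to the plain provider table,
so classification cannot leak truth. The generator emulates only Poisson
sampling variation around known expected counts — it does not emulate
overdispersion between providers, errors in the risk model that produced
λᵢ, or correlated outcomes. Passing tests therefore demonstrate the
arithmetic of the limits, not that real providers are well described by a
pure Poisson in-control model.

## Numerical and design notes

- Limits are deterministic; float assertions in tests use absolute
  tolerance 1e−10 for limit values and 5e−5 for probabilities compared to
  4-dp published values.
- Poisson integer limits come from scipy's discrete `ppf` (smallest k with
  F(k) ≥ q) plus one explicit survival-function check for the upper tie
  case F(k) = 1 − α/2, so ties resolve exactly as the definitions require.
- Confidence-interval curves are always rendered raw; only the prediction
  curve is ever smoothed.
- The CLI is a thin layer over the library: exit code 0 on success, 1 on
  validation errors, 2 on I/O errors; every run logs package version and
  resolved parameters (and seed where stochastic) to stderr.

## Known limitations

- The in-control model is pure Poisson; with overdispersion all three
  methods' true flag rates would exceed the values computed here.
- Expected counts are taken as given; uncertainty in the risk model behind
  them is out of scope.
- The liberal rule is undefined (empty interval) for very small λ; callers
  probing λ ≪ 1 should use the conservative rule.
- Min/max bin statistics are suprema/infima of discontinuous curves and
  are reported at the resolution of the default grid, not as analytic
  extremes.
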