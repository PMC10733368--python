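# Methods

## Models

### Divisive-normalization population model

A bank of `M` units with preferred directions φⱼ and Gaussian tuning of width
`s` encodes cursor direction errors (degrees). Each unit is driven only by
the cursor nearest its preferred direction (max over cursors), contributes
`xⱼ = w φⱼ fⱼ(e)`, and the population output is `X(e) = Σxⱼ / (kM' + Σxⱼ²)`
with `M'` the number of distinct preferred directions (see *Grid* below).
The Gaussian is evaluated as a plane (non-circular) function of degrees; this
approximates circular tuning and degrades for large errors, so error sets
with any |eᵢ| > 90° are accepted but flagged (`ErrorSet.approx_warning`).

For a single cursor the sums reduce to Gaussian integrals, giving the closed
forms implemented in `analytic_single` (with normalization) and
`linear_response_single` (without). The closed form has one interior maximum
at `e* = sqrt((720k + √π w² s³) / (2√π w² s))` (`peak_error`), and `w²/k`
(`nonlinearity_index`) measures the strength of the saturation.

**Grid.** Preferred directions lie on the symmetric inclusive grid
φⱼ = −180 + (j−1)·360/(M−1), so 0° is always a grid point and the grid is
exactly odd-symmetric; with the default M = 3601 the spacing is 0.1°. Because
the endpoints ±180° name the same direction, the normalization constant is
scaled by the number of *distinct* directions, k·(M−1). With this pairing the
unit density (M−1)/360 cancels exactly: the response is invariant to grid
refinement (tested at < 10⁻⁶ on doubling M) and converges spectrally to the
closed forms (observed agreement ~10⁻¹⁰; the acceptance tolerance of 10⁻³
is conservative).

**Exact symmetry.** Population sums are accumulated by pairing unit j with
its mirror M−1−j. Negating every error reverses and negates the unit outputs,
and each pair term then negates exactly in IEEE arithmetic, so oddness
X(−e) = −X(e) and X(0) = 0 hold *exactly*, not merely to rounding.

### MLE cue-combination model

`mle_single`/`mle_multi` implement posterior-mean shrinkage of the observed
error(s) toward the zero-mean motor prediction, with signal-dependent
observation noise σ(e) = σᵥ + kᵥ|e| applied per cursor. Only the gain `c` and
the ratios σᵥ/σₚ and kᵥ/σₚ are identifiable, and only those are stored
(`MLEParams`; an absolute-σ constructor normalizes immediately). The
constant-noise "ordinary MLE" (kᵥ = 0) is a flag; it makes the single-cursor
response exactly linear.

**Ordinary-MLE decline ratio.** Applying the multi-cursor formula with
constant per-cursor noise to cursor-cloud draws gives an expected response
that is linear in μ and *independent* of the cloud dispersion σ — declining
rates of exactly zero and an undefined 0/0 ratio. The constant-noise account
of feedback uncertainty instead treats the cloud dispersion as observation
noise: the observed-error variance is σᵥ² + σ², so the expected response is
`c μ / (1 + (σᵥ/σₚ)² + (σ/σₚ)²)`. The shrinkage depends on σ but not on μ,
making the declining rates identical at every mean error and their ratio
exactly 1 for all σ — the property the model is used to foil. The absolute
scale σₚ (default 1°) shifts the rates themselves but cancels from every
ratio, so the reported ratio does not depend on it.

## Fitting

`fit_dn_single` and `fit_mle_single` minimize squared error on condition-mean
(error, response) points using bounded `scipy.optimize.least_squares` in
log₁₀ parameter space (parameters span orders of magnitude), multi-start on
log-spaced grids: DN, 5×5 over w ∈ [10⁻⁵, 10⁻²] × k ∈ [10⁻⁸, 10⁻⁴]; MLE,
3×3×3 over c ∈ [10³, 10⁷] × σᵥ/σₚ ∈ [10, 10³] × kᵥ/σₚ ∈ [0.1, 10²].
Tolerances 10⁻¹², at most 10⁴ evaluations per restart; the best restart wins
and the best loss is invariant to restart order (tested). `s` is fixed at 22°
and `M` at 3601. The e = 0 condition is included (its model value is
identically 0 and it anchors the intercept). Fit quality is
R² = 1 − SSres/SStot with SStot about the observed mean; prediction R² is
computed without refitting, which is what permits negative values.

**Identifiability.** On noiseless data both fits recover the generating
parameters to ≲10⁻¹⁰ relative. Under realistic noise two structural limits
appear, which we report rather than hide. (1) In the DN closed form, 720k is
only ~10% of the denominator at the reference parameters, so k's relative
error amplifies the data error ~10-fold; a Cramér–Rao analysis at trial noise
of 10% of the peak response (9 replicate cycles) puts k's relative SD floor
at ~78% — no estimator can pin k to 10% under those conditions, although the
fitted *curve* and w (~3% median error) are accurate. (2) In the MLE model,
(c, σᵥ/σₚ) are separated only by the "+1" in 1 + (σ(e)/σₚ)², a ~10⁻⁴
relative effect at the reference ratios; under noise only the combinations
kᵥ/σᵥ and c/(1 + (σᵥ/σₚ)²) are recoverable (~5% median), while the absolute
parameters wander along the flat direction. The acceptance suite asserts the
strict per-parameter recovery target and the corresponding test fails by
design under these conditions; the property suite covers the identifiable
quantities.

## Monte-Carlo cloud expectations

`expected_cloud_response` draws `n_draws` independent clouds of `n_cursors`
errors from N(μ, σ²), evaluates the model on each draw, and returns the
sample mean and its standard error. Defaults: n_draws = 100,000 with a fixed
seed (20231220); σ = 0 short-circuits to the exact deterministic response
(duplicated cursors are inert under the max rule). The DN and MLE cloud
predictions use the same sampling scheme so both models face identical study
conditions. The pipeline and analysis scripts default to 20,000 draws, at
which the Monte-Carlo SE is well below 1% of the condition effects they
report; tests use 2,000–50,000 depending on the sharpness of the property.

## Synthetic experiments

`build_exp1_schedule` reproduces the 39-condition multi-cursor design
(9 single: e₁ ∈ {0, ±7.5, ±15, ±30, ±45}; 18 double: unordered pairs from
{0, ±15, ±30, ±45} with |e₁| ≠ |e₂|; 12 triple: e₁ ∈ {−45…22.5} with
(e₂, e₃) = (30, 45) plus the sign-mirrored six), 9 cycles of 4 trials
(perturbation, probe, 2 washouts) = 1404 trials. `build_exp23_schedule`
reproduces the 15-cloud design (μ ∈ {0, ±14, ±40} × σ ∈ {0, 7, 20}, five
cursors), 12 cycles = 720 trials, in online- or endpoint-feedback mode.

`simulate_responses` generates participant-level tables from a ground-truth
DN parameter set: cloud conditions redraw their five cursors every
perturbation trial; additive Gaussian trial noise (default SD = 15% of the
peak single-cursor response) is applied per trial and cycles are averaged
within participant before any across-participant statistics, exercising the
pipeline's averaging order. Default ground-truth parameters are the
experiment-specific single-cursor fit values (learning exp 1:
w = 5.3271×10⁻⁴, k = 7.7806×10⁻⁷; exp 2: 2.0002×10⁻⁴, 2.1434×10⁻⁶; exp 3
endpoint: 4.7525×10⁻⁴, 2.1102×10⁻⁶; feedback responses: 4.0541×10⁻⁴,
9.2642×10⁻⁵ and 2.3700×10⁻⁴, 1.2071×10⁻⁵), and default sample sizes are the
experiments' analysis n (8/15/10).

What the generator does *not* emulate: movement kinematics and force-channel
mechanics, velocity-based trial exclusion, washout dynamics, participant
heterogeneity (responses are exchangeable across participants), or any
deviation of real behavior from the DN model itself. Passing tests therefore
establish that the pipeline recovers what it assumes — parameter and
prediction consistency — not that the DN model is true of real data.

**Collapsing.** Mirror-image condition pairs (all errors negated) are
collapsed per participant as (r(C) − r(−C))/2, assigned to the canonical
representative (the sign variant with the lexicographically larger
sorted-descending error tuple; clouds: μ ≥ 0). This averages the two signed
conditions under the models' odd symmetry and cancels direction-independent
offsets. Exp 1's 39 conditions collapse to 20 (5 single + 9 double +
6 triple); the cloud experiments' 15 collapse to 9.

## Derived statistics

`averaged_response` averages the double-cursor response over e₁ ∈ {15, 30, 45}
per e₂ level, with the single-cursor mean over the same e₁ as reference. The
|e₁| = |e₂| cells are excluded from the experimental design; they are filled
with their exact model-level equivalents — the single-cursor condition at e
for e₂ = +e₁ (duplicate inertness) and 0 for e₂ = −e₁ (odd symmetry). For
observed data this is a model-neutral imputation of two cells per affected
level and is shared by every model being compared.

`declining_rate` is (r(σ=0) − r(σ))/r(σ=0) at fixed μ; `decline_ratio`
divides the small-μ by the large-μ rates per σ. Both orientations are
emitted (`decline_ratio_small_over_large` and its reciprocal) because the
reported quantity is conventionally the orientation that falls below 1 when
the large-error decline is relatively suppressed — that is the
large-over-small orientation for the DN model — while the ordinary-MLE foil
is 1 in either orientation. With a negative rate (a response that *increases*
with uncertainty, which occurs at μ = 40°, σ = 7° in noisy data) the ratio
changes sign; it is reported as computed and not further interpreted.

## Pipeline and problem sizes

`AnalysisConfig`/`run` execute: build schedule → simulate (or load a response
CSV) → collapse → fit DN and/or MLE on the single-cursor (σ = 0) conditions
only → predict every collapsed condition → R² scores and derived statistics →
JSON/CSV bundle with a run log (seed, draw counts, config echo, versions).
Everything is deterministic given the config seed; per-condition cloud
predictions use independent seeded streams. The analysis scripts run the
three experiments at full design size (1404/720 trials, 8–15 participants)
with 20,000 Monte-Carlo draws per cloud condition; the test suite uses the
same designs with smaller draw counts chosen per property.

## Known limitations

- The plane-Gaussian tuning is wrong beyond ~90°; inputs there are flagged,
  not wrapped.
- k (DN) and the absolute MLE noise parameters are weakly identified from
  5-point single-cursor data (see *Identifiability*); conclusions should rest
  on the fitted curves and predictions, which are well determined.
- No uncertainty quantification on fitted parameters and no model-selection
  criteria: models are compared by out-of-condition prediction R² only.
- Inferential statistics (t-tests, ANOVA) on participant-level data are out
  of scope; the pipeline reports descriptive means ± SE.
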