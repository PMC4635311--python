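# Methods

## The model

Stimuli live on a common normalized depth axis: a point in the
disparity–motion plane `(s_d, s_m)`, positive = behind the surround. The
default calibration maps the consistent-cue standards — 8 arcmin of
disparity, 0.25° of surround-relative motion — both to 1.0, preserving the
task's relative geometry without asserting a perceptual exchange rate
between arcmin and degrees (none is known; `CueCalibration` makes it
configurable). Condition geometry: D = `(s, 0)`, M = `(0, s)`,
DM = `(s, s)`, conflict D−M = `(s, −s)` with motion carrying the negated
(in-front) depth by default; the convention is switchable because a
child's "furthest behind" judgment under extreme conflict could in
principle track either cue.

An observer measures each interval with independent Gaussian channel noise
(`σ_d`, `σ_m` per interval). Two readouts:

- **Fusion** projects each interval's noisy measurement onto the fixed
  reliability-weighted direction `w = (σ_m², σ_d²)/(σ_d² + σ_m²)` and
  compares intervals. The fused estimate has
  `1/σ_f² = 1/σ_d² + 1/σ_m²`, and the predicted psychometric sensitivity in
  condition `c` with cue direction `u_c` is `|w·u_c| / (σ_f √2)` — the √2 is
  the standard two-interval factor (noise in both intervals).
- **Independence** weights each channel's interval difference by
  `Δμ_c/σ_c²` (the optimal linear readout given the true separations) and
  reports the signed judgment. Its sensitivity is the quadratic sum
  `√(Σ u_c²/σ_c²) / √2`, blind to the relative sign of the cues.

These closed forms are the oracles for the Monte-Carlo simulator; the two
agree within 3 Monte-Carlo SEs at 10,000 trials/level over a 3×3 grid of
noise levels (an acceptance check).

For an exactly equal-weight fusion observer the conflict psychometric
function is flat (sensitivity 0); with unequal reliabilities it has a
shallow slope that may even be *decreasing* (the observer follows the
heavier-weighted cue). The fitter therefore tries both orientations of the
cumulative Gaussian and reports `σ > 0` with a `slope_sign`; sensitivity
`1/σ` measures discriminability magnitude.

## Psychometric fitting and exclusions

Fits are trial-wise binomial maximum likelihood of
`P(choose comparison) = Φ((x − μ)/σ)` in `(μ, log σ)`, bounded
`σ ∈ [10⁻⁶, 10³]`; a fit pinned at a bound is flagged non-converged (flat
data never raise). No lapse parameter is fitted — σ absorbs lapses,
matching the stated analysis. R² is computed on the six level-wise response
proportions against the fitted curve, because that is the scale on which
the fit-quality exclusion rule is defined. The delta-method SE of `1/σ`
comes from the observed information in `(μ, log σ)`, where
`SE(1/σ) = SE(log σ)/σ`.

Exclusion rules (all configurable; defaults R² < 0.7 in any condition,
|PSE − standard| > 3 arcmin after mapping the condition axis to
arcmin-equivalents, either index > 5 SDs from the cohort mean): applied in
a single pass using pre-exclusion cohort statistics — the conservative
reading absent a stated iteration scheme. Note an algebraic consequence of
the single-pass rule: a lone outlier can reach at most `(n−1)/√n` SDs of
the contaminated cohort, so the 5-SD rule can only ever fire in cohorts of
more than ~26 subjects.

The developmental curve fits constant, linear, and exponential
`I(age) = a·exp(b·(age − 6)) + c` (anchored at the cohort minimum age for
identifiability) by least squares, selecting by AIC. Besides the zero
crossing (reported when the curve crosses zero inside [6, 12]), the fit
exposes a **half-rise age** — where the exponential reaches half its total
age-6→12 rise. The zero crossing is undefined whenever the early plateau
fits at or above zero, which happens in roughly half of realizations when
the young-age indices are truly zero; the half-rise age is defined for any
growing exponential and is the transition summary used in the end-to-end
recovery check.

## Synthetic cohort (study conditions)

Defaults model a developmental cohort: 140 tested children aged 6–12,
drawn from the three analysis bins (6–8.5, 8.5–10.5, 10.5–12) with weights
0.20/0.38/0.42 (recruitment skewed toward older children, where the
transition of interest lies); the readout mechanism switches from
independence to fusion at 10.5 years. Disparity channel noise is log-uniform in 0.2–0.3
normalized units (≈1.6–2.4 arcmin discrimination threshold — steep enough
for the fixed 3–13 arcmin level design to yield R² > 0.7 fits, as the
included real subjects must have been); motion noise is 1.4–1.7× disparity
noise, making motion reliably the weaker cue. The asymmetry matters: an
exactly equal-weight fusion observer has a flat conflict psychometric and
would always be excluded by the fit-quality rule, whereas really
integrating children were not — unequal weights keep the conflict slope
measurable. Lapse rate 0.02. With these conditions ~100 of 140 subjects
survive exclusion — an exclusion fraction (~25–30%) typical of pediatric
psychophysics under strict fit-quality rules.

What the generator does not emulate: age-dependent sensitivity improvement
within mechanism, partial/graded fusion, session-order or learning effects,
and any response bias beyond the PSE. Passing tests therefore show that the
analysis recovers a known mechanism switch under realistic noise — not that
real development is a hard switch.

## Synthetic fMRI and decoding

Each voxel responds linearly through three latent channels — disparity
sign, motion sign, fused depth — plus a nonnegative overall
stimulus-response weight (larger for selective voxels) that makes selection
by the stimulus-vs-baseline t contrast meaningful, as it is for responsive
gray matter. The fused channel responds to the mean of the two cue
activations (full for consistent cues, half for single cues, zero under
conflict) scaled by `fused_gain`; gain 0 is the "younger" regime in which
the near/far pattern separation in DM equals both the quadratic sum of the
single-cue separations and the conflict separation exactly (in
expectation), giving the decoding stage a ground-truth identity to recover.
Hemodynamics are a pure 2-volume (4 s) boxcar delay — the same shift the
analysis applies — rather than an HRF convolution, so generator and
analyzer agree by construction. Run length follows from block arithmetic
(24 blocks × 8 volumes + 16 baseline volumes = 208), which takes precedence
over forcing any particular printed volume count.

Decoding follows the standard chain: per-run z-scoring (whole run,
including baselines), +2-volume window shift, 8-volume block averaging,
per-pattern mean-centering, linear SVM with C = 1 and no further scaling,
leave-one-run-out over 6 runs (15+15 train, 3+3 test per fold). Accuracies
are clipped to `[1/(2N), 1 − 1/(2N)]` (N = 36 test patterns) before
`d′ = 2·erfinv(2a − 1)` so finite designs map to finite d′. Permutation
nulls shuffle near/far labels *within run*, preserving the cross-validation
structure, and are computed per condition. Because fold accuracies are
multiples of 1/36, the null is discrete; the 97.5th-percentile bound is
therefore conservative (the exceedance rate under the null is at most, and
typically slightly under, 2.5%).

Default SNR (300 voxels, unit channel gains, volume noise SD 25, 120
selected voxels) yields single-cue decoding accuracies ≈ 0.65–0.75,
in the range typical of near/far depth decoding from visual-cortex block
designs (~65% overall SVM accuracy).

The searchlight uses Euclidean neighborhoods on the integer voxel lattice;
the default 3-voxel radius corresponds to an 8-mm sphere at 2.3-mm voxels
(`mm_to_voxel_radius`). Map smoothing is a NaN-aware Gaussian with FWHM
equivalent to 3 mm at the configured voxel size. Neighborhoods with fewer
than two voxels are masked.

## Numerical choices and problem sizes

- Psychometric optimizer: L-BFGS-B from `(median level, log(span/4))`;
  both slope orientations tried, better likelihood kept.
- Voxel-selection ties broken by ascending voxel index (stable sort), so
  repeated calls agree.
- Exponential curve fit: `scipy.optimize.curve_fit` with the exponent
  clipped at ±50; on non-convergence the best converged model is used and
  flagged.
- Validation sizes: oracle grid 2 mechanisms × 3×3 noise levels × 4
  conditions at 10,000 trials/level; mechanism signatures 8 observers each;
  decoding identity 30 seeds; permutation calibration 200 shuffles vs 200
  permutations; developmental recovery 50 cohort replicates in the test
  suite and 25 in the acceptance script. These sizes keep each stage's
  Monte-Carlo error well below the effects being checked.

## Known limitations

- The behavioral observer is a pure mechanism (full fusion or full
  independence); graded or cue-switching strategies are out of scope.
- The fMRI generator has i.i.d. Gaussian noise — no temporal
  autocorrelation, physiological noise, or motion — so permutation nulls
  are exactly exchangeable by construction; real data are harsher.
- The exponential parameterization and model-selection procedure for the
  developmental curve are this package's documented choices; the original
  analysis's exact procedure was not specified in the available text.
- Searchlight maps are single-dataset; group-level surface statistics are
  out of scope.

Two estimator caveats follow from converting 36-test-pattern accuracies to
d′. First, the transform `2·erfinv(2a − 1)` is convex above chance, so fold
noise inflates estimated d′ more for stronger conditions; at the default
SNR this leaves the no-fusion gap `d′_DM − √(d′_D² + d′_M²)` with a small
positive bias (≈ +0.3 d′ units) even though the underlying pattern
separations obey the identity exactly. The identity checks are therefore
run at tolerances tied to simulation error across seeds rather than
asserted pointwise. Second, on group tests of index2: when true d′ values approach zero, the
quadratic-sum term √(d′_D² + d′_M²) folds noise fluctuations upward, so the
per-subject index2 becomes skewed and its independent-samples t test runs
slightly anti-conservative. At the default SNR (d′ ≈ 1–1.6) the measured
false-positive rate is nominal; very-low-SNR configurations should use a
permutation-based group test instead.
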