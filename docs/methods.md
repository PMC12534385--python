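# Methods

`pitchsync` chains three measurement layers — missing-fundamental (MF)
psychophysics, pedal-timing metrics, and hierarchical Bayesian recall
models — and closes the loop with a synthetic-study generator whose truth
is expressed in the fitted models' own coordinates, so parameter recovery
is a well-defined experiment.

## Missing-fundamental stimuli and the pitch index

An MF complex tone has harmonics at n·F0 for n = n_min … n_min+N−1 with
n_min ≥ 2, so no energy at the periodicity frequency F0. Its pitch can be
heard at F0 (periodicity pitch) or at a sounding harmonic, taken here as
the lowest one: F_SP = n_min·F0 (an amplitude-weighted spectral-centroid
alternative is available via `HarmonicComplexSpec.spectral_centroid_hz`).

Component levels: −5 dB per harmonic order above n_min, relative to the
n_min component before attenuation, plus a log-linear high-frequency
attenuation of −3 dB from 1 to 3 kHz and a further −17 dB from 3 to
15.9 kHz. We read the two attenuation segments as cumulative (−20 dB
total at 15.9 kHz) and hold the value constant above 15.9 kHz; the level
reference and the behaviour past 15.9 kHz are conventions of this
implementation. Synthesis uses sine (zero) phases — deterministic and
testable spectra — 0.6 s duration, 10 ms linear fades, peak normalization
to −3 dBFS, 44.1 kHz PCM16 WAV output.

The test battery pairs tones so that F0 and F_SP move in opposite
directions while the highest sounding harmonic is exactly shared (the
partner of (f0, n_min, N) is (f0·m/(m−1), n_min−1, N) with m =
n_min+N−1), which removes the edge-pitch cue. The default grid — 9
log-spaced base F0 in [100, 500] Hz × n_min ∈ {3…8} × N ∈ {2, 3, 4} —
yields the fixed design size of 162 pairs / 324 unique sounds; the grid
itself is configurable (YAML round-trip via `save_design`/`load_design`),
the design size is an invariant. Pair order and within-pair order are a
plain seeded shuffle; no further ordering constraints are imposed.

A "which tone was higher" answer matches exactly one of the two cue
directions; counting spectral- and fundamental-consistent answers gives
the pitch perception index δ_P = (n_SP − n_F0)/(n_SP + n_F0) ∈ [−1, 1].
δ_P is undefined (an error, not 0) when nothing was classified.

## Pedal timing

Crossings of the left pedal through a light barrier are detected as
upward threshold crossings of the 100 Hz photocell voltage with linear
sub-sample interpolation; a refractory window (default 0.25 s) suppresses
bounce. The default threshold is the midpoint of the trace's peak-to-peak
range. Metrics use complete revolution durations d_i only:

* mean speed = mean(1/d_i) (Hz),
* CV = sd(1/d_i)/mean(1/d_i) with the sample (n−1) SD — the default of
  the surrounding statistical ecosystem,
* IBD = mean |d_i − SOA/2| with SOA = 2 s, so the target duration is 1 s.

Under self-initiated stimulation the stimuli are triggered by the
pedaling, so the synchronization error is zero by construction;
`ibd(..., mode="self_initiated")` returns exactly 0 rather than
evaluating a deviation against a moving target.

## The regression engine

Families: binomial (logit), Gaussian (identity; optionally with known
per-observation SEs added in quadrature to the residual SD, and the
residual SD optionally fixed to zero), Gamma (log). Linear predictors
combine:

* orthonormal factor contrasts (columns orthonormal and orthogonal to the
  intercept, equalizing marginal priors across level differences),
* low-rank thin-plate regression splines: radial basis |r|³ restricted to
  quantile knots, the T′δ=0 constraint absorbed by null-space projection,
  columns centered (sum-to-zero next to the intercept), the linear trend
  kept as an unpenalized column. Inside a model the penalized block is
  reparameterized to an identity penalty and scaled by a half-normal τ
  (non-centered). Smooth-by-factor interactions are built as a shared
  reference smooth plus one deviation smooth per factor cell; the
  redundancy between reference and deviations is resolved softly by the
  shrinkage priors rather than by a hard constraint,
* monotonic ordinal effects β·Σ_{i≤x} ζ_i with ζ a simplex; ζ is
  parameterized by a pinned softmax whose Jacobian yields the exact
  Dirichlet(1) prior,
* correlated group-level intercepts/slopes b_j = A z_j with z_j standard
  normal (non-centered) and A the covariance Cholesky factor. Priors go
  directly on A: half-normal(1) on the diagonal (the leading scales) and
  normal(0, 0.5) on the off-diagonal entries. This keeps correlations
  centered on zero and weakly regularized while staying exactly
  differentiable; it replaces the more common separate SD + LKJ
  parameterization as this package's own design choice.

Default priors: normal(0, 2.5) on fixed effects of standardized
predictors; the intercept prior is centered on the empirical link-scale
mean of the response (data-derived location, scale 2.5); half-normal(1)
on group SDs, smooth scales, and the Gaussian residual SD;
normal(0, 1.5) on the log Gamma shape. All scales are configurable via
`PriorSet`.

Sampling is Hamiltonian Monte Carlo with analytic gradients (every term
is linear in its coefficients; scale parameters are sampled on the log
scale with Jacobians). Warmup is the first half of each chain: dual
averaging tunes the step size toward 0.8 acceptance and the diagonal mass
matrix is re-estimated in two windows. Trajectory lengths are jittered
uniformly up to `max_leapfrog` (default 24; models with hundreds of
correlated parameters mix better around 48–64 at proportional cost).
Divergent transitions (non-finite or energy error > 1000) are rejected
and counted. Diagnostics are rank-normalized split-Rhat and bulk/tail ESS
(via ArviZ); any Rhat above 1.05 raises a warning flag on the result
object, 1.01 is the soft warning threshold. Identical (seed, config,
data) reproduce identical draws.

Summaries: median; 66/90/95% highest-density intervals as the shortest
contiguous window of sorted draws (ties broken toward the lower window);
probability of direction pd = larger share of draws above/below zero
(zeros split evenly), with ER = pd/(1−pd) and the two-sided-p analogue
2(1−pd). Response-scale machinery: marginal predictions with group
effects zeroed (population level) and unspecified covariates held at
reference/mean; contrasts of per-draw means; finite-difference slopes
(central, h = 1% of the observed range, degrading to one-sided with a
flag at the support edge); upper-vs-lower half splits of a predictor
(median split default, mean split available — both agree under
symmetry); Gelman-style Bayesian R² on the response scale; ICC by
variance decomposition of the posterior predictive distribution
(simulated with fresh group effects vs. zeroed ones; Monte-Carlo error
may push individual values slightly below zero).

## Study models

The recall model is binomial-logit with trials = 40 per test: subject
random intercept plus correlated random slopes for condition, day, and
within-subject sleep; fixed condition × day interaction; session (order)
effect; a smooth of pitch index with one difference smooth per
condition × day cell ("smooth" variant) or the parametric 3-way product
("linear" variant); a monotonic effect of the number of foreign
languages; a smooth (or linear) effect of years of musical training; and
sleep split into a subject-mean (between) smooth/linear effect and a
subject-centered (within) linear effect interacting with day. A reduced
"basic" variant (condition, day, their interaction, session, random
intercept) is used for calibration experiments.

Motor-covariate models replace the pitch-index block with one motor
metric: speed untransformed; CV log-transformed and decomposed into
between-/within-subject components; IBD log-transformed after copying
each subject's isochronous IBD onto their self-initiated rows (IBD is
treated as a subject trait; the copy makes the column condition-invariant
within subject, which is asserted before fitting). Motor-outcome models:
speed is Gaussian with the observed per-session SE as known noise and a
subject random intercept (two rows per subject); CV is Gamma log-link
with a subject random intercept; IBD is Gamma log-link on isochronous
rows only (one row per subject, no grouping). Screening keeps subjects
with ≤ 20 of 40 pseudoword recalls. Session schedules carry 350 lead-in
tones (650 Hz, 50 ms), two 40-item blocks (block 2 reshuffled), a 7-min
break, repeat-cue tones, and exact 2 s onsets in the isochronous
condition; the two sessions cover 80 unique items. Gender, age and time
of day are not in the default models.

## Synthetic studies and what they show

The generator's defaults are the study conditions: 47 subjects, 2 × 2
within design, 40 trials per cell. Pitch index is Beta on [−1, 1]
moment-matched to mean 0.36 / SD 0.33 (left-skewed, as observed).
Recall truth is a packed parameter vector for the *same built model* the
pipeline fits — one shared linear-predictor code path — with defaults
anchored to the reported response-scale magnitudes converted to the link
scale at the ~8.5/40 baseline: day coefficient +0.10 on the orthonormal
contrast (≈ 0.9 words of overnight forgetting), session −0.18 (≈ 1.6
words of session-2 gain), condition +0.04 (≈ half a word of isochronous
advantage). Pedaling uses lognormal revolution durations (positive
support, multiplicative jitter) around 1 Hz with a +7% isochronous speed
bias and lower isochronous dispersion (0.045 vs 0.07), with per-subject
speed and dispersion multipliers; default 1560 revolutions per session
(~26 min at ~1 Hz). The MF observer answers each pair spectrally with
probability invlogit(θ + 0.8·difficulty), θ mapped from the subject's
latent pitch index and difficulty a standardized function of the pair's
harmonic order and register.

Not emulated: item-level word difficulty, response-time structure,
drop-out, serial-position effects, drift in pedaling over a session, and
any genuine pitch-index/training association (treated as coincidental).
Passing recovery therefore shows that the estimation machinery is
calibrated under the assumed generative structure — not that real data
meet that structure.

## Problem sizes and numerical choices

Recovery experiments run 20 replicates of 47-subject studies at reduced
draws (4 chains × 600 iterations for the basic variant; 2 × 600 for the
full linear variant), sizes at which the sampler's 90% HDIs cover truth
at roughly nominal rate and the day-effect sign is recovered in well over
80% of replicates. Report runs default to 4 × 3000. Degenerate inputs
are errors, not silent fixes: zero classified MF responses, nonpositive
revolution durations, all-equal smooth covariates, binomial responses
outside 0..trials. pd = 1 maps to ER = +inf (a sentinel, not a crash).

## Known limitations

* The HMC trajectory length is jittered-static, not NUTS; very stiff
  posteriors may need `max_leapfrog` raised manually.
* Difference smooths are soft-identified; the reference/deviation split
  is interpretable only jointly (cell-wise predictions are unaffected).
* The Gamma ICC and R² use the mean-parameterized shape; extreme shapes
  (< 0.1) are untested territory.
* Each model is fit independently; no cross-outcome correlation structure
  is estimated.
* The battery grid is a documented stand-in for the original (unpublished)
  stimulus set; only the design invariants are guaranteed to match.
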