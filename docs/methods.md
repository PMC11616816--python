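# Methods

## The task and the four subprocesses

The reference-back paradigm separates working-memory gating into four
measurable subprocesses.  Letters (X/O) appear inside a red frame
(*reference* trials: the letter becomes the new referent held in working
memory) or a blue frame (*comparison* trials: the letter is only matched
against the current referent).  Crossing trial type with gate switch
(whether the frame colour changed from the previous trial) and the
required same/different response gives eight conditions.  Four signed
combinations of condition means isolate the subprocesses, on reaction
times and on event-related potentials alike:

| subprocess   | contrast                                                     |
|--------------|--------------------------------------------------------------|
| updating     | no-switch reference − no-switch comparison                   |
| substitution | (different − same \| ns reference) − (different − same \| ns comparison) |
| gate opening | switch reference − no-switch reference                       |
| gate closing | switch comparison − no-switch comparison                     |

Switch trials are excluded from updating and substitution so gate
toggling does not contaminate them.  Where a contrast collapses over the
same/different sub-cells, the two sub-cell means are averaged unweighted
(cell-means convention, matching the ANOVA framing), not weighted by
trial counts.  The RT-ratio index divides each cost by the mean of its
two condition means, discounting general (e.g. age-related) slowing; the
substitution ratio is the reference-cell ratio minus the comparison-cell
ratio.

## Session generator

Defaults are the study design: 9 blocks × 80 trials, p(reference) = .5,
p(switch) = .25 among transitions, same/different balanced within block,
stimulus 500 ± 50 ms and fixation 1,400 ± 100 ms jittered on the 16.6 ms
display-refresh grid.  Each block's frame sequence is parameterised by
its switch positions: the switch count is drawn once per block with its
fractional part randomised (so the long-run switch rate equals the
target exactly), and switch positions are resampled until the
reference/comparison split lands within the balance tolerance
(1.5 trials).  Holding the count fixed across resamples matters:
redrawing it inside the rejection loop biases the realised switch rate
upward by about a percentage point.  The first trial of each block is
forced to be a reference trial and flagged unanalysable — this
guarantees a referent exists for every later trial; at session start the
required response is undefined until the first reference trial.
Responses are balanced within trial-type × gate-switch cells where the
cell size allows, with odd-cell remainders assigned to keep the block
total balanced.

## Behaviour model

Each trial's latent mean RT is a sum of a subject base RT, a group
slowing term, and the subprocess costs its condition triggers.  The
costs enter as *orthogonal* contrasts: updating loads on all reference
trials, gate opening on switch-reference, gate closing on
switch-comparison, and substitution as ±half-cost on different/same
reference trials.  Under this parameterisation each contrast estimator
above is unbiased for the generative cost of the same name — the naive
alternative (+cost on different-reference trials only) leaks half the
substitution cost into the updating estimator.

RTs are drawn from a shifted lognormal (shift 150 ms, the validity
floor: faster responses would have been initiated before the stimulus;
log-scale spread 0.35 by default), with the log-mean set so the expected
RT equals the latent mean exactly.  Misses occur with a lapse
probability and whenever a drawn RT exceeds the trial's response
deadline (stimulus + following fixation, 1,900 ± 150 ms).  Incorrect
responses occur with a lapse probability independent of RT.  Deadline
censoring removes a handful of the slowest responses and therefore
shifts the substitution cost estimate down by well under a millisecond
at the default parameters; this is a property of the task design, not of
the estimator.  Between-subject variance comes from a normal base-RT
random effect (SD 40 ms by default).

Default group parameters mirror the magnitudes observed in the reference
cohorts: costs of roughly (49, 55, 30, 92) ms in the younger and
(44, 123, 43, 63) ms in the older group, 130 ms overall slowing, and
incorrect/miss rates of 11%/3.1% vs 14.1%/5%.

## Epoch model

Epochs span −100…1,000 ms at 1,000 Hz (1,101 samples) across the 12
electrodes used in the mass-univariate analyses (F3, Fz, F4, C3, Cz, C4,
P3, Pz, P4, O1, Oz, O2).  Each epoch is a sum of Gaussian-in-time
components (latency, temporal SD, amplitude), each with a smooth scalp
weighting (Gaussian fall-off on a crude electrode grid) and signed
per-condition coefficients, plus noise with a 1/f amplitude spectrum
(white noise available), plus — with a configurable probability — a
single-channel step artifact large enough to trip peak-to-peak
rejection.  Per-trial randomness is seeded from (seed, block, trial), so
an epoch's content is a function of trial identity, not presentation
order.  The default template carries one component per subprocess
(occipital late updating negativity, frontal substitution positivity,
parieto-occipital gate-opening positivity, frontal gate-closing
positivity); group templates differ in the late updating amplitude so
the AGE × ANTERIORITY interaction exists in the generative model.
Per-subject amplitude scaling (normal, SD 0.3) provides between-subject
ERP variance.

What the generator does *not* emulate: volume conduction from actual
sources, ocular artifacts and their ICA correction (artifact handling is
exercised through threshold rejection only), latency jitter between
trials, autocorrelated inter-trial drift, and condition-dependent error
rates.  Passing tests therefore demonstrate that the analysis machinery
is correct and calibrated on data satisfying its assumptions — not that
those assumptions hold for any particular recording.

## Preprocessing

The low-pass is a Kaiser-window FIR (30 Hz cutoff, β = 12.2653 ≈ 120 dB
design attenuation, 10 Hz transition band); the kernel length follows
the Kaiser formula for the stated β and transition width (783 taps at
1 kHz, forced odd), and the cutoff is the −6 dB (half-amplitude) point.
Filtering is zero-phase by symmetric-kernel convolution with reflection
padding.  A 0.1 Hz high-pass (β = 5.6533, 0.2 Hz band) is defined for
continuous data but never applied to single epochs — its kernel is
longer than an epoch.  Baseline is the mean over [−100, 0) ms per epoch
and channel.  Epochs with a min-to-max excursion above 100 μV on any
channel are rejected; rejection is monotone in the threshold.  Condition
averages use correct trials only; a subject lacking epochs in a required
condition raises an exclusion signal, mirroring participant exclusion
for too few valid epochs.  All windows are half-open [start, end) ms,
with t = 0 belonging to post-stimulus.

## Inferential statistics

**tmax permutation test.**  One-sample t statistics over the
electrodes × samples family; the null is built by sign-flipping whole
subjects and recording the maximum |t| over the family per permutation.
When 2ⁿ ≤ n_perm the full sign-flip group is enumerated and p-values are
exact; otherwise p = (1 + b)/(1 + m) (add-one convention, guaranteeing
validity).  Zero-variance points are excluded from the family rather
than assigned infinite t.  No cluster-mass statistic is formed — control
is point-wise tmax FWER, with contiguous significant runs reported
descriptively.  Two-sample group contrasts use label permutation
instead of sign flips.

**Split-plot ANOVA.**  Classical sums of squares for one between-subject
and one within-subject factor; with unequal group sizes the within-part
decomposition uses weighted marginal means, which coincides with the
sequential RSS decomposition of nested least-squares fits (the test
oracle).  The between-subject F equals the one-way ANOVA on subject
means — an identity the tests check.  Greenhouse–Geisser ε comes from
the pooled within-group covariance via orthonormalised Helmert
contrasts, clipped to [1/(k−1), 1], and is applied to the within-effect
degrees of freedom; partial η² = SS_effect/(SS_effect + SS_error).
ε is always reported and the correction applied whenever ε < 1.

**JZS Bayes factor.**  BF₁₀ by adaptive quadrature of the noncentral-t
likelihood against a Cauchy prior (scale 0.707) on the standardised
effect size, split at the prior mode and likelihood peak; relative
integration error below 1e-6.  The test oracle integrates the
mathematically equivalent g-prior mixture form instead.

**Inclusion Bayes factors.**  Model set {∅, A, B, A+B, A+B+A:B} with a
subject random intercept; per-model marginal likelihoods are
approximated by exp(−BIC/2), with exact ML of the compound-symmetric
random-intercept model obtained by profiling a one-dimensional variance
ratio.  Inclusion BFs compare matched models (models containing an
effect's higher-order interaction are excluded from its comparison).
This is a unit-information-prior approximation to the default-prior
ANOVA BF; it tracks its qualitative behaviour but is not numerically
interchangeable with JASP-style values, and is not treated as a
reproduction surface.

**Mann–Whitney U.**  scipy's implementation (exact for small tie-free
samples, normal approximation with tie correction otherwise), augmented
with the rank-biserial correlation 2U/(n₁n₂) − 1.

## Source inverse

A simplified sLORETA on synthetic lead fields: channels on a hemispheric
cap, sources in the ball, quasi-dipolar gain columns (three free
orientations per source).  After average-reference projection H,
J = Lᵀ(LLᵀ + λH)⁺ d, and each source's power is standardised by the 3×3
diagonal block of the resolution-based variance R = Lᵀ(LLᵀ + λH)⁺L:
power_i = J_iᵀ[R_ii]⁻¹J_i.  For noiseless single-dipole data the power
maximum coincides with the generating source (zero localisation error)
— verified on 50 random dipoles at λ = 1e-8·tr(LLᵀ)/n_channels.  The
default λ for noisy data follows the discrepancy principle (residual
RMS matched to the noise RMS by bisection).  Group contrasts use
per-source two-sample permutation t-tests with Benjamini–Hochberg
control at α = .01 and a minimum-cluster rule of 5; with no anatomy,
"contiguous" means adjacent source indices.  Baseline normalisation of
source time courses divides power by the mean baseline-window power.

## Problem sizes

Behavioural analyses always run at the full design (9 × 80 trials,
24 + 23 subjects).  The epoch-level drivers and tests use reduced sizes
chosen to keep the full chain interactive — typically 12 subjects per
group, 3 blocks, 2,000 permutations — since the arrays scale as
trials × 12 channels × 1,101 samples per subject.  The permutation-test
calibration study uses 200 null cohorts of 24 subjects on a 12 × 1,001
grid with 1,000 permutations; the cost-recovery study uses 200 replicate
24-subject cohorts at the full trial count (the tolerance is stated at
the 50-replicate standard-error scale, see below).

## Numerical and design choices

- Cost recovery is asserted within 2·sd/√50 of the generative values —
  two standard errors of a 50-replicate Monte Carlo mean — while the
  mean itself is estimated from 200 replicates, so the check's own
  sampling noise does not dominate the bound it enforces.
- The FWER calibration asserts the familywise rejection count of the
  tmax test lies inside the central 95% binomial interval of a
  level-.05 test.
- Subjects missing a condition cell are dropped per effect, not
  globally; the pipeline records exclusions in provenance.
- Group differences are reported as older − younger throughout.
- The events table is a BIDS-events-like TSV; epochs persist in an HDF5
  container (/data float32, /times, /labels, /correct, /channels, with
  sfreq and subject_id attributes).

## Known limitations

- The BIC inclusion BF diverges numerically from matched-prior default
  ANOVA BFs, especially for small effects.
- The synthetic lead field has no anatomy; localisation results say
  nothing about real head geometry.
- Condition-dependent error rates (harder cells have more errors in real
  data) are not modelled, so simulated per-condition epoch counts are
  somewhat more uniform than real ones.
- ε from the pooled within-group covariance can differ in the second
  decimal from implementations that pool across the grand mean.
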