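# Methods

## The scientific problem

Touch produced by one's own movement feels weaker than identical touch
applied externally: the motor system's internal forward model predicts the
sensory consequences of a movement, and predicted input is attenuated.  In
reaching-to-self-touch paradigms this attenuation is temporally tuned — it
deepens as the moving hand approaches the contact — and the precision of
that tuning depends on the sensory input available to update the prediction
during the reach.  The package implements the complete analysis chain of a
two-session (reaching with vision vs. blindfolded) force-discrimination
experiment, plus a synthetic-study generator so every stage can be verified
end-to-end without human data.

## Task and trial model

Each trial delivers two 100 ms force pulses to the pulp of the left index or
ring finger: a *test* force of nominally 2 N and a *comparison* force drawn
from seven intensities (1, 1.5, 1.75, 2, 2.25, 2.5, 3 N), the comparison
1200 ms after the test.  The participant reports which felt stronger
(2AFC).  A session holds 56 baseline trials (hands at rest, test 100 ms
after trial onset) and 280 reaching trials in four groups of 70: the test
force is scheduled at 25, 50 or 75% of the mean movement time of the last
five reaching trials, or triggered by the terminal tap on the target force
sensor (*target* trials, ~20 ms system latency).  Instructed reach targets
(index/ring) are balanced within each group (35/35).

## Observer model

Responses follow a logistic psychometric function
`P(comparison stronger | x) = 1/(1 + exp(-(b0 + b1 x)))` with
`PSE = -b0/b1` and `JND = ln(3)/b1` (natural log: the 0.5→0.75 probability
step equals a log-odds step of ln 3).  Attenuation enters as a linear drift
of the effective PSE with the trial's movement-time fraction `f` (percent of
movement duration at test-force onset):

    PSE(f) = baseline_pse + intercept + slope * f

Baseline trials use `baseline_pse` alone.  An optional lapse rate mixes in
stimulus-independent guessing; it defaults to 0 (the fitted model has no
lapse parameter, so simulated lapses act as a robustness stressor only).
The generator evaluates `f` on the same definition the analysis uses —
velocity-threshold onset to force-threshold offset — so that recovery tests
compare like with like.

## Reach simulation

Reaches are minimum-jerk transports `s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5`
over ~25 cm (peak speed 1.875 d/T at mid-movement) with a small vertical
arc, Gaussian endpoint noise (per-axis SD 0.1 cm with vision, 0.4 cm
without; offset norm clipped at 3 SD so endpoints stay near the sensor), and
Gaussian movement-duration jitter (within-participant SD 80 ms around a
participant tempo of ~1 s shared between sessions, since the study trains
participants to move identically with and without vision).  Force channels
carry the event structure the detectors rely on: the start-sensor hold force
drops below 0.2 N at movement start, the target sensor shows an 80 ms
half-sine tap pulse (peak 3 N), and the probe channel carries the test and
comparison pulses with 0.05 N amplitude noise.  Human features *not*
emulated: online corrections, submovements, asymmetric velocity profiles,
endpoint drift and fatigue.  Passing tests therefore demonstrate the
correctness of the analysis chain on data satisfying its assumptions, not
robustness to every idiosyncrasy of real reaches.

The population model links the two sessions per participant: baseline PSE
(~N(2, 0.15) N), JND (lognormal around 0.25 N) and movement tempo are
shared; attenuation slopes average -2.512e-3 N/% with vision and
-1.101e-3 N/% without (between-subject SD ~3.2e-3, partly shared across
sessions); intercepts average -0.054 vs -0.150 N.  A participant's no-vision
endpoint noise is coupled positively to their no-vision slope and negatively
to their intercept, producing the slope-variability and
intercept-variability partial correlations the analysis is designed to
detect.  Slope/intercept means and spreads follow the reported group
statistics; endpoint-noise levels and the coupling strengths are generator
choices made once for plausibility.

## Kinematic analysis

* Positions smoothed by a centered 5-point moving average (~21 ms at
  240 Hz); edge samples average the available in-window samples; forces are
  never smoothed.
* 3D speed: Euclidean norm of central finite differences (one-sided at the
  trace ends).
* Onset: first sample whose speed strictly exceeds 5 cm/s at every sample of
  the next 100 ms (24 samples; the boundary sample is included — a
  conservative reading of "for the next 100 ms").
* Offset: first sample where the instructed finger's sensor force strictly
  exceeds 0.2 N.
* Peak velocity: maximum speed within the first 67% of the movement, which
  captures the transport peak and excludes the terminal tap transient.
* Endpoints are expressed relative to the position at trial onset; endpoint
  variability is `sqrt(var_x + var_y + var_z)` (sample variances, n-1) per
  target finger, averaged over the two fingers.  The root-total-variance
  reading of "SD of the 3D position" was chosen over averaging per-axis SDs;
  it is the Euclidean dispersion and is invariant to axis rotation.

## Trial filtering

Rules fire in a fixed order a→e and a trial is logged under the first rule
that fires (precedence affects only the audit log, never the kept set):
(a) measured test force outside [1.85, 2.15] N (strict inequalities, so the
boundary values survive); (b) any baseline-trial speed sample above the
5 cm/s onset threshold; (c) zero, multiple, or both-sensor presses;
(d) movement-conduct failures — a speed dip below 1 cm/s longer than 150 ms
between onset and offset, any supra-threshold motion during the comparison
pulse, or a horizontal retreat of more than 5 cm before the comparison;
(e) a timed (non-target) trial whose test fraction is ≤ 12.5% or > 87.5%.
The conduct sub-rules operationalize qualitative instructions; their
thresholds are config-exposed rather than claimed faithful.  Surviving timed
trials are rebinned by realized fraction into (12.5, 37.5], (37.5, 62.5],
(62.5, 87.5]; target trials keep their label (their fraction can exceed
100% by the tap-trigger latency, which is left uncorrected).  Measured
comparison forces are rebinned to the nearest grid intensity before
fitting, ties breaking toward the lower intensity (deterministic;
measure-zero on continuous data).

## Psychometric fitting

Maximum likelihood by Newton-Raphson on the exact gradient/Hessian
(gradient max-norm < 1e-8, 100 iterations, Newton steps damped to max-norm
20), success coded as "comparison stronger".  Quasi-separation (|b1| > 50
logits/N, i.e. a fitted JND below ~0.02 N) and degenerate inputs return a
non-converged fit with finite log-likelihood rather than raising, so the
exclusion gate handles them uniformly: a participant is dropped when any
trial-group cell has McFadden R² = 1 − ll_model/ll_null < 0.2 or a
non-converged fit.  Responses are pooled across press locations within each
group.  Normalized PSEs subtract the same-session baseline PSE.

## Statistics

* Per-participant OLS of normalized PSE on the group's mean realized test
  fraction (target trials at their realized, tap-synchronous fraction);
  participant-sessions with fewer than 3 points are excluded from slope
  tests.  Mean fractions use final (rebinned) group membership.
* Paired comparisons: Shapiro-Wilk on the differences at alpha = .05 gates
  paired t (Cohen's d = mean/SD of differences, t-based CI) vs. Wilcoxon
  signed-rank (zero differences dropped; exact null distribution for
  n ≤ 25, continuity-corrected normal approximation above — the design's
  n = 28 lands in the approximation regime; matched-pairs rank-biserial
  (T+ − T−)/(T+ + T−); Hodges-Lehmann pseudomedian CI from Walsh averages).
* Benjamini-Hochberg step-up FDR within each comparison family.
* Repeated-measures ANOVA (one- and two-way fully within) via orthonormal
  contrast scores: SS_effect = n·||mean score||², error = within-subject
  score scatter.  Greenhouse-Geisser epsilon from the score covariance;
  epsilon-corrected dfs applied when Mauchly's test rejects sphericity at
  .05 (the correction gate is a choice; the epsilon is always reported).
  Effect size: partial eta² = SS_effect/(SS_effect + SS_error).
* Correlations: Pearson (or Kendall's tau for non-normal data); partial
  correlation by residualizing both variables on the covariate, p from the
  t transform with n − 3 df.  A covariate that fully explains a variable
  yields a partial correlation of 0 by convention; a constant covariate
  falls back to the simple correlation with a warning.

## Numerical and design notes

* All randomness flows through counter-based `SeedSequence` keys
  (seed, session, participant, trial), so any trial is reproducible in
  isolation and whole runs are byte-identical under a fixed config.
* "Movement time of the last five reaching trials" is the arithmetic mean of
  the last five online durations (release-to-tap); an empty history (first
  reaching trials) falls back to the generator's mean duration.
* The scheduled test fractions are defined online (from start-sensor
  release), while the analysis re-references them to the kinematic
  (velocity) onset; realized fractions therefore sit slightly below the
  scheduled 25/50/75%, exactly as in the histograms of realized times this
  design produces, and duration jitter makes offline rebinning reassign a
  few percent of timed trials.
* Problem sizes in the verification suites — 28 participants for the
  end-to-end study, 200 observers for recovery, 2000 replicates for the
  ANOVA calibration — were chosen to give stable estimates at interactive
  runtimes.

## Known limitations

* The generator's trial rejection rate (~1-2%) is lower than in human data;
  rules (b)-(d) are exercised by targeted unit fixtures rather than by the
  default simulation, which moves too cleanly to trigger them.
* Bayes-factor analyses of the original design are out of scope.
* The Wilcoxon p-value above n = 25 and the Mauchly chi-square are
  approximations; cross-checks against an independent implementation agree
  to ~1e-6 on shared exact paths and to a few percent where the
  approximations differ.
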