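# Methods notes

## Simulated observers

### Rise-time discrimination (3AFC)

The observer's probability of picking the deviant with rise time x (ms)
against the 15 ms reference is

p(x) = 1/3 + (2/3) · F(u),  u = log(x / 15),

with F a monotone sigmoid on the log rise-time axis. Two anchors are
imposed: F(0) = 0 (a deviant identical to the reference is at 3AFC
chance) and F(u₇₀₇) = 0.5605 so that p equals exactly 0.707 at the
observer's threshold parameter x₇₀₇. A plain shifted logistic cannot
satisfy both anchors with a free width, so F is a logistic renormalised
at the reference; in closed form

F(u) = (e^{u/w} − 1) / (e^{u/w} + K),  K = (e^{u₇₀₇/w}(1 − c) − 1)/c,

with c = 0.5605 and w the width on the log axis. K > 0 requires
u₇₀₇/w > log(1/(1 − c)) ≈ 0.822; the cohort generator clips sampled
widths to 95% of this bound (and keeps x₇₀₇ at least one ladder quantum
above the reference), so every generated observer is valid by
construction.

### Phoneme identification (2AFC)

ψ(x) = γ + (1 − γ − λ)·S((x − m)/w) on the 10-step continuum index, S
the standard logistic (a cumulative-normal option exists). γ is the
guess rate (lower asymptote), λ the lapse rate (1 − upper asymptote).

### Cohort generator defaults

Defaults encode the study conditions the analyses assume: 23 controls
and 29 patients; log thresholds Normal(log 40 ms, 0.35) for controls and
Normal(log 80 ms, 0.65) for the aphasia group; identification widths
Normal(1.2, 0.15) vs Normal(3.0, 1.2) continuum steps, with guess rates
uniform on [0, 0.08] (controls) vs [0, 0.30] (aphasia) and lapse rates
on [0, 0.04] vs [0, 0.10]; matched hearing (Fletcher index
Normal(32, 9) dB HL in both groups) and a lower cognition composite in
the aphasia group (Normal(−1.5, 1) vs Normal(0, 1)). Phonology
(ScreeLing subtest, 0–24) is intercept 32 − 2.70·log x₇₀₇ +
0.5·cognition + Normal(0, 2.5), clipped to [0, 24]; the −2.70 slope is
the generating brain–behavior link the within-aphasia regression is
expected to recover. Word fluency has no generating task link (matching
the null finding the fluency models test against). Task-incompletion
probabilities default to 6/29 (staircase) and 3/29 (identification) for
patients, 0 for controls. Where the source material gives no numeric
group parameters (thresholds and widths are shown only graphically),
values were fixed once at magnitudes typical for elderly listeners and
never revisited.

## Staircase

1-up/2-down on the 50-level geometric ladder (entry k =
699·(16/699)^((k−1)/49) ms). Choices that the task description leaves
open, fixed here: runs start at the easiest level; moves are one ladder
step; a reversal is logged when the realized movement direction flips
(clamped moves that do not change the level are not movement); runs with
fewer than 4 reversals are invalid and flagged "task not completed";
the 87-trial cap applies unconditionally. The threshold averages the
deviant rise times of the last 4 reversals in ms.

Targeting: the 2-down/1-up equilibrium is p² = ½, i.e. 70.7% correct.
The convergence validation (500 runs) uses a steep probe observer
(x₇₀₇ = 100 ms, w = 0.05): for a steep function the percent correct at
the mean threshold isolates the staircase's targeting property. With
realistic shallower observers the design itself — only 8 reversals,
starting from the easiest level — biases measured thresholds toward the
easy side (the first reversals happen during the initial descent); the
simulator reproduces this property of the task, and it is why measured
thresholds are treated as scores rather than unbiased estimates of
x₇₀₇.

## Psychometric fitting

Deterministic dense-grid posterior evaluation (no sampling, no seed):
binomial likelihood, uniform priors, default grid 25 × 25 × 24 × 11 over
midpoint ∈ [0, 11], width ∈ [0.25, 10] (log-spaced), γ ∈ [0, 0.89],
λ ∈ [0, 0.1], followed by two zoom refinements of the box around the
mode (point estimate = posterior mode). Asymptote intervals are 95%
equal-tailed marginal credible intervals read from the full-prior coarse
grid by linear interpolation of the cumulative marginal. The width floor
of 0.25 steps reflects that a transition sharper than a quarter step is
not resolvable on a 10-step continuum; without it, step-like data drive
the width to an arbitrary floor and the 50%-point slope diverges.

The 50% point is where the full ψ (including γ, λ) equals 0.5 — for
retained participants the QC rule guarantees 0.5 lies strictly between
the asymptotes. Slope there has the closed form (1 − γ − λ)·s₀(1 − s₀)/w
with s₀ = (0.5 − γ)/(1 − γ − λ). The exclusion rule is closed at the
boundary: an interval endpoint exactly at 0.5 excludes.

With 8 repetitions per step, subject-level slope estimates are noisy
(SD of the estimate is comparable to the control-group mean slope
divided by 3). Two consequences in the simulation: the control norm for
the deviance analysis is wider than the latent slope distribution, so
patient-level deviance on the identification task is less sensitive
than on the RTD task; and group comparisons on slopes remain powerful
because averaging defeats the noise. Passing tests therefore show the
machinery is correct under the stated design, not that 80 trials
suffice for precise single-subject slopes.

## Deviance analysis

Trim count is ceil(0.05·n) (rule configurable): n = 23 controls → 2
removed, n = 21. z-scores use the trimmed norm's mean and sample SD
(n − 1); classification is strict ("exceeds" 1.65 SD) in the worse
direction per task; RTD scores enter on the natural-log scale. Because
the norm is built from a 5%-trimmed sample, its mean and SD are those of
a truncated normal; under normality the control flag rate implied by the
procedure is ≈ 8.4%, not the naive 4.95% tail — the calibration test
checks the empirical rate against this truncated-normal value. Union and
overlap proportions are computed over patients with at least one (resp.
both) valid task scores, so missing-data denominators differ per
statistic.

## Statistics

Welch's t (unequal variances) is the parametric default; the gate is a
per-group Shapiro-Wilk at α = 0.05. The rank-sum test uses the
first-sample Mann-Whitney U with exact small-sample p-values (tie-free)
and mid-rank normal approximation otherwise. Per-term tests in the
linear models are marginal (Type-II) F tests. The smooth-hearing model
is a Gaussian GAM with a 6-df cubic B-spline for hearing; the penalty
weight is selected by the fitter's AIC-based search (falling back to a
fixed weight of 1 if the search fails), the smooth's test is a joint
Wald F over its coefficients, and its effective df is reported. The
adjusted R² of the smooth model uses total effective df. FDR adjustment
is Benjamini-Hochberg step-up.

## Cohort table

The packaged CSV transcribes the published 29-row table (demographics,
lesion information, naming and ScreeLing scores). Cut-off semantics are
strict "below" (score = cut-off is not below), which reproduces the
printed counts (17 below each cut-off, 20 below at least one). Sample
SDs use n − 1 throughout. Two transcription notes: one row's naming and
ScreeLing scores are printed run together ("328"); the split 32/8 is the
only one consistent with both printed cut-off totals. The printed
time-since-stroke median is 18 while the column's median computes to
18.2, and the printed age SD is 12.15 while the column computes 12.156
(the source presumably used unrounded ages); the table is authoritative
for all recomputation, and the discrepancies are recorded here rather
than "fixed".

## Problem sizes

Default validation sizes — 500 staircases for the convergence check, 100
replicates at 200 reps/step for psychometric parameter recovery, 1000
synthetic controls for deviance calibration, 1000 randomized runs for
reversal bookkeeping — were chosen so each Monte-Carlo error is well
below the tolerance it is compared against.

## Known limitations

- The simulator models neither reaction times, attention drift beyond
  the lapse parameter, nor stimulus-level acoustics (stimulus synthesis
  is provided for completeness, not used by the analyses).
- Generator group parameters for the tasks are plausible magnitudes, not
  published values; analyses that depend on them (e.g. deviance
  percentages) are validated as properties, not as numeric matches.
- The GAM penalty search on small samples can be unstable; the fallback
  fixed penalty makes the fit deterministic but slightly smoother than
  optimal.
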