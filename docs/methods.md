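# Methods

This note documents the generative and statistical models implemented in
`psyflex`, the defaults and why they were chosen, what the synthetic data do
and do not emulate, and the numerical choices that affect results.

## Paradigm designs

All three generators sample trial sequences by *constrained sequential
composition*: interval-bounded segment or gap lengths are drawn one at a
time, uniformly over the values that keep the remaining budget feasible, so
every generated design satisfies its count constraints exactly and an
infeasible configuration fails fast with the violated bound named.

**Cognitive (oddball switching).** Two runs of 150 trials; 80% single-digit
baseline trials (parity judgment, left hand), the rest split evenly into
switch (magnitude judgment, right hand), distractor, and ambiguous trials.
Each critical trial is followed by 3–6 baseline trials — including the last
one of a run, so gap counts are invariant across seeds. A run may open with
a 0–6-trial baseline lead-in. Digits are drawn from 1–9 excluding 5 with the
response-relevant category (odd/even or </> 5) balanced within condition per
run; the paradigm specifies only "pseudo-random" ordering, so balancing is a
package choice. Ambiguity is modelled categorically (an `ambiguous` cue
value), not as a pixel offset: whether the physical jitter is decodable is
irrelevant to the analyses, which only need the trial class.

**Affective (position-cued switching).** One run of 240 trials alternating
gender- and emotion-task segments of 3–7 trials. Segment counts are solved
so each task receives exactly 120 trials in 25 + 24 alternating segments,
which forces the published totals: 24 switch (first trial of each
non-initial segment) and 96 repeat trials per task. The initial segment is
all-repeat — the printed totals (48 + 192 = 240) leave no other
classification. Stimuli are abstract face descriptors (120 identities × 2
valences), each used exactly once per run.

**Feedback (uninstructed reversal).** 109 trials, 10 reversals, segment
lengths 6–15. A probabilistic error (negative feedback after a correct
response) is placed in `round(0.2 × eligible)` segments, where a segment is
eligible if it has any allowed position: never the first four trials after a
reversal, never the trial before the next reversal, hence never in a
length-6 segment. All 11 segments (including lead-in and tail) count as
candidate sequences, since the placement rule applies to them identically.
ITIs are uniform integers in 1,000–6,000 ms. Four pre-generated sequence
variants (seeds 1–4) stand in for the study's four counterbalanced
sequences; assignment logistics beyond round-robin are not modelled.

Onsets are cumulative trial durations (plus ITIs for the feedback task);
non-trial lead-in screens that pad the printed session durations are not
modelled.

## Participant simulator

The simulator is an explicit stand-in: the source analyses consume only
trial-level RT/accuracy logs, and no trial-level behavioral model is
prescribed, so the parametric forms below are package choices and make no
claim about the underlying cognition.

**Between-subject structure.** Every trait is generated as
`μ + σ(λη + √(1−λ²)u)` with η (latent flexibility) and u independent
standard normals, then clipped to its admissible range. The five study
indicators default to the loadings the study's factor analysis estimated
(.58 cognitive RT cost, .06 switch rate, .72/.97 affective RT costs, .08
reversal errors); all other traits default to λ = 0. Trait means and SDs for
RT cells are the published condition descriptives (e.g. baseline 687.96 ±
87.93 ms, RT switch cost 335.60 ± 132.39 ms). Error-rate trait means are
stored as *pre-truncation* Gaussian locations (e.g. .0386 for the cognitive
baseline) solved once so that the truncated, floor-at-zero condition error
rates reproduce the published cell means (.04/.11/.20 cognitive, .08/.16
emotion, .06/.07 gender) — flooring probabilities at zero would otherwise
inflate the small cells by up to ~17%. Distractor-condition costs (100 ms,
+.01 ER) are free choices; the study tabulates no distractor statistics.

**Within-subject behavior.** RTs are log-normal with subject/condition mean
μ and log-scale SD 0.20 (a typical RT coefficient of variation; it yields
split-half reliabilities for RT costs in the published .7–.9 range). Draws
beyond the response window (2,000 ms cue-based, 1,500 ms feedback task)
become omissions in the cue-based tasks — counted as errors with missing RT,
keeping the accuracy denominator at the trial count — and are clipped in the
feedback task, whose state machine needs a response every trial. Accuracy is
Bernoulli per condition; ambiguous trials use the switch hand with
probability θ (the switch-propensity trait). `lapse_rate` and
`omission_rate` default to 0 because the per-condition error probabilities
already carry the published total error rates; a separate lapse channel
would double-count.

**Feedback-task cognition** is a two-state win-stay/lose-shift rule
follower, not a reinforcement-learning model — the simplest mechanism that
reproduces the published 1–3.2 reversal-error range. After negative
feedback the internal rule switches with probability `q`; on the first
post-reversal error the subject stays with probability `perseveration`
(default 0); positive feedback never triggers a switch. A probabilistic
error can trigger an unwarranted switch with probability `q`, and the next
negative feedback restores the correct rule. With perseveration 0 the
expected error count per reversal is `1/q`, so each subject's `q` is the
reciprocal of a target mean-reversal-errors trait drawn from N(1.72, .42)
truncated to [1, 4]. Because per-reversal counts are geometric, the
*observed* subject SD exceeds the trait SD (≈ .47 vs .42 at the default 10
reversals); only the mean is a calibration target.

**Seeding.** A master seed drives population sampling; each subject's
behavior uses an independent stream seeded by `(master, subject_id)`, so
per-subject logs are reproducible in isolation and independent of
simulation order.

**What the synthetic data do not emulate.** Practice/fatigue and
training-run effects, sequential RT dependencies (post-error slowing,
congruency), stimulus-identity effects, response-button structure within a
hand, and any non-Gaussian trait distributions. Passing tests therefore
show that the *pipeline* recovers known structure from data of this form —
not that real data satisfy these forms.

## Preprocessing and indices

Order: 250 ms floor → single-pass subject-and-condition mean + 3 SD upper
trim (mean/SD from the ≥ 250 ms trials; the rule is stated once in the
source protocol, so it is deliberately not re-iterated — note a second
application would trim slightly more, the rule is not mathematically
idempotent) → error-trial removal for RT analyses only. The trim is
upper-tail only. Exclusion error rates always come from the untrimmed log;
a subject-condition cell with ER > .30 (strictly) is excluded from every
analysis involving that cell, and a subject who never switched hands in the
feedback run is excluded from feedback indices. Cells with fewer than two
valid RTs keep their trials (SD undefined) with a warning.

Switch costs are mean differences (switch − baseline; affective costs use
the target task's repetition trials). The switch rate counts switch-hand
responses over responded-to ambiguous trials, omissions excluded from both
numerator and denominator. Reversal errors are counted from the first
post-reversal trial to the first new-rule-consistent response; a later
relapse does not reopen the count, and errors after probabilistic errors are
not reversal errors. Baseline means include every baseline trial (the first
post-critical baseline trial is not treated specially).

## Reliability

Permutation split-half: per iteration each subject's trials per condition
are randomly halved (odd counts give split 1 the extra trial), the index is
computed per half, halves are correlated across subjects (Pearson,
regardless of normality — the referenced procedure's default), the
Spearman–Brown correction is applied *per iteration*, and the estimate and
95% CI are the mean and 2.5/97.5 percentiles of the 5,000-iteration
distribution. The feedback index shuffles each subject's 10 per-reversal
error counts and splits 5/5. The switch rate uses a single deterministic
first-half vs second-half count correlation with a Fisher-z CI (no
permutation distribution exists to take percentiles from, and no
Spearman–Brown correction is reported): random splits of serially dependent
binary switch/stay data can misstate the generative reliability, which the
test suite demonstrates with blocked responses.

## Inference battery

Repeated-measures ANOVAs (one-way and 2×2 within) report partial eta
squared recovered as `F·df1/(F·df1+df2)`. Hedges' g is the bias-corrected
standardized mean of the pair differences (`mean(d)/sd(d) × (1−3/(4df−1))`).
Correlation method per pair is gated by Shapiro–Wilk at α = .05 on each
variable (either non-normal → Spearman). One-sided p-values follow the
pre-declared direction; CIs are Fisher-z (Spearman variant uses the
Fieller-corrected variance 1.06/(n−3); the source does not state its CI
method). Bonferroni control is applied as adjusted α thresholds per
hypothesis family, with the family composition: H1 (three RT-level tests,
α/3), H1b, H3a, H3b, H5 (two tests each, α/2), H2 (three tests, α/3) — the
source prints only the family sizes, so the exact membership is this
package's codification. Dependent overlapping correlations are compared
with the Hotelling–Williams t (df = n−3). Partial correlations are
residual-based (on ranks for Spearman) with df = n−3. Sphericity correction
defaults to off; the ANOVA wrapper exposes the underlying engine's
Greenhouse–Geisser option for users who want it.

## Factor model

One factor, unit factor variance (so loadings are standardized — matching
how loadings are reported, rather than a marker-indicator scale), diagonal
uniquenesses bounded at zero (a bound hit is flagged as a Heywood case).
Indicators are z-standardized; incomplete rows are dropped listwise (the
source does not state its missing-data treatment). The ML discrepancy is
minimized with L-BFGS-B from a first-principal-component start; chi-square
is `(n−1)F_min` on `p(p+1)/2 − 2p` df; SEs come from the inverse observed
information `2/(n−1)·H⁻¹` with a numerically differenced Hessian. CFI/TLI
use the independence baseline `−(n−1)ln|R|`; RMSEA and its 90% CI invert
the non-central chi-square CDF. The optional MLM estimator divides the
chi-square by the Satorra–Bentler mean-scaling factor `tr(UΓ)/df`, with Γ
the fourth-moment (ADF) covariance of the sample covariances and U the
normal-theory residual weight matrix; the baseline statistic is scaled with
its own factor before robust CFI/TLI/RMSEA. Scaling conventions differ
slightly across software; this package's tests verify the defining property
E[T_ML] ≈ c·df on elliptical data instead of matching any one program.
KMO uses the anti-image partial-correlation matrix; Bartlett's statistic is
`−(n−1−(2p+5)/6)ln|R|`; Mardia's skewness/kurtosis use the standard
asymptotic χ²/normal references. The optional bootstrap KMO CI is a plain
percentile bootstrap and is this package's own construction.

## Problem sizes and determinism

Fixed seeds make every simulation-based test deterministic. The test suite
uses 40 subjects for pipeline checks, 2,000 for parameter-recovery and
calibration checks (group means within 10% of the published descriptives;
index-vs-trait correlations ≥ .9), 10 × 500 subjects (chunked to bound
memory) for the λλᵀ-recovery check, and 200 replicate studies of n = 100
for the type-I-error calibration of the battery. The λλᵀ check runs with a
low-measurement-noise configuration (RT noise 0.05, four cognitive runs,
100 reversals): with the default 10 reversals the reversal-error index has
reliability ≈ .6, and attenuation alone (~.10) would mask the ±.05 latent
structure being verified — the check is about the simulator/indices chain,
not the default study's power. Enumeration oracles for the split-half
estimators use 3–4 subjects with 2–4 trials per cell, small enough to
enumerate every split exactly.

## Known limitations

- The behavioral model is deliberately minimal; fitting it to real data is
  out of scope, and its parameter estimates have no empirical status.
- The single-factor CFA handles only complete cases; no FIML.
- The MLM scaling follows the formula documented above; third-party
  programs may print slightly different scaled statistics.
- Counterbalancing is reduced to four seeded sequence variants assigned
  round-robin.
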