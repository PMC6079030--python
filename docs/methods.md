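# Methods

## Task structure and design generation

The reciprocal evaluation task presents 75 trials: every combination of 3
feedback valences (negative/neutral/positive) and 5 objective-creativity
(OC) levels occurs exactly 5 times. Two ordering constraints are enforced:
no more than 2 consecutive trials of the same (valence, OC) condition, and
the running sum of valence codes (−1/0/+1) stays within ±3. The second
constraint is what keeps the accumulated-feedback regressor inside [−1, 1]
after rescaling by 3, and it is treated as a generation constraint with a
configurable bound. The original study used a single fixed pseudorandom
sequence which is not published; the generator reproduces the stated
constraints instead, via randomized greedy sequential construction with
restarts (budget 10,000 — in practice a valid 75-trial sequence is found in
the first handful of attempts). A `fixed_sequence` slot in `DesignSpec`
accepts an explicit ordering when one is available. The 20/5 split of
neutral trials into "not yet evaluated" / "no response" cover-story
subtypes is assigned at random among neutral trials; the two subtypes are
analytically identical.

The run-length rule is applied to the full (valence, OC) condition pair,
not to valence alone; only the pair rule is stated for the task.

## Predictors

- `cfb`: −1 / 0 / +1 for negative / neutral / positive feedback.
- `accfb(t)` = (sum of cfb over trials 1..t−1) / bound, bound = 3;
  `accfb(1)` = 0. Division by the design bound (rather than per-participant
  min–max) is used because all participants see sequences respecting the
  same bound; sequences that exceed it raise a warning, not an error.
- `oc` = (level − 3)/2, mapping 1..5 onto −1..+1.

No mean-centering is applied to behavioral predictors.

## Feedback-influence model

Per participant, a binomial logit of the binary partner evaluation on
(cfb, accfb, oc, intercept), fit by Newton–Raphson to a log-likelihood
tolerance of 1e-8 (max 100 iterations). Participants with uniform or
near-uniform button presses are excluded first; the near-uniform rule is a
minority class below 3 responses (configurable) — 3 being the minimum that
gives any leverage on three slopes. The original exclusion rule is not
stated precisely; this threshold is a stand-in, not a claim about it.

Quasi-complete separation (possible for agents that deterministically
mirror feedback) is detected by divergent coefficients or non-convergence;
the fit then falls back to a Jeffreys-penalized (Firth) likelihood and is
flagged, rather than returning divergent estimates. Rank-deficient designs
(e.g. all-neutral sequences) are flagged and solved by pseudoinverse.

The Newton core is cross-checked in the tests against statsmodels' Logit
and against brute-force dense-grid likelihood maximization on small
instances.

## Self-protection RL model

Feedback is reverse-coded (negative → +1) so that negative evaluation
raises the value of self-protection. VSP starts at 0 and follows the delta
rule; equivalently VSP_t is the exponentially weighted sum of past
feedback with weights (1−α)^(t−i)·α. Neutral feedback contributes FB = 0,
so VSP decays toward 0 by the factor (1−α) on neutral trials — the update
rule taken literally.

The decision at trial t uses VSP updated through the current trial's
feedback (VSP_t), matching the event pairing of the evaluation phase;
`vsp_timing="previous"` switches to VSP_{t−1} for sensitivity analysis.
OC enters the policy on the rescaled −1..+1 coding, consistent with the
feedback-influence model (this affects only the scale of β_OC).

α is estimated by profiling: at each grid α the three policy weights are
refit by full MLE and the maximized log-likelihood is recorded; the grid α
with the highest value wins, ties broken toward smaller α (deterministic).
The reference grid is exhaustive with step 0.0001; the default
`two_stage` method pre-scans at 0.01 and refines the winning ±0.01 window
at 0.0001 on the same lattice, which the tests show reproduces the
exhaustive argmax on this model's profiles. A flat profile
(max − min < 1e-6 over the grid) is reported as α = 0 and flagged
non-identifiable. Fits with β_VSP > 0 ("violators" — favorable evaluation
under high VSP, contradicting the self-protection assumption) are flagged
and excluded from group analyses; the sign rule operationalizes the
described exclusion, whose exact original criterion is not stated.

### Identifiability at 75 trials

Parameter-recovery simulation (the acceptance experiments) shows that with
all three policy weights free, α recovery at β_VSP = −3 is unbiased on
average (|bias| ≈ 0.04 at the grid MLE for α = 0.3, 200 agents) but noisy
per participant: weak-signal realizations produce near-flat profiles
(log-likelihood range < 1) and occasional boundary estimates, giving a
per-agent Spearman(true α, α̂) around 0.65–0.8 depending on the design
realization. The recovery *curve* — per-α mean estimates — is cleanly
monotone (Spearman ≈ 0.93–0.96), and recovery sharpens with |β_VSP|
(≈ 0.9 per-agent at β_VSP = −5) or when the policy weights are known.
This is an inherent small-sample property of the profile MLE, worth
keeping in mind when interpreting individual-level α estimates from 75
trials.

## VSP-conditioned bias analysis

Per participant, fitted decision probabilities from the RL policy are
averaged within VSP > 0 and VSP < 0 trial sets (VSP = 0 trials belong to
neither; an empty set is reported as missing). Group-level one-sample
Wilcoxon signed-rank tests compare each set's means against chance (0.5)
and a paired test compares the sets.

## Group statistics

All tests are two-tailed. Age regressions report the OLS slope with the
F-statistic of the age term. The bootstrap regression is case-resampling
of the OLS slope (default 5000 resamples, percentile CI, seed mandatory);
significance means the CI excludes 0. The ANCOVA fits
estimate ~ type + age + type×age on the long table of per-participant
influence estimates and F-tests the interaction; the within-participant
pairing of the two rows is deliberately ignored (replicating the original
analysis); a paired variant can be built from the same table but is not
the default. Wilcoxon signed-rank uses exact enumeration up to n = 25
non-tied values and the continuity-corrected normal approximation above,
dropping exact ties (standard convention), and reports median and IQR.
Spearman uses mid-ranks; Shapiro–Wilk (3 ≤ n ≤ 5000) gates the
nonparametric branch.

## Mediation

Single-mediator path model estimated by two OLS fits (mediator ~ age;
outcome ~ mediator + age); the indirect effect is a·b and satisfies
c = c′ + a·b exactly. Inference is a case-resampling bootstrap of a·b
(default 5000 samples) with a percentile CI; a bias-corrected CI is
available, since the CI flavor of the original macro-based analysis is
unreported. Variables are analyzed on raw scales with an optional
standardization switch. Before fitting, the mediator is screened by a
single-pass two-sided Grubbs test at the 0.05 level, removing at most one
maximal-deviation point — mirroring the single-outlier removal the
analysis calls for. Note the screen's null removal probability is its
nominal level (~5% on clean Gaussian data); with multiple gross outliers
a single-pass Grubbs can mask, which is out of scope here.

## Synthetic cohorts

No generative model of participants exists beyond the fitted model itself,
so the simulator uses it — the standard parameter-recovery convention:
agents update VSP by the delta rule and decide through the logistic
policy. Defaults: 60 agents, ages uniform on 10–25; α linear in age with
slope −0.029/year (the fitted developmental effect), α = 0.65 at the
reference age 10 (chosen so α spans roughly 0.2–0.65 over the age range
while staying interior to [0, 1]), Gaussian perturbation SD 0.1, clipped
to [0, 1]; policy weights Gaussian with means (β_VSP, β_OC, β_0) =
(−3, 1, 0) and SDs (0.5, 0.3, 0.3) — self-protective agents of realistic
effect size with mild heterogeneity. Mediation triads use n = 56 (the
study's mediation sample size), paths a = 0.5, b = 0.4, c′ = 0, unit
noise SDs, and optional injected outliers of a configurable magnitude.

What the simulator does *not* emulate: reaction times, trial timing,
session effects, within-participant drift in the policy weights, any
non-delta-rule learning, or realistic ROI covariance structure in the
mediation triads. Passing tests therefore establish that the estimators
recover the assumed model and that the statistics are calibrated — not
that real participants follow the model.

## Problem sizes in the validation experiments

The acceptance experiments use 200 agents for fixed-α recovery, 19 α
values × 8 agents for the recovery correlation, a 60-agent cohort for the
developmental dissociation, 5000 replicates per type-I calibration (with
999 bootstrap resamples inside each bootstrap-regression replicate), 500
replicates × 2000 resamples for mediation coverage, and 2000 replicates
for the Grubbs rates — sizes at which the Monte-Carlo error of each
reported rate is well below the band it is checked against, while the full
suite completes in a few minutes on one CPU. Cohort-level RL fits in the
dissociation experiment use the two-stage grid at step 0.001; production
fits default to 0.0001.

## Reproducibility

Every stochastic stage derives its seed from (master seed, stage name) via
SHA-256, so stages are decoupled and reruns are byte-identical. The
pipeline manifest records versions, seeds, per-stage timing, and SHA-256
hashes of every output file.
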