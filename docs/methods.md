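# Methods

## The behavioral protocol being modeled

Each daily session has 12 discrete trials separated by long (10 min)
inter-trial intervals.  Trials 1–4 are *sampling* trials: a single lever
(cocaine or saccharin) is presented alone, each option twice, in alternation;
trials 5–12 are *choice* trials with both levers out.  The response latency is
the time from lever insertion to completion of an FR2 press requirement.  A
rat that fails to respond within 5 min registers an *omission*, recorded at
the 300 s ceiling with no option attributed.  Analyses run on the last three
sessions of a stable choice phase, giving each rat 6 sampling latencies per
option and up to 24 choice latencies split between options according to its
preference (% cocaine choices among completed choice trials; below 33.3% =
saccharin-preferring SP, above 66.6% = cocaine-preferring CP, between = IND,
with the exact thirds assigned to IND).

## Generative regimes

All regimes share one latency law per option: `latency = floor + X`, with
`floor = 3 s` (the empirical reaction-time minimum) and `X` lognormal,
`X = exp(N(mu, sigma))`.  Draws at or above the 300 s cap become omissions.  A
shifted-exponential special case (`X ~ Exp(rate)`) exists solely because the
race then has closed forms (`P(A wins) = rate_A/(rate_A+rate_B)`, recorded
choice latency `~ floor + Exp(rate_A+rate_B)`) used as independent oracles in
the tests.  The lognormal family is a deliberate modeling choice for
right-skewed response latencies; the data constrain only the floor and cap,
not the family.

* **SCM (race)**: on a choice trial each option draws a latent latency from
  its own sampling law; the shorter wins and is recorded.  Selection is
  *cross-censorship*: the recorded distribution for an option keeps only its
  race-winning draws, trimming the right tail — so mean recorded choice
  latency ≤ mean sampling latency, with the gap growing with the overlap of
  the two laws.  Omission iff both latents exceed the cap.
* **DCM (deliberative)**: the chosen option follows a softmax on the value
  difference, `P(cocaine) = 1/(1+exp(−beta·value_gap))`; the recorded latency
  is the chosen option's law draw **plus** an independent lognormal
  deliberation delay (default log-mean 1.0, log-sd 0.5, mean ≈ 3.1 s), so
  choice latencies stochastically exceed sampling latencies.
* **HABIT**: softmax choice with no added delay; per-option choice latencies
  are distributed exactly like sampling latencies.

Sampling trials are regime-independent by construction (one law draw), which
the tests assert stream-for-stream.

## Cohort archetypes and defaults

A cohort mixes three archetypes whose per-rat parameters are drawn uniformly
from ranges:

| archetype | mu_cocaine | mu_saccharin | value_gap | sigma |
| --- | --- | --- | --- | --- |
| SP | (1.0, 1.8) | (−0.1, 0.5) | (−2.5, −1.5) | 0.8 |
| IND | (0.5, 1.1) | (0.5, 1.1) | (−0.3, 0.3) | 0.8 |
| CP | (−0.1, 0.5) | (1.0, 1.8) | (1.5, 2.5) | 0.8 |

The preferred option's mean latency is floor + ~1.5–2.5 s and the
non-preferred option's floor + ~8–11 s, with heavy overlap (sigma = 0.8).
The overlap is substantive, not incidental: observed cocaine sampling
latencies in drug-preferring and indifferent rats are long and broadly
distributed, choice latencies are comparatively homogeneous between rewards,
and a detectable within-subject shortening for a *preferred* option is only
possible when its law overlaps the alternative's.  Default head-counts are
SP 109 / IND 23 / CP 19 — the profile mix of a large trained cohort — over
5 sessions, of which the last 3 form the analysis window.  Because a
simulated rat's *realized* profile is classified from its simulated choices,
archetype and profile can disagree near the 33.3%/66.6% boundaries; all
downstream analyses use the realized profile, as they must.

Omissions are possible (any draw reaching 300 s) but rare under the default
scales, matching their rarity in stable trained behavior.

## Statistics

* **LR** = mean(saccharin sampling) / (mean(saccharin) + mean(cocaine));
  1 ⇔ cocaine relatively fast.  LR(S,C) + LR(C,S) = 1 identically.
* **WL**: all |C|×|S| sampling pairs compared two-by-two; strict cocaine wins
  count 1, exact ties 0.5 (preserving the complement identity; at millisecond
  resolution ties are measure-zero, so the convention is inert on real data).
  Under the SCM, WL computed from sampling draws estimates the model's own
  race probability — an internal consistency the tests verify against the
  exponential closed form.
* **Preference correlations**: Spearman rank correlation of LR or WL against
  % cocaine choice.
* **Within-subject contrast**: per rat, mean sampling latency vs mean choice
  latency for one option, within one preference group (groups are only
  compared on options they actually choose: SP×saccharin, CP×cocaine,
  IND×both — avoiding selection bias from the SP majority).  Two-sided
  Wilcoxon signed-rank (scipy, exact for ≤ 50 untied pairs, otherwise
  tie-corrected normal approximation; zero differences discarded) with the
  matched-pairs rank-biserial correlation r = (W⁺ − W⁻)/(W⁺ + W⁻) as effect
  size.  Sign convention: r > 0 ⇔ choice faster than sampling (race
  signature); r < 0 ⇔ choice slower (deliberation signature).
* **Omission sensitivity**: every contrast is computed with omissions
  included (300 s kept in sampling lists) and excluded.  An omitted *choice*
  trial has no chosen option, so in both modes it contributes to no
  choice-latency list and is excluded from the preference denominator.

### Stability screen

Cohorts qualify for analysis when preference is stable over the last three
sessions.  Two criteria: (a) *no trend* — a two-sided Wilcoxon signed-rank
across rats between the first and last window session does not reject at
0.05 (a rank correlation of the three cohort means against session index
cannot reject at any conventional level with only three points, so the
across-rat paired test carries the trend criterion); (b) *consistency* — per-
rat preferences rank-correlate (Spearman p < 0.05) between consecutive
sessions.

## Decoding

Features are each rat's mean cocaine and mean saccharin sampling latency;
labels are the realized profiles.  The discriminant is the pooled-covariance
LDA with uniform priors (balance is enforced by construction):
`delta_k(x) = x'S⁻¹mu_k − ½ mu_k'S⁻¹mu_k + log pi_k`, with
`eps = 10⁻⁶·trace(S)/2` added to the covariance diagonal (19-per-class
samples can be near-singular) and prediction ties resolved to the lowest
class index in the fixed order SP < IND < CP (deterministic under seeding).
Accuracy is estimated by repeated stratified 10-fold cross-validation (20
repeats) inside each of 50 balanced subsamples; the smallest profile sets the
per-class count (n_per_class=None), generalizing the design in which the CP
group (n = 19) fixes it.  Chance for three balanced classes is 1/3, and the
shuffled-label pipeline must calibrate there — the package's key negative
control.

The permutation test's observed statistic is accuracy(real) −
accuracy(shuffled).  Each of the (default 1,000; desk-scale for runtime,
configurable to 10,000) permutations redraws cohort-level labels, runs a
reduced balanced decode (5 subsamples) and differences it against the fixed
shuffled baseline; p = (1 + #{null ≥ observed}) / (n_perm + 1), never exactly
zero.  Differencing against the fixed baseline is one defensible reading of
"distribution of differences under permutation"; the simpler rule that
counts permuted accuracies ≥ the real accuracy is available via
`null_rule="accuracy"`.

## Regime recovery

The pipeline's model-comparison experiment simulates one cohort per regime
and classifies each from the pooled preferred-option contrast: significant
r < 0 → deliberation-like, significant r > 0 → race-like, otherwise
habit-like.  Default design: 40 rats of the indifferent-like archetype, 8
sessions, whole run as window.  Two design notes:

* *Overlap*: recovery cohorts use overlapping option laws because the race's
  censorship shrinks toward zero as the laws separate; with near-disjoint
  laws the SCM is empirically indistinguishable from habit on the preferred
  option — a genuine property of the mechanism, not an implementation limit.
* *Calibration*: the signed-rank test assumes symmetric differences under the
  null.  Per-rat differences of means of few, skewed lognormal draws with
  unequal counts (sampling vs choice) are mildly asymmetric, which inflates
  the habit-null false-positive rate (~7% at 6 sessions in a 400-replicate
  pilot).  Sixteen sampling latencies per option (8 sessions) restore the
  nominal ~5%, which is why 8 is the default.

## What the simulator does and does not emulate

It reproduces the session anatomy, the latency floor and omission ceiling,
the heterogeneous-preference cohort structure, and the three latency-
generation mechanisms with their censorship/deliberation signatures.  It does
**not** model within-session pharmacological state, learning across sessions
(regimes are stationary; the limited-vs-extended-training contrast is
represented by *choosing* a DCM vs SCM configuration, not by a learning
process), value–latency coupling inside the DCM beyond the shared archetype
laws, or sequential dependencies between trials.  Passing tests therefore
show the *analysis* behaves correctly on data with the stated statistical
structure; they cannot certify conclusions about any real cohort, where the
latency family, stationarity and independence assumptions are approximations.

## Numerical and interface choices

Problem sizes in the test and acceptance suites (e.g. 19–50 rats per
condition, 10⁴–10⁵ Monte-Carlo draws, 100 recovery replicates, 200-iteration
permutation examples) are chosen so each check's Monte-Carlo error is well
below the effect it measures.  Stochastic assertions use 3-standard-error
tolerances.  All randomness flows through `numpy.random.Generator` objects
seeded at the configuration level; cohort generation, decoding and the
pipeline manifest are bit-reproducible under a fixed seed.  Trial tables are
plain CSV with shortest round-tripping float representation, so
write∘read is the identity.  Report bundles are delimited text plus a JSON
manifest of SHA-256 content hashes; no binary artifacts.
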