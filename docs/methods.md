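# Methods

This note records the models, conventions and numerical choices behind
`popscore`, in the order the pipeline applies them.

## Study design implemented

Term and late-preterm neonates with respiratory distress are monitored
once within six hours of birth. Eligibility requires birth weight
≥ 2000 g, umbilical-artery pH strictly above 7.20, and measurement age
≤ 360 min. The outcome is dichotomized on the highest C-reactive
protein within 48 h after birth (closed window: a sample at exactly
48 h counts): cases at ≥ 20 mg/L, controls below. Each case is matched
to four controls on gestational age within ±2.0 weeks (inclusive
comparison, decimal weeks).

The umbilical-pH boundary deserves a remark: the inclusion rule is
stated as "pH > 7.20" in one place and "excluding pH < 7.20" in
another, which disagree at exactly 7.20. The stricter reading (7.20 is
excluded) is implemented; the threshold is an explicit argument of
`apply_eligibility` for anyone preferring the other convention.

### Matching algorithm

The source design does not specify how controls were selected when more
than four were compatible. The implemented matcher is deterministic and
auditable: greedy without replacement, processing cases in ascending
order of in-tolerance candidate count (most constrained first, ties by
id) and giving each case the four candidates with smallest gestational
age difference (ties by id). A case that cannot receive four
in-tolerance controls is dropped with a reason; leftover controls are
reported as unused. Greedy matching is not guaranteed to maximize the
number of fully matched cases, so `max_matchable_cases` provides an
exact max-flow oracle (capacity-4 case edges, unit control edges) for
auditing; the test suite cross-checks greedy against it on randomized
instances and flags under-matching (none observed on feasible pools in
300 randomized draws, but the possibility is inherent to greedy).

## Session summarization

The measurement protocol yields five short pTOI traces (sensor
reapplied after 10-s rests) plus continuous SpO₂/HR streams and cuff
pressures before and after the session.

- **Stability.** "Stable for approximately 30 s" is operationalized as
  the earliest half-open window [start, start + 30 s) whose sample
  standard deviation (ddof = 1) is at or below a threshold. The
  threshold defaults to 2.0 %-points. The short-term noise of a quiet
  neonatal pTOI trace is about 1 %-point, and the sample sd of 30
  noise-only points exceeds its true sd half the time; a threshold
  equal to the typical noise sd would therefore reject 15–35% of
  genuinely stable plateaus. Twice the quiet-signal sd accepts those
  plateaus while still rejecting settling artefacts and motion (which
  sit at several %-points). Both window length and threshold are
  explicit arguments.
- **pTOI.** Mean of the per-placement stable-segment means, unweighted.
  Sessions with fewer than the protocol's five usable segments still
  summarize — the shortfall is recorded in `n_segments_used` and
  flagged — because real recordings lose placements; zero usable
  segments is an error.
- **Vitals.** SpO₂ and HR are averaged over the union of accepted pTOI
  windows only, excluding the rest periods, matching "during the NIRS
  measurements".
- **SABP.** Arithmetic mean of the before and after cuff readings; a
  missing phase is an error (no single-phase fallback).
- **pFTOE** = (SpO₂ − pTOI)/SpO₂; negative values (tissue index above
  arterial saturation) are kept and flagged.

All time windows are half-open throughout, which makes unions and
sample-membership tests unambiguous at boundaries.

## The score

POP-Score = (pTOI × fat × HR)/(SpO₂ × SABP), a raw ratio with no
weighting, clamping or transformation. Scores are carried at full
precision and rounded to 2 dp only in serialized tables; downstream
stages that read serialized scores recompute from the full-precision
component columns. Fat thickness above 5 cm triggers a unit-suspicion
flag (neonatal forearm fat is well under 1 cm; such a value almost
certainly means millimetres). Classification at the pre-specified
cut-off 1.00 is boundary-inclusive (score ≥ 1.00 is positive).

## Evaluation statistics

- Sensitivity/specificity are reported both as exact fractions and as
  integer percents under **truncation toward zero** — the convention
  that reproduces the published 87% from 21/24 = 87.5%.
- **Mann–Whitney U**: exact when the combined sample size is ≤ 30 *and*
  the number of group assignments is ≤ 2×10⁶ (the study-shaped 6-vs-24
  comparison has C(30,6) ≈ 5.9×10⁵ and is always exact). Without ties
  the exact p comes from scipy; with ties it is computed by full
  enumeration of rank assignments, whose null is symmetric about
  n₁n₂/2. Beyond the limits, the tie-corrected normal approximation is
  used. The 2×10⁶ cap exists because balanced splits (C(30,15) ≈
  1.6×10⁸) are not enumerable at interactive speed; it is part of the
  documented contract rather than a silent library default.
- **Fisher's exact test** for 2×2 tables (sex); chi-square for wider
  categorical tables (delivery mode).
- **Spearman correlation**: average ranks for ties; two-sided p by
  exhaustive permutation of all n! orderings for n ≤ 9, t approximation
  otherwise.
- The cut-off sweep (midpoints between sorted unique scores, ±∞
  sentinels) is labelled exploratory in the report: the study design
  fixes a single pre-specified cut-off and performs no ROC analysis.

## Synthetic cohort generator

The generator's defaults encode the published two-group summaries: for
every study variable, the per-group median (minimum; maximum) triplet,
the group sex and delivery-mode compositions, and the per-group peak-CRP
ranges (cases 20.8–36.2 mg/L, controls 1.0–14.3 mg/L).

- **Marginals.** Each variable is drawn from a Beta distribution
  rescaled to [min, max], with shapes a + b fixed at 6 and a solved
  (Brent's method on the Beta quantile function) so the distribution
  median equals the printed median. Bounded support makes the printed
  extremes hard bounds of every draw. A triangular family with apex at
  the median is available as an explicit alternative. Medians printed
  exactly at a support endpoint (some Apgar rows) are not representable
  by any continuous distribution on that support; the normalized median
  is clamped to [0.005, 0.995], which concentrates the mass at the
  correct integer after charting-precision rounding.
- **Dependence.** pTOI, SpO₂, HR, SABP and fat thickness share a
  Gaussian copula (Spearman ρ mapped to the Gaussian parameter by
  r = 2 sin(πρ/6)). Published evidence fixes only signs — SpO₂ and
  subcutaneous fat positively, HR negatively associated with pTOI — so
  the default magnitudes (+0.4, +0.3, −0.2) are free parameters,
  user-overridable in the config. Mean and diastolic pressure are
  comonotone with the systolic draw: marginals remain exact while
  SABP > MABP > DABP holds by construction.
- **Signals.** Each sensor placement is a 10-s settling phase
  (zero-mean noise, sd 3 %-points) followed by a 45-s plateau
  (sd 1.0 %-point) around the subject's latent pTOI plus a
  per-placement offset (sd 1.5 %-points); placements are separated by
  10-s rests, streams run at 1 Hz, and cuff panels are jittered
  antithetically (±d) so their mean equals the latent pressure. Values
  are rounded to device display precision (pTOI 0.01 %, streams 0.1,
  cuff whole mmHg, CRP 0.1 mg/L), which also makes CSV round-trips
  exact. All noise parameters are free choices, not published claims.
- **CRP trajectories.** Logistic rise value(t) = peak/(1 + e^−(t−t₅₀)/τ)
  with t₅₀ = 11 h (the 10–12-h CRP response delay) and τ = 2 h, sampled
  at 12, 24 and 40 h; the peak is uniform on the printed group range, so
  every case crosses 20 mg/L within 48 h and no control does.
- **Reproducibility.** Subject i of group g draws from the substream
  `SeedSequence(seed, spawn_key=(g, i))`; growing the cohort never
  reshuffles earlier subjects, and identical arguments give
  byte-identical tables.
- **Null generator.** `generate_null_cohort` draws both groups from the
  control distributions and only keeps the group-specific CRP
  trajectories, making the score independent of the outcome — the
  reference against which "the pipeline recovers the effect direction"
  is judged.

### What the generator does and does not emulate

It reproduces the two-group marginal structure, the sign pattern of the
physiological couplings, raw-signal texture, and the CRP-threshold
separation. It does **not** model sepsis progression, missing data,
motion artefacts, repeated sessions, or the joint distribution beyond
the five-variable copula — in particular, group medians of *derived*
quantities need not match the source cohort (medians do not compose:
the score of the case-group component medians is ≈ 1.37, and the
synthetic case-group score median lands near 1.3, whereas the source
cohort's observed median was 1.11, reflecting within-subject
correlations no marginal calibration can pin down). Passing tests
therefore demonstrate correctness of the pipeline's mechanics and
direction-level behaviour, not subject-level realism.

## Test calibration choices

Generator calibration is asserted on 500 subjects per group: each
empirical group median must fall inside the order-statistic band of the
configured distribution (quantiles at 0.5 ± z√(0.25/n)); z = 3.29
(~99.9% per variable) keeps the familywise false-alarm rate across ~46
simultaneous checks near 5%. Direction recovery uses 20 seeded cohorts
of 200 + 200 subjects (case median score above control median required
in ≥ 19 of 20); the null check uses 50 seeds with the same sizes and
requires the sign split to stay inside the central 95% band of
Binomial(50, ½), i.e. 18–32. Problem sizes were chosen so the whole
suite runs in about two minutes on one CPU.

## Known limitations

- Greedy matching can in principle under-match relative to the max-flow
  optimum; the oracle is provided and the condition is flagged, not
  hidden.
- The copula covers five variables; all others are independent within
  group, so cross-variable statistics beyond those five are not
  calibrated.
- The exact-test contracts switch to approximations outside their
  enumeration limits, as documented above.
- Blood-gas MABP/DABP and several descriptive variables pass through
  the pipeline but enter no computation, mirroring the source design.
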