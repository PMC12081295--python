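# Methods

## Scope and data model

`lewyprog` analyzes cross-sectional postmortem Lewy pathology: per-case
semiquantitative scores (0 = none ... 4 = very severe, DLB-consortium
convention) over a fixed 16-region panel spanning the neuraxis — ten CNS
regions (DMV, LC, SN, NBM, AMY, TrE, CIN, temporal, frontal and parietal
cortex), the olfactory bulb, the sympathetic trunk, and four peripheral
organ biopsies (heart, esophagus, adrenal gland, skin). Two complementary
analyses run on such matrices:

1. an **a priori stratification** driven by the brain-first vs body-first
   disease model, and
2. an **unsupervised ordinal subtype-and-stage model** (a mixture of
   monotone event sequences) that infers progression subtypes and per-case
   pseudotemporal stages.

Cases with missing region scores are excluded at load time, never imputed.

## The 4-to-3 score cap

Scores of 4 occur almost exclusively in limbic/olfactory regions (those
regions accumulate more aggregates per microscopy field than small
brainstem nuclei), which would bias any severity comparison between the
brain markers (AMY, OB) and the autonomic markers (DMV, SY). All severity
analyses therefore first convert every 4 to 3 (`cap_scores`). The cap is
idempotent and never changes which regions are positive. Severity-dependent
operations refuse input that still contains 4s, so the correction cannot be
silently skipped.

## A priori stratification

- **Dissemination category**: cases are binned by the number of
  Lewy-positive regions in two-region intervals, category = ceil(n/2),
  giving eight categories over 1–16 positive regions. Zero-positive cases
  are rejected (the cohorts contain only Lewy-positive cases).
- **Brain-first / body-first**: a case is brain-first when mean(AMY, OB) >
  mean(DMV, SY) on the capped scale, body-first for the reverse, and
  indeterminate on ties — no secondary tie-breaker is applied. The rule is
  deliberately insensitive to all other regions.
- **Clinical stage**: categories 1–6 are labelled prediagnostic, 7–8
  postdiagnostic. The boundary reflects where antemortem diagnoses
  concentrate in the published cohort.
- **Profiles**: per (group, category, region) mean and s.e.m. (sample
  s.d./sqrt(n)); s.e.m. for n = 1 is reported as NaN rather than 0,
  and indeterminate cases are excluded from the group curves.
- **Peripheral summaries**: any-positivity and summed severity over the
  four organ biopsies (0–12 on the capped scale).
- **Single-region census and isolation check**: the census counts cases
  positive in exactly one region; the isolation check certifies that
  SY/DMV-positive cases with LC, SN and AMY all negative carry no pathology
  anywhere else. On synthetic data this property holds for the
  brain-first and vagal (caudo-rostral) orderings; the sympathetic ordering
  intentionally violates it (SY and HE are both positive early), matching
  its role as a distinct early-peripheral phenotype.

## Ordinal subtype-and-stage model

Each subtype is a total ordering of K = 16 x 3 = 48 events; event (r, l)
is region r crossing from level l-1 to l. A subject at stage t in subtype c
has true level profile given by the first t events of sequence S_c.

- **Measurement model**: p(x | z) is a normal density with s.d. 0.5
  (default) evaluated at the score grid 0..3 and normalized per level. The
  s.d. is the scale of grading noise relative to one score step; 0.5 makes
  adjacent-score confusion common (p(correct) ≈ 0.88 at the grid corners)
  and two-step confusion rare.
- **Subject likelihood**: P(X | S) = (K+1)^-1 * sum_{t=0..K} prod_r
  p(x_r | level_r(S, t)): a uniform stage prior including stage 0, because
  the cohorts include minimal-pathology incidental cases.
- **Mixture fitting**: maximize sum_i log sum_c f_c P(X_i | S_c). A single
  sequence is fitted by greedy single-event repositioning from 25 random
  valid sequences (each start gets one improvement pass; the best 5 are run
  to convergence). All insertion positions for one event are scored in
  O(nK) via a prefix/suffix decomposition of the stage sums. Multi-subtype
  models use hierarchical initialization — random bipartitions of the
  largest clusters plus a k-means (on burden-normalized rows) candidate —
  followed by generalized EM: soft responsibilities, one greedy pass per
  cluster per iteration, exact fraction updates, and a final polish phase
  that runs each cluster's sequence to full greedy convergence. Every step
  only accepts improvements, so the mixture log-likelihood trace is
  non-decreasing; the fitter raises if it ever observes a decrease.
- **MCMC**: Metropolis–Hastings over sequences with a flat prior: pick a
  subtype and an event uniformly, move it to a uniformly chosen admissible
  position (within-region order preserved; the proposal is symmetric
  because the admissible-slot count of an event is invariant under its own
  move). Fractions stay at their EM estimates during sampling. Default
  100,000 iterations for production runs; the test suite uses 10,000. No
  burn-in is discarded for positional variance (the chain starts at the
  fitted mode).
- **Positional variance**: empirical frequency, over draws, of each event
  at each sequence position; rows sum to 1.
- **Allocation**: subtype posterior ∝ f_c P(X_i | S_c); stage posterior
  under the assigned subtype; MAP stage with ties broken toward the lower
  stage (conservative staging).
- **Model selection (CVIC)**: stratified random folds (dealt over total
  burden), hierarchical fits on each training set for 1..max candidate
  counts, and CVIC(c) = -2 x the total out-of-fold log-likelihood evaluated
  under the training posterior predictive (held-out likelihood averaged
  over thinned MCMC draws). Scoring the single maximum-likelihood sequence
  instead is systematically biased toward extra subtypes: a duplicated
  subtype imitates exactly this posterior averaging, and in experiments the
  point-estimate CVIC preferred c+1 duplicate-sequence models while the
  predictive CVIC recovers the planted count. The lowest CVIC wins.
- **CNS-only configuration**: selecting the ten-region CNS subset runs the
  identical code path with K = 30; an optional five-level mode (K = 64)
  accepts uncapped 0–4 scores.

## Synthetic cohorts

The generator plants three sequences built from region onset schedules
(onset time plus per-level lag per region; sorting event times yields the
ordering):

- **brain-first** — OB/AMY onset, rostro-caudal spread, peripheral organs
  last;
- **parasympathetic body-first** — DMV/LC onset, then SY, NBM, SN, then
  AMY/OB, peripheral organs soon after;
- **sympathetic body-first** — SY/HE onset with SY saturating (level 3)
  before any CNS region except the DMV becomes positive, then ADR and DMV,
  later LC/AMY/OB, finally SN/NBM.

Cohort defaults: mixture 51/27/22%, stages uniform over {0..48} (the
emulated cohort spans incidental minimal pathology through fully
disseminated disease; a uniform law is an assumption — the source data's
stage distribution is unknown), measurement s.d. 0.5, and a sampled
(Bernoulli, not deterministic) diagnosis label: P(diagnosed) = 0.75 at
stage ≥ 29 and 0.017 below. Ages are N(83, 9) clipped to 50–105;
Alzheimer-pathology flags are more frequent in brain-first cases (25% vs
3%), mirroring the association of limbic-predominant Lewy pathology with
AD. What the generator does **not** emulate: region-specific grading
noise, correlated rater effects, missingness, cohort-specific stage
distributions, and any departure of real progression from a strict shared
event order — so passing recovery tests demonstrate internal consistency
of the pipeline, not validity of the disease model on real data.

## Numerical choices

- Stage sums are computed in log space with per-case max subtraction; the
  greedy insertion scorer bounds the shifted exponent by the moved event's
  own likelihood ratio, so no overflow occurs for measurement s.d. ≥ 0.2.
- Equality tolerance for the EM monotonicity guard: 1e-6 on a total
  log-likelihood of magnitude ~1e3–1e4.
- LOESS: tricube weights over the span fraction of nearest points, local
  degree-2 weighted least squares on a centered design, evaluated at
  integer stages 0..48; the local degree is reduced automatically when a
  window carries too few points. Default span 0.75.
- Percent formatting follows the printed convention: one decimal below
  10%, whole percent otherwise, half-up rounding in exact integer
  arithmetic.
- All randomness flows from one user seed through
  `numpy.random.default_rng`; derived stream seeds stay below 2^31.

## Problem sizes used in the shipped checks

Recovery and selection checks run on the default 300-case cohort with
10,000-iteration chains and 5-fold selection over 1–4 subtypes; the
diagnosis-rule check uses 5,000 cases; oracle equivalences run on 1–3
region panels where exhaustive enumeration is exact. These sizes were
chosen so the full suite completes on a single desktop core while leaving
all assertions comfortably away from their thresholds.

## Known limitations

- Greedy ascent offers no global-optimality guarantee beyond the tiny
  panels where exhaustive search is feasible; multi-start plus k-means
  initialization makes recovery reliable in practice but pathological
  mixtures can still stall.
- The uniform stage prior is shared between generator and model; real
  cohorts with strongly non-uniform stage distributions would need the
  configurable stage law.
- CVIC compares only point hierarchies of nested fits; it does not explore
  non-hierarchical subtype configurations.
- Binary (presence/absence) matrices support the census and isolation
  checks only; severity-dependent operations reject them by design.
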