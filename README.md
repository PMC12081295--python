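# lewyprog

Analysis pipeline for cross-sectional postmortem Lewy pathology: a priori
brain-first / body-first stratification of semiquantitative score matrices,
an ordinal subtype-and-stage mixture model that infers progression subtypes
without supervision, and the summary reports built on both — together with
a synthetic-cohort generator so that every stage is testable without any
restricted dataset.

**Who it is for.** Neuropathology and biostatistics groups working with
case x region ordinal pathology scores (0 = none .. 4 = very severe,
DLB-consortium convention) over a panel that spans both the CNS and the
peripheral autonomic nervous system, who want to ask: where does
alpha-synuclein pathology start, and along which routes does it spread?

## The model

A 16-region panel is scored per case: ten CNS regions (DMV, LC, SN, NBM,
AMY, TrE, CIN, T, F, P), the olfactory bulb (OB), the sympathetic trunk
(SY) and four peripheral organs (HE, ESO, ADR, SKIN).

*A priori stratification.* Cases are binned into eight dissemination
categories by positive-region count (category = ⌈n/2⌉) and classified as
**brain-first** when mean(AMY, OB) > mean(DMV, SY) on the capped 0–3 scale,
**body-first** for the reverse, and indeterminate on ties; categories 7–8
are the postdiagnostic stage.

*Subtype-and-stage inference.* Each progression subtype c is a total
ordering S_c of K = 16 x 3 = 48 events, where event (r, l) is region r
reaching level l. A subject at stage t has undergone the first t events.
Observed scores x are linked to true levels z through a normalized normal
kernel p(x|z) with s.d. 0.5, and with a uniform stage prior the subject
likelihood is

    P(X | S_c) = (K+1)^-1 Σ_{t=0..K} Π_r p(x_r | level_r(S_c, t)).

The cohort is a mixture Σ_c f_c P(X | S_c), fitted by greedy event
repositioning inside EM with hierarchical cluster-splitting
initialization; sequence uncertainty is sampled by Metropolis–Hastings
(positional variance diagrams), the number of subtypes is chosen by a
cross-validation information criterion (CVIC, lower is better), and each
case receives a maximum-posterior subtype and stage.

## Worked example

```python
import lewyprog as lp

spec = lp.CohortSpec(n_cases=300, seed=0)      # 3 planted subtypes, 51/27/22%
matrix, truth = lp.make_cohort(spec)

strata = lp.stratify_cases(matrix)
summary = lp.category_summary(strata, matrix.metadata)
print(summary[["total", "brain_first", "body_first", "indeterminate",
               "diagnosed"]])
```

```
          total  brain_first  body_first  indeterminate  diagnosed
category
1             7            0           3              4          0
2            11            3           8              0          0
3            27           12          15              0          0
4            32           15          17              0          0
5            33           18          12              3          0
6            34           11          22              1          1
7            41           21          17              3          8
8           115           33          29             53         82
total       300          113         123             64         91
```

Diagnosed cases concentrate in the last two dissemination categories
(the postdiagnostic stage), indeterminate cases pile up in the most
disseminated category where the marker regions saturate — the structure the
stratification is designed to expose. Staging the same cohort against the
planted truth:

```python
dx = matrix.metadata["diagnosis"].isin(["PD", "PDD_DLB"])
print(lp.stage_threshold_report(truth["stage"], dx, threshold=29))
# ThresholdReport(threshold=29, n_below=175, diagnosed_below=1,
#                 pct_below=0.6, n_above=125, diagnosed_above=90,
#                 pct_above=72.0)
```

i.e. 72% of cases at or above stage 29 carry an antemortem diagnosis and
almost none below — the generator's planted severity threshold, recovered
by the report. Fitting the subtype model itself (minutes, not seconds):

```python
model = lp.fit_subtypes(matrix, n_subtypes=3, seed=0)
assign = lp.assign_subjects(model, matrix)
pv = lp.positional_variance(model)
```

The `examples/` directory holds one short script per capability; the same
pipeline is scriptable from a shell via the `lewyprog` CLI
(`simulate`, `stratify`, `sustain`, `report`).

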