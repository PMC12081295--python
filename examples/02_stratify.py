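"""A priori brain-first vs body-first stratification of a cohort.

Caps scores at 3, bins cases into eight dissemination categories, labels
each case brain-first/body-first/indeterminate from the four marker
regions, and summarizes peripheral-organ involvement per group.
"""

import lewyprog as lp

matrix, _ = lp.make_cohort(lp.CohortSpec(n_cases=400, seed=2))
matrix = matrix.lewy_positive()   # cohort inclusion: >= 1 positive region
strata = lp.stratify_cases(matrix)

print(strata["subtype_label"].value_counts().to_string())
print("\nPer-category summary:")
summary = lp.category_summary(strata, matrix.metadata)
print(summary[["total", "brain_first", "body_first", "diagnosed"]])

# Peripheral involvement: body-first cases show organ pathology in early
# categories, brain-first cases only late - the core signature the
# stratification is built to expose.
early = strata[strata["category"] <= 4]
for label in ("brain_first", "body_first"):
    sub = early[early["subtype_label"] == label]
    pct = 100 * sub["peripheral_any"].mean() if len(sub) else float("nan")
    print(f"early-category {label}: {pct:.0f}% with any peripheral "
          f"pathology (n={len(sub)})")

print("\nsingle-region census:", lp.isolated_region_census(matrix))
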