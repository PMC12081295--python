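"""A priori stratification of Lewy pathology score matrices.

Cases are binned into eight dissemination categories by the number of
Lewy-positive regions (two-region intervals), classified as brain-first or
body-first from the four marker regions (AMY+OB vs DMV+SY mean severity),
labelled prediagnostic/postdiagnostic, and summarized per region and per
peripheral-organ panel. Severity comparisons run on the capped 0-3 scale;
uncapped input (any score of 4 among the markers) is refused so the 4-to-3
correction cannot be silently skipped.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .catalog import CATALOG, RegionCatalog
from .io import PathologyMatrix

BRAIN_FIRST = "brain_first"
BODY_FIRST = "body_first"
INDETERMINATE = "indeterminate"
PREDIAGNOSTIC = "prediagnostic"
POSTDIAGNOSTIC = "postdiagnostic"


def dissemination_category(n_positive: int) -> int:
    """Two-region-interval bin of the positive-region count.

    Category 1 covers 1-2 positive regions, ..., category 8 covers 15-16.
    A case with zero positive regions has no Lewy pathology and does not
    belong in the cohort, so 0 is an error.
    """
    n = int(n_positive)
    if n < 1 or n > 16:
        raise ValueError(
            f"n_positive must be 1..16 (cohort contains only Lewy-positive "
            f"cases); got {n_positive}"
        )
    return (n + 1) // 2  # == ceil(n / 2)


def label_clinical_stage(category: int) -> str:
    """Categories 1-6 are prediagnostic; 7-8 are postdiagnostic."""
    c = int(category)
    if c < 1 or c > 8:
        raise ValueError(f"category must be 1..8; got {category}")
    return POSTDIAGNOSTIC if c >= 7 else PREDIAGNOSTIC


def _marker_scores(row: Mapping, markers, what: str) -> np.ndarray:
    try:
        vals = np.array([row[m] for m in sorted(markers)], dtype=float)
    except KeyError as e:
        raise KeyError(f"{what}: marker region {e.args[0]} missing") from None
    if (vals > 3).any():
        raise ValueError(
            f"{what}: marker score above 3 found; apply cap_scores before "
            "classification"
        )
    return vals


def classify_brain_body(row: Mapping, catalog: RegionCatalog = CATALOG) -> str:
    """Classify one case as brain-first, body-first or indeterminate.

    Brain-first: mean severity of the brain markers (AMY, OB) strictly above
    the body markers (DMV, SY); body-first the opposite; ties are
    indeterminate (no secondary tie-breaker). Non-marker regions are ignored.
    """
    brain = _marker_scores(row, catalog.brain_markers, "classify_brain_body")
    body = _marker_scores(row, catalog.body_markers, "classify_brain_body")
    if brain.mean() > body.mean():
        return BRAIN_FIRST
    if brain.mean() < body.mean():
        return BODY_FIRST
    return INDETERMINATE


def peripheral_summary(row: Mapping,
                       catalog: RegionCatalog = CATALOG) -> tuple[bool, int]:
    """(any peripheral organ positive, summed severity over the four organs)."""
    organs = sorted(catalog.peripheral_organs)
    try:
        vals = np.array([row[o] for o in organs], dtype=float)
    except KeyError as e:
        raise KeyError(f"peripheral organ {e.args[0]} missing") from None
    return bool((vals > 0).any()), int(vals.sum())


def stratify_cases(matrix: PathologyMatrix) -> pd.DataFrame:
    """Full per-case stratification table.

    Returns one row per case with ``n_positive``, ``category``,
    ``subtype_label``, ``clinical_stage``, ``peripheral_any`` and
    ``peripheral_sum``. Requires a capped full-panel ordinal matrix.
    """
    matrix.require_severity("stratify_cases")
    missing = set(matrix.catalog.regions) - set(matrix.regions)
    if missing:
        raise ValueError(f"stratification needs the full 16-region panel; "
                         f"missing {sorted(missing)}")
    if (matrix.scores.to_numpy() > 3).any():
        raise ValueError("scores above 3 present; apply cap_scores first")
    rows = []
    for cid, row in matrix.scores.iterrows():
        n_pos = int((row > 0).sum())
        cat = dissemination_category(n_pos)
        any_p, sum_p = peripheral_summary(row, matrix.catalog)
        rows.append({
            "case_id": cid,
            "n_positive": n_pos,
            "category": cat,
            "subtype_label": classify_brain_body(row, matrix.catalog),
            "clinical_stage": label_clinical_stage(cat),
            "peripheral_any": any_p,
            "peripheral_sum": sum_p,
        })
    return pd.DataFrame(rows).set_index("case_id")


def profile_table(matrix: PathologyMatrix,
                  strata: pd.DataFrame) -> pd.DataFrame:
    """Region severity profiles per (subtype group, dissemination category).

    For each brain-first/body-first group, category 1..8 and region, returns
    the mean score, its standard error (sample s.d. / sqrt(n); NaN for
    n < 2) and n. Indeterminate cases are excluded from the curves; empty
    cells are kept with n = 0 and NaN mean.
    """
    long = (matrix.scores.reset_index(names="case_id")
            .melt(id_vars="case_id", var_name="region", value_name="score"))
    long = long.merge(
        strata[["category", "subtype_label"]].reset_index(names="case_id"),
        on="case_id")
    long = long[long["subtype_label"].isin([BRAIN_FIRST, BODY_FIRST])]
    g = long.groupby(["subtype_label", "category", "region"])["score"]
    table = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
    table["sem"] = table["sd"] / np.sqrt(table["n"])
    table = table.drop(columns="sd")
    full = pd.MultiIndex.from_product(
        [[BRAIN_FIRST, BODY_FIRST], range(1, 9), matrix.regions],
        names=["subtype_label", "category", "region"])
    table = table.reindex(full)
    table["n"] = table["n"].fillna(0).astype(int)
    return table.reset_index()


def isolated_region_census(matrix: PathologyMatrix) -> dict[str, int]:
    """Count cases positive in exactly one region, keyed by that region.

    Works for ordinal or binary matrices over any region subset; regions
    with no single-region case are omitted.
    """
    pos = matrix.scores.to_numpy() > 0
    single = pos.sum(axis=1) == 1
    census: dict[str, int] = {}
    for j, region in enumerate(matrix.regions):
        k = int((single & pos[:, j]).sum())
        if k:
            census[region] = k
    return census


def sy_dmv_isolation_check(matrix: PathologyMatrix) -> list:
    """Certify isolated autonomic pathology against the full panel.

    Among cases positive in SY or DMV but negative in LC, SN and AMY, return
    the ids of any case with pathology in another region. An empty list
    certifies that SY/DMV-positive, LC/SN/AMY-negative cases carry no Lewy
    pathology anywhere else in the cohort.
    """
    gate = ["SY", "DMV", "LC", "SN", "AMY"]
    missing = [r for r in gate if r not in matrix.regions]
    if missing:
        raise ValueError(f"isolation check needs regions {gate}; "
                         f"missing {missing}")
    s = matrix.scores
    eligible = ((s["SY"] > 0) | (s["DMV"] > 0)) & \
        (s["LC"] == 0) & (s["SN"] == 0) & (s["AMY"] == 0)
    others = [r for r in matrix.regions if r not in ("SY", "DMV")
              and r not in ("LC", "SN", "AMY")]
    violating = eligible & (s[others] > 0).any(axis=1)
    return list(s.index[violating])


def diagnosed_counts(strata: pd.DataFrame,
                     metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-category diagnosed (PD / PDD-DLB) counts next to totals."""
    dx = metadata["diagnosis"].isin(["PD", "PDD_DLB"])
    df = pd.DataFrame({"category": strata["category"], "diagnosed": dx})
    out = df.groupby("category")["diagnosed"].agg(diagnosed="sum", total="count")
    return out.reindex(range(1, 9), fill_value=0).reset_index()
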