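"""Summary tables: category summaries, diagnosed fractions, stage-threshold
reports, stage-burden correlation and LOESS peripheral trajectories.

Percentages follow the printed convention of the field's tables: one decimal
below 10% ("1.7%"), whole percent otherwise ("75%"), with half-up rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .io import PathologyMatrix
from .stratify import BODY_FIRST, BRAIN_FIRST, INDETERMINATE


def diagnosed_fraction(diagnosed_n: int, total_n: int) -> int:
    """Percent diagnosed, rounded half-up to the nearest integer."""
    if total_n <= 0:
        raise ValueError("total_n must be positive")
    if not 0 <= diagnosed_n <= total_n:
        raise ValueError("need 0 <= diagnosed_n <= total_n")
    # floor(100*d/n + 1/2) in exact integer arithmetic
    return (200 * diagnosed_n + total_n) // (2 * total_n)


def format_percent(diagnosed_n: int, total_n: int) -> float:
    """Percent with one decimal below 10%, integer otherwise (half-up)."""
    if total_n <= 0:
        raise ValueError("total_n must be positive")
    raw = 100 * diagnosed_n / total_n
    if raw < 10:
        return (2000 * diagnosed_n + total_n) // (2 * total_n) / 10
    return float(diagnosed_fraction(diagnosed_n, total_n))


def category_summary(strata: pd.DataFrame,
                     metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-dissemination-category cohort summary plus a totals row.

    For each category 1..8: total cases, brain-first/body-first/indeterminate
    counts, diagnosed (PD or PDD-DLB) count, AD count, mean age, and the
    mean of any extra numeric metadata columns (pass-through). A final
    ``total`` row aggregates across categories.
    """
    df = strata[["category", "subtype_label"]].join(metadata, how="left")
    extra = [c for c in metadata.columns
             if c not in ("diagnosis", "ad_flag", "age")
             and pd.api.types.is_numeric_dtype(metadata[c])]
    rows = []
    groups = list(df.groupby("category")) + [("total", df)]
    for cat, sub in groups:
        row = {
            "category": cat,
            "total": len(sub),
            "brain_first": int((sub["subtype_label"] == BRAIN_FIRST).sum()),
            "body_first": int((sub["subtype_label"] == BODY_FIRST).sum()),
            "indeterminate": int((sub["subtype_label"]
                                  == INDETERMINATE).sum()),
            "diagnosed": int(sub["diagnosis"]
                             .isin(["PD", "PDD_DLB"]).sum()),
            "ad": int(sub["ad_flag"].fillna(False).astype(bool).sum()),
            "mean_age": sub["age"].mean() if "age" in sub else np.nan,
        }
        for c in extra:
            row[f"mean_{c}"] = sub[c].mean()
        rows.append(row)
    out = pd.DataFrame(rows).set_index("category")
    out = out.reindex([*range(1, 9), "total"])
    for col in ("total", "brain_first", "body_first", "indeterminate",
                "diagnosed", "ad"):
        out[col] = out[col].fillna(0).astype(int)
    return out


@dataclass(frozen=True)
class ThresholdReport:
    """Diagnosed-case partition at a stage threshold T (below vs at/above)."""

    threshold: int
    n_below: int
    diagnosed_below: int
    pct_below: float
    n_above: int
    diagnosed_above: int
    pct_above: float


def stage_threshold_report(stages, diagnosed, threshold: int = 29
                           ) -> ThresholdReport:
    """Partition cases at ``stage < threshold`` vs ``>=`` and report percents.

    ``stages`` and ``diagnosed`` are aligned sequences (model stages and
    boolean antemortem-LBD-diagnosis labels).
    """
    stages = np.asarray(stages)
    diagnosed = np.asarray(diagnosed, dtype=bool)
    if stages.shape != diagnosed.shape:
        raise ValueError("stages and diagnosis labels must align")
    below = stages < threshold
    n_b, n_a = int(below.sum()), int((~below).sum())
    d_b, d_a = int(diagnosed[below].sum()), int(diagnosed[~below].sum())
    return ThresholdReport(
        threshold=threshold,
        n_below=n_b, diagnosed_below=d_b,
        pct_below=format_percent(d_b, n_b) if n_b else 0.0,
        n_above=n_a, diagnosed_above=d_a,
        pct_above=format_percent(d_a, n_a) if n_a else 0.0,
    )


def stage_burden_correlation(stages, matrix: PathologyMatrix
                             ) -> float:
    """Pearson r between model stage and total pathology burden.

    Burden is the per-case sum of all (capped) region scores. Zero variance
    in either variable leaves r undefined and raises.
    """
    stages = np.asarray(stages, dtype=float)
    burden = matrix.scores.sum(axis=1).to_numpy(dtype=float)
    if len(stages) != len(burden) or len(stages) < 3:
        raise ValueError("need >= 3 aligned cases")
    if np.std(stages) == 0 or np.std(burden) == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(pearsonr(stages, burden).statistic)


def loess_trajectory(x, y, span: float = 0.75, degree: int = 2,
                     grid=None) -> pd.DataFrame:
    """Locally weighted polynomial (LOESS) fit on a stage grid.

    Tricube weights over the ``span`` fraction of nearest points, local
    polynomial of the given degree (<= 2), evaluated at integer stages 0..48
    by default. Returns a DataFrame with ``stage`` and ``fit``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 10:
        raise ValueError("need >= 10 (x, y) points")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if degree > 2 or degree < 0:
        raise ValueError("local degree must be 0, 1 or 2")
    if grid is None:
        grid = np.arange(0, 49, dtype=float)
    grid = np.asarray(grid, dtype=float)
    q = max(degree + 1, int(np.ceil(span * len(x))))
    if q > len(x):
        raise ValueError("span window larger than the data")
    fit = np.empty(len(grid))
    for i, g in enumerate(grid):
        d = np.abs(x - g)
        h = np.sort(d)[q - 1]
        if h == 0:
            h = max(np.sort(d)[-1], 1.0) * 1e-9
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        use = w > 0
        deg = degree
        while deg > 0 and use.sum() < deg + 2:
            deg -= 1
        # centered design for conditioning
        A = np.vander(x[use] - g, deg + 1, increasing=True)
        W = np.sqrt(w[use])
        beta, *_ = np.linalg.lstsq(A * W[:, None], y[use] * W, rcond=None)
        fit[i] = beta[0]
    return pd.DataFrame({"stage": grid, "fit": fit})
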