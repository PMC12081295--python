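"""Score-matrix container and delimited-text readers/writers.

Scores follow the DLB-consortium semiquantitative convention: integers from 0
(no pathology) to 4 (very severe). Binary (presence/absence) matrices over a
region subset are supported for Newcastle-style data; severity-dependent
operations reject binary input explicitly.

File dialect: comma-separated UTF-8, first column ``case_id``, region columns
named by canonical identifiers (case-insensitive on read), optional metadata
columns ``diagnosis``, ``ad_flag``, ``age``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import CATALOG, RegionCatalog

logger = logging.getLogger(__name__)

DIAGNOSES = ("ILBD", "PD", "PDD_DLB", "none")
METADATA_COLUMNS = ("diagnosis", "ad_flag", "age")


@dataclass
class PathologyMatrix:
    """Case x region ordinal (or binary) pathology scores plus metadata.

    Attributes
    ----------
    scores
        Integer DataFrame indexed by case id, one column per region in the
        declared subset. Ordinal mode allows 0-4 (0-3 once capped); binary
        mode allows 0/1.
    metadata
        Per-case metadata aligned with ``scores``; always carries
        ``diagnosis``, ``ad_flag`` and ``age`` (extra columns pass through).
    mode
        ``"ordinal"`` or ``"binary"``.
    capped
        Provenance flag: scores live on the capped 0-3 scale (either the
        4-to-3 correction was applied or the data were generated on that
        scale).
    """

    scores: pd.DataFrame
    metadata: pd.DataFrame
    mode: str = "ordinal"
    capped: bool = False
    #: ``None`` allows free-form region names (toy panels); catalog-aware
    #: operations (stratification, region subsets) then refuse the matrix.
    catalog: RegionCatalog | None = field(default_factory=lambda: CATALOG)

    def __post_init__(self) -> None:
        if self.mode not in ("ordinal", "binary"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.scores.index.has_duplicates:
            dup = self.scores.index[self.scores.index.duplicated()][0]
            raise ValueError(f"duplicate case id: {dup!r}")
        if self.catalog is not None:
            unknown = [c for c in self.scores.columns
                       if c not in self.catalog.regions]
            if unknown:
                raise ValueError(f"unknown region column(s): {unknown}")
        if self.scores.isna().any().any():
            raise ValueError("missing scores are not allowed; drop the case")
        vals = self.scores.to_numpy()
        hi = self._max_score()
        bad = (vals < 0) | (vals > hi) | (vals != vals.astype(int))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"score out of range for case {self.scores.index[i]!r}, "
                f"region {self.scores.columns[j]}: {vals[i, j]} "
                f"(allowed 0..{hi})"
            )
        self.scores = self.scores.astype(int)
        self.metadata = self.metadata.reindex(self.scores.index)
        for col, default in (("diagnosis", "none"), ("ad_flag", False),
                             ("age", np.nan)):
            if col not in self.metadata.columns:
                self.metadata[col] = default
        baddx = ~self.metadata["diagnosis"].isin(DIAGNOSES)
        if baddx.any():
            raise ValueError(
                f"invalid diagnosis for case "
                f"{self.metadata.index[baddx][0]!r}: "
                f"{self.metadata['diagnosis'][baddx].iloc[0]!r}"
            )

    def _max_score(self) -> int:
        if self.mode == "binary":
            return 1
        return 3 if self.capped else 4

    # -- convenience accessors -------------------------------------------------
    @property
    def regions(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def case_ids(self) -> list:
        return list(self.scores.index)

    @property
    def n_cases(self) -> int:
        return len(self.scores)

    def select_regions(self, regions: list[str]) -> "PathologyMatrix":
        """Project onto a region subset (e.g. the ten-region CNS panel)."""
        missing = [r for r in regions if r not in self.scores.columns]
        if missing:
            raise KeyError(f"regions not present in matrix: {missing}")
        return replace(self, scores=self.scores[list(regions)].copy(),
                       metadata=self.metadata.copy())

    def lewy_positive(self) -> "PathologyMatrix":
        """Subset to cases with pathology in at least one region.

        Cohort inclusion requires a severity score >= 1 somewhere; cases
        without any pathology do not belong in a Lewy-pathology cohort and
        are dropped here (with a logged count) before stratification.
        """
        keep = (self.scores > 0).any(axis=1)
        if (~keep).any():
            logger.info("dropped %d Lewy-negative case(s)", (~keep).sum())
        return replace(self, scores=self.scores.loc[keep].copy(),
                       metadata=self.metadata.loc[keep].copy())

    def require_severity(self, what: str = "operation") -> None:
        """Reject binary-mode input for severity-dependent operations."""
        if self.mode == "binary":
            raise ValueError(f"{what} requires ordinal severity scores; "
                             "matrix is binary presence/absence")


def cap_scores(matrix: PathologyMatrix) -> PathologyMatrix:
    """Apply the 4-to-3 score correction.

    Region scores of 4 (very severe) are far more common in limbic/olfactory
    regions than in small brainstem nuclei, which would bias severity
    comparisons between them; every 4 is therefore converted to 3 before
    stratification or subtype inference. Positivity (score > 0) is unchanged
    and the operation is idempotent.
    """
    matrix.require_severity("cap_scores")
    capped = matrix.scores.clip(upper=3)
    return replace(matrix, scores=capped, metadata=matrix.metadata.copy(),
                   capped=True)


def _resolve_columns(columns, catalog: RegionCatalog):
    """Split raw header names into (region-map, metadata list); error on junk."""
    region_map: dict[str, str] = {}
    meta: list[str] = []
    for col in columns:
        low = col.strip().lower()
        if low == "case_id":
            continue
        if low in (m.lower() for m in METADATA_COLUMNS) or low in (
                "braak_asyn", "braak_nft", "thal", "cerad"):
            meta.append(col)
            continue
        try:
            region_map[col] = catalog.resolve(col)
        except KeyError:
            raise ValueError(
                f"unknown region column {col!r}; expected one of "
                f"{list(catalog.regions)} or metadata "
                f"{list(METADATA_COLUMNS)}"
            ) from None
    return region_map, meta


def read_scores(path: str | Path, mode: str = "ordinal", *,
                capped: bool = False,
                catalog: RegionCatalog = CATALOG) -> PathologyMatrix:
    """Read a score-matrix CSV into a validated :class:`PathologyMatrix`.

    Cases with any missing score in the region subset present in the file are
    dropped (never imputed); the exclusion count is logged. Unknown region
    names, out-of-range scores and duplicate case ids are hard errors.

    Parameters
    ----------
    path
        CSV with a ``case_id`` column, region columns and optional metadata.
    mode
        ``"ordinal"`` (scores 0-4, or 0-3 when ``capped``) or ``"binary"``.
    capped
        Declare that the file is already on the capped 0-3 scale.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"score file not found: {path}")
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "case_id" not in cols:
        raise ValueError(f"{path}: no 'case_id' column")
    region_map, meta_cols = _resolve_columns(df.columns, catalog)
    if mode == "ordinal":
        missing = set(catalog.regions) - set(region_map.values())
        if missing:
            raise ValueError(
                f"{path}: ordinal mode requires all 16 regions; missing "
                f"{sorted(missing)}"
            )
    df = df.set_index(cols["case_id"]).rename_axis("case_id")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate case id {dup!r}")
    scores = df[list(region_map)].rename(columns=region_map)
    # Keep panel order for the columns actually present.
    scores = scores[[r for r in catalog.regions if r in scores.columns]]
    incomplete = scores.isna().any(axis=1)
    if incomplete.any():
        logger.info("excluded %d case(s) with missing scores: %s",
                    incomplete.sum(), list(scores.index[incomplete]))
    scores = scores.loc[~incomplete]
    vals = scores.to_numpy(dtype=float)
    if (vals != np.round(vals)).any():
        i, j = np.argwhere(vals != np.round(vals))[0]
        raise ValueError(f"non-integer score for case {scores.index[i]!r}, "
                         f"region {scores.columns[j]}")
    metadata = df.loc[scores.index, meta_cols].copy() if meta_cols else \
        pd.DataFrame(index=scores.index)
    metadata.columns = [c.strip().lower() for c in metadata.columns]
    if "ad_flag" in metadata.columns:
        metadata["ad_flag"] = metadata["ad_flag"].map(_parse_bool)
    if "diagnosis" in metadata.columns:
        metadata["diagnosis"] = metadata["diagnosis"].fillna("none")
    return PathologyMatrix(scores=scores.astype(int), metadata=metadata,
                           mode=mode, capped=capped, catalog=catalog)


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, float, np.integer)) and not pd.isna(x):
        return bool(int(x))
    if isinstance(x, str):
        return x.strip().lower() in ("true", "1", "yes")
    return False


def write_scores(matrix: PathologyMatrix, path: str | Path) -> None:
    """Write a matrix as CSV such that :func:`read_scores` round-trips it."""
    path = Path(path)
    out = matrix.scores.copy()
    for col in METADATA_COLUMNS:
        out[col] = matrix.metadata[col]
    extra = [c for c in matrix.metadata.columns if c not in METADATA_COLUMNS]
    for col in extra:
        out[col] = matrix.metadata[col]
    out.rename_axis("case_id").to_csv(path)
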