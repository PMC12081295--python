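"""Synthetic cohorts with the structure the progression analysis assumes.

The generator plants three progression orderings — a brain-first (olfactory
bulb/amygdala onset), a parasympathetic body-first (vagal/locus-coeruleus
onset) and a sympathetic body-first (sympathetic trunk/heart onset) sequence
— mixes them at 51/27/22%, draws each case's stage from a law over {0..48}
(uniform by default, covering the spectrum from incidental minimal pathology
to fully disseminated disease), observes the implied true levels through the
normal measurement kernel (s.d. 0.5), and samples an antemortem LBD
diagnosis label that switches on above a stage threshold (75% diagnosed at
or above stage 29, 1.7% below).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import CATALOG, RegionCatalog
from .io import PathologyMatrix
from .sustain import EventSequence, build_measurement_model

#: Region onset schedules: region -> (onset time, per-level lag). Event
#: (region, level) fires at onset + (level-1) * lag; sorting event times
#: (ties broken by schedule order, then level) yields the full 48-event
#: ordering. The three schedules realize the three progression narratives:
#: brain-first spreads rostrocaudally with peripheral organs last; the
#: parasympathetic type starts in the DMV/LC with the sympathetic trunk next;
#: the sympathetic type saturates the sympathetic trunk before any CNS
#: region beyond the DMV becomes positive.
BRAIN_FIRST_SCHEDULE = {
    "OB": (0, 5), "AMY": (1, 5), "TrE": (2, 5), "CIN": (3, 5), "LC": (4, 5),
    "SN": (5, 5), "NBM": (6, 5), "DMV": (7, 5), "SY": (8, 5), "T": (9, 5),
    "F": (10, 5), "P": (11, 5), "HE": (12, 5), "ESO": (13, 5),
    "ADR": (14, 5), "SKIN": (15, 5),
}
PARASYMPATHETIC_SCHEDULE = {
    "DMV": (0, 5), "LC": (1, 5), "SY": (2, 4), "NBM": (3, 5), "SN": (4, 5),
    "HE": (5, 5), "ADR": (5.5, 5), "AMY": (6, 5), "OB": (7, 5),
    "ESO": (8, 5), "SKIN": (9, 5), "TrE": (10, 5), "CIN": (11, 5),
    "T": (12, 5), "F": (13, 5), "P": (14, 5),
}
SYMPATHETIC_SCHEDULE = {
    "SY": (0, 1), "HE": (0.5, 4), "ADR": (2, 5), "DMV": (3, 5), "LC": (5, 5),
    "AMY": (6, 5), "OB": (7, 5), "ESO": (8, 5), "SN": (9, 5), "NBM": (10, 5),
    "SKIN": (11, 5), "TrE": (12, 5), "CIN": (13, 5), "T": (14, 5),
    "F": (15, 5), "P": (16, 5),
}

SUBTYPE_NAMES = ("brain_first", "parasympathetic", "sympathetic")


def sequence_from_schedule(schedule: dict[str, tuple[float, float]],
                           catalog: RegionCatalog = CATALOG,
                           n_levels: int = 3) -> EventSequence:
    """Expand an onset schedule into a valid total event ordering."""
    onset_rank = {r: i for i, r in enumerate(schedule)}
    events = [(r, l) for r in catalog.regions for l in range(1, n_levels + 1)]
    events.sort(key=lambda e: (schedule[e[0]][0] + (e[1] - 1)
                               * schedule[e[0]][1], onset_rank[e[0]], e[1]))
    return EventSequence(events=tuple(events), regions=catalog.regions,
                         n_levels=n_levels)


def default_sequences(catalog: RegionCatalog = CATALOG
                      ) -> list[EventSequence]:
    """The three planted progression orderings (brain-first, para-, sympathetic)."""
    return [sequence_from_schedule(s, catalog) for s in
            (BRAIN_FIRST_SCHEDULE, PARASYMPATHETIC_SCHEDULE,
             SYMPATHETIC_SCHEDULE)]


@dataclass
class CohortSpec:
    """Generative description of a synthetic cohort.

    Defaults encode the study conditions the pipeline is built for: three
    planted sequences mixed at 51/27/22%, stages uniform over the full
    {0..48} range, measurement s.d. 0.5, and a diagnosis rule that labels
    75% of cases at or above stage 29 (and 1.7% below it) as diagnosed LBD.
    """

    n_cases: int
    sequences: list[EventSequence] = field(default_factory=default_sequences)
    fractions: tuple[float, ...] = (0.51, 0.27, 0.22)
    stage_law: str | np.ndarray = "uniform"
    mm_sd: float = 0.5
    diagnosis_threshold: int = 29
    p_diag_above: float = 0.75
    p_diag_below: float = 0.017
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.fractions):
            raise ValueError("one mixture fraction per planted sequence")
        if abs(sum(self.fractions) - 1.0) > 1e-9 or \
                min(self.fractions) <= 0:
            raise ValueError("fractions must be positive and sum to 1")
        for p in (self.p_diag_above, self.p_diag_below):
            if not 0 <= p <= 1:
                raise ValueError("diagnosis probabilities must be in [0, 1]")


def make_cohort(spec: CohortSpec,
                catalog: RegionCatalog = CATALOG
                ) -> tuple[PathologyMatrix, pd.DataFrame]:
    """Draw a cohort; returns (observed matrix, per-case ground truth).

    Per case: subtype ~ fractions; stage ~ stage law; true level per region
    is the planted sequence's expected level at that stage; the observed
    score is drawn from the measurement-model column of the true level; the
    diagnosis label is Bernoulli by planted stage. Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    K = spec.sequences[0].n_stages
    n_levels = spec.sequences[0].n_levels
    mm = build_measurement_model(spec.mm_sd, n_scores=n_levels + 1)

    subtype = rng.choice(len(spec.fractions), size=spec.n_cases,
                         p=spec.fractions)
    if isinstance(spec.stage_law, str):
        if spec.stage_law != "uniform":
            raise ValueError(f"unknown stage law: {spec.stage_law!r}")
        stage = rng.integers(0, K + 1, size=spec.n_cases)
    else:
        law = np.asarray(spec.stage_law, dtype=float)
        if len(law) != K + 1:
            raise ValueError(f"stage law must have {K + 1} entries")
        stage = rng.choice(K + 1, size=spec.n_cases, p=law / law.sum())

    # Expected-level lookup per (subtype, stage, region).
    levels = np.empty((len(spec.sequences), K + 1, len(catalog.regions)),
                      dtype=int)
    for s, seq in enumerate(spec.sequences):
        for t in range(K + 1):
            for j, r in enumerate(catalog.regions):
                levels[s, t, j] = seq.expected_level(t, r)
    true = levels[subtype, stage]                       # (n, R)

    u = rng.random(size=true.shape)
    cdf = np.cumsum(mm.prob, axis=0)                    # (score, level)
    observed = (u[:, :, None] > cdf.T[true]).sum(axis=2)

    p_dx = np.where(stage >= spec.diagnosis_threshold, spec.p_diag_above,
                    spec.p_diag_below)
    diagnosed = rng.random(spec.n_cases) < p_dx
    # Among diagnosed LBD, dementia phenotypes dominate (roughly 4:1).
    dementia = rng.random(spec.n_cases) < 0.8
    diagnosis = np.where(diagnosed, np.where(dementia, "PDD_DLB", "PD"),
                         "ILBD")
    age = np.clip(np.round(rng.normal(83, 9, spec.n_cases)), 50, 105)
    ad_flag = rng.random(spec.n_cases) < np.where(subtype == 0, 0.25, 0.03)

    ids = [f"case_{i:05d}" for i in range(spec.n_cases)]
    scores = pd.DataFrame(observed, index=pd.Index(ids, name="case_id"),
                          columns=list(catalog.regions))
    metadata = pd.DataFrame({"diagnosis": diagnosis, "ad_flag": ad_flag,
                             "age": age}, index=scores.index)
    truth = pd.DataFrame({"subtype": subtype, "stage": stage},
                         index=scores.index)
    for j, r in enumerate(catalog.regions):
        truth[f"true_{r}"] = true[:, j]
    matrix = PathologyMatrix(scores=scores, metadata=metadata,
                             mode="ordinal", capped=True, catalog=catalog)
    return matrix, truth


def make_isolated_cases(region: str, n: int, level: int = 1,
                        catalog: RegionCatalog = CATALOG) -> PathologyMatrix:
    """n cases positive only in ``region`` at ``level``; all else zero."""
    region = catalog.resolve(region)
    if not 1 <= level <= 3:
        raise ValueError("level must be 1..3")
    ids = [f"{region.lower()}_only_{i:03d}" for i in range(n)]
    scores = pd.DataFrame(0, index=pd.Index(ids, name="case_id"),
                          columns=list(catalog.regions))
    scores[region] = level
    metadata = pd.DataFrame({"diagnosis": "ILBD", "ad_flag": False,
                             "age": np.nan}, index=scores.index)
    return PathologyMatrix(scores=scores, metadata=metadata, mode="ordinal",
                           capped=True, catalog=catalog)
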