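"""Ordinal subtype-and-stage inference for pathology score matrices.

The model expresses a cross-sectional cohort as a mixture of monotone event
sequences. Each subtype is a total ordering of K = R x L events, where event
(r, l) means region r crossing from severity level l-1 to l; a subject at
stage t has undergone the first t events of its subtype's sequence. Observed
ordinal scores are linked to the underlying levels by a normal measurement
kernel (s.d. 0.5 by default) normalized over the level grid, and the subject
likelihood marginalizes over a uniform stage prior on {0..K} (stage 0 - no
event yet - included, since cohorts contain minimal-pathology cases).

Fitting maximizes the mixture log-likelihood sum_i log sum_c f_c P(X_i|S_c)
by greedy single-event repositioning inside an EM loop, with hierarchical
cluster-splitting initialization for multi-subtype models. Posterior
uncertainty over sequences is sampled with Metropolis-Hastings (single-event
moves to admissible positions, flat prior over valid sequences).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .catalog import CATALOG
from .io import PathologyMatrix

# ---------------------------------------------------------------------------
# Measurement model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeasurementModel:
    """p(observed score x | true level z) on a shared integer grid.

    Columns (fixed z) sum to 1; the kernel is a normal density with scale
    ``sd`` evaluated at the score grid and renormalized.
    """

    sd: float
    n_scores: int = 4
    prob: np.ndarray = field(default=None, repr=False)

    @property
    def levels(self) -> np.ndarray:
        return np.arange(self.n_scores)


def build_measurement_model(sd: float = 0.5,
                            n_scores: int = 4) -> MeasurementModel:
    """Build the normalized normal-kernel score/level confusion matrix."""
    if sd <= 0:
        raise ValueError(f"sd must be positive; got {sd}")
    grid = np.arange(n_scores, dtype=float)
    dens = norm.pdf(grid[:, None], loc=grid[None, :], scale=sd)
    prob = dens / dens.sum(axis=0, keepdims=True)
    return MeasurementModel(sd=sd, n_scores=n_scores, prob=prob)


# ---------------------------------------------------------------------------
# Event sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventSequence:
    """Total ordering of (region, level-transition) events for one subtype.

    ``events[t]`` is the (region, target level) transition occurring at stage
    t+1. Every region contributes one event per level 1..n_levels, and a
    region's levels appear in increasing order.
    """

    events: tuple[tuple[str, int], ...]
    regions: tuple[str, ...]
    n_levels: int = 3

    def __post_init__(self) -> None:
        expected = {(r, l) for r in self.regions
                    for l in range(1, self.n_levels + 1)}
        if set(self.events) != expected or len(self.events) != len(expected):
            raise ValueError("sequence must contain each (region, level) "
                             "event exactly once")
        pos = {e: i for i, e in enumerate(self.events)}
        for r in self.regions:
            for l in range(1, self.n_levels):
                if pos[(r, l)] > pos[(r, l + 1)]:
                    raise ValueError(
                        f"within-region order violated for {r}: level {l} "
                        f"after level {l + 1}")

    @property
    def n_stages(self) -> int:
        return len(self.events)

    def positions(self) -> dict[tuple[str, int], int]:
        return {e: i for i, e in enumerate(self.events)}

    def expected_level(self, stage: int, region: str) -> int:
        """Highest level reached by ``region`` within the first ``stage`` events."""
        if region not in self.regions:
            raise KeyError(f"unknown region: {region}")
        if not 0 <= stage <= self.n_stages:
            raise ValueError(f"stage must be 0..{self.n_stages}; got {stage}")
        level = 0
        for r, l in self.events[:stage]:
            if r == region:
                level = max(level, l)
        return level

    def expected_levels(self, stage: int) -> dict[str, int]:
        return {r: self.expected_level(stage, r) for r in self.regions}

    def subset(self, regions: list[str]) -> "EventSequence":
        """Restrict to a region subset, preserving relative event order."""
        keep = [e for e in self.events if e[0] in regions]
        return EventSequence(events=tuple(keep), regions=tuple(regions),
                             n_levels=self.n_levels)

    # -- numeric codec ------------------------------------------------------
    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        idx = {r: i for i, r in enumerate(self.regions)}
        reg = np.array([idx[r] for r, _ in self.events], dtype=np.int64)
        lev = np.array([l for _, l in self.events], dtype=np.int64)
        return reg, lev

    @classmethod
    def from_arrays(cls, reg: np.ndarray, lev: np.ndarray,
                    regions: tuple[str, ...],
                    n_levels: int = 3) -> "EventSequence":
        events = tuple((regions[r], int(l)) for r, l in zip(reg, lev))
        return cls(events=events, regions=tuple(regions), n_levels=n_levels)


def random_sequence(regions: tuple[str, ...], n_levels: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform draw over valid sequences (as (reg, lev) arrays).

    A uniform permutation of all events is drawn, then each region's slots
    are relabelled so its levels ascend; every valid sequence corresponds to
    the same number of raw permutations, so the result is uniform.
    """
    R = len(regions)
    codes = rng.permutation(R * n_levels)
    reg = codes // n_levels
    lev = np.empty_like(reg)
    for r in range(R):
        slots = np.flatnonzero(reg == r)
        lev[slots] = np.arange(1, n_levels + 1)
    return reg.astype(np.int64), lev.astype(np.int64)


def enumerate_sequences(regions: tuple[str, ...], n_levels: int):
    """Exhaustively yield every valid EventSequence (tiny panels only)."""
    events = [(r, l) for r in regions for l in range(1, n_levels + 1)]
    if len(events) > 10:
        raise ValueError("exhaustive enumeration is for tiny panels only")
    for perm in itertools.permutations(events):
        pos = {e: i for i, e in enumerate(perm)}
        if all(pos[(r, l)] < pos[(r, l + 1)] for r in regions
               for l in range(1, n_levels)):
            yield EventSequence(events=perm, regions=tuple(regions),
                                n_levels=n_levels)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _case_level_logp(X: np.ndarray, mm: MeasurementModel) -> np.ndarray:
    """log p(x_ir | level z) for every case, region, level; (n, R, L+1)."""
    return np.log(mm.prob)[X]


def _stage_logliks(logp: np.ndarray, reg: np.ndarray,
                   lev: np.ndarray) -> np.ndarray:
    """Per-case log-likelihood at each stage 0..K; shape (n, K+1)."""
    L0 = logp[:, :, 0].sum(axis=1)
    delta = logp[:, reg, lev] - logp[:, reg, lev - 1]
    return np.concatenate(
        [L0[:, None], L0[:, None] + np.cumsum(delta, axis=1)], axis=1)


def _log_marginal(logp: np.ndarray, reg: np.ndarray,
                  lev: np.ndarray) -> np.ndarray:
    """log P(X_i | S) marginalized over the uniform stage prior; (n,)."""
    M = _stage_logliks(logp, reg, lev)
    return logsumexp(M, axis=1) - np.log(M.shape[1])


def subject_marginal_likelihood(scores, seq: EventSequence,
                                mm: MeasurementModel) -> float:
    """Marginal likelihood of one subject's score row under a sequence.

    ``scores`` maps region -> observed score (dict or pandas Series over the
    sequence's regions). The stage prior is uniform over {0..K}.
    """
    x = np.array([[int(scores[r]) for r in seq.regions]])
    if (x < 0).any() or (x >= mm.n_scores).any():
        raise ValueError(f"scores must lie in 0..{mm.n_scores - 1}")
    logp = _case_level_logp(x, mm)
    reg, lev = seq.to_arrays()
    return float(np.exp(_log_marginal(logp, reg, lev)[0]))


# ---------------------------------------------------------------------------
# Greedy sequence optimization
# ---------------------------------------------------------------------------


def _admissible_insertions(reg: np.ndarray, lev: np.ndarray,
                           e: int) -> tuple[list[int], list[int]]:
    """Candidate insertion slots for event ``e`` after its removal.

    Returns (remaining-order index list, admissible insertion positions):
    positions strictly after the same region's previous level and no later
    than its next level, so the within-region ordering is preserved.
    """
    K = len(reg)
    rem = [i for i in range(K) if i != e]
    r, l = reg[e], lev[e]
    lo, hi = 0, K - 1
    for j, i in enumerate(rem):
        if reg[i] == r and lev[i] == l - 1:
            lo = j + 1
        if reg[i] == r and lev[i] == l + 1:
            hi = j
    return rem, list(range(lo, hi + 1))


def _insertion_scores(logp: np.ndarray, w: np.ndarray, reg: np.ndarray,
                      lev: np.ndarray, e: int,
                      slots: list[int]) -> np.ndarray:
    """Weighted objective for re-inserting event ``e`` at each slot.

    With the event removed, inserting it at slot j leaves stage likelihoods
    for stages <= j unchanged and multiplies those for stages > j by the
    event's own likelihood ratio, so every insertion position is scored from
    one prefix and one suffix cumulative sum - O(nK) for all candidates.
    """
    L0 = logp[:, :, 0].sum(axis=1)
    delta = logp[:, reg, lev] - logp[:, reg, lev - 1]   # (n, K)
    de = delta[:, e]
    drem = np.delete(delta, e, axis=1)
    Mrem = np.concatenate(
        [L0[:, None], L0[:, None] + np.cumsum(drem, axis=1)], axis=1)
    mx = Mrem.max(axis=1) + np.maximum(de, 0.0)
    E = np.exp(Mrem - mx[:, None])                      # (n, K)
    pre = np.cumsum(E, axis=1)
    suf = pre[:, -1:] - pre + E                         # suf[:, j] = sum_{t>=j}
    s = np.asarray(slots)
    tot = pre[:, s] + np.exp(de)[:, None] * suf[:, s]
    ll = np.log(tot) + mx[:, None] - np.log(len(reg) + 1)
    return w @ ll


def _greedy_pass(logp: np.ndarray, w: np.ndarray, reg: np.ndarray,
                 lev: np.ndarray, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """One sweep of single-event repositioning; accepts only improvements."""
    K = len(reg)
    improved = False
    best = float(w @ _log_marginal(logp, reg, lev))
    for e in rng.permutation(K):
        rem, slots = _admissible_insertions(reg, lev, e)
        if len(slots) == 1:
            continue
        vals = _insertion_scores(logp, w, reg, lev, e, slots)
        k = int(np.argmax(vals))
        if vals[k] > best + 1e-12:
            j = slots[k]
            order = np.array(rem[:j] + [e] + rem[j:], dtype=np.int64)
            reg, lev = reg[order], lev[order]
            best = float(vals[k])
            improved = True
    return reg, lev, best, improved


def _optimize_sequence(logp, w, reg, lev, rng, max_passes: int
                       ) -> tuple[np.ndarray, np.ndarray, float]:
    best = float(w @ _log_marginal(logp, reg, lev))
    for _ in range(max_passes):
        reg, lev, best, improved = _greedy_pass(logp, w, reg, lev, rng)
        if not improved:
            break
    return reg, lev, best


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------


@dataclass
class FitConfig:
    """Tunable fitting controls.

    ``n_starts`` random initializations each receive one greedy pass; the
    best ``n_refine`` are run to convergence. ``mcmc_iters`` defaults to a
    long chain for production runs; tests use shorter chains.
    """

    n_starts: int = 25
    n_refine: int = 5
    max_passes: int = 30
    em_max_iter: int = 50
    em_tol: float = 1e-4
    mcmc_iters: int = 100_000
    split_tries: int = 2
    n_bipartitions: int = 2
    n_levels: int = 3
    sd: float = 0.5


@dataclass
class SubtypeModel:
    """Fitted mixture of event sequences.

    ``loglik_trace`` records the mixture log-likelihood across EM iterations
    (non-decreasing by construction). ``mcmc_orders`` stores, per posterior
    draw and subtype, the event index occupying each sequence position.
    """

    sequences: list[EventSequence]
    fractions: np.ndarray
    log_likelihood: float
    loglik_trace: np.ndarray
    regions: tuple[str, ...]
    n_levels: int
    mm: MeasurementModel
    mcmc_orders: np.ndarray | None = None      # (draws, c, K) int16
    mcmc_fractions: np.ndarray | None = None   # (draws, c)
    mcmc_loglik: np.ndarray | None = None
    mcmc_acceptance: float | None = None

    @property
    def n_subtypes(self) -> int:
        return len(self.sequences)

    @property
    def n_stages(self) -> int:
        return len(self.regions) * self.n_levels

    @property
    def mcmc_samples(self):
        """Posterior draws as (list of EventSequence, fractions) pairs."""
        if self.mcmc_orders is None:
            return []
        events = [(r, l) for r in self.regions
                  for l in range(1, self.n_levels + 1)]
        out = []
        for d in range(self.mcmc_orders.shape[0]):
            seqs = []
            for c in range(self.n_subtypes):
                ev = tuple(events[i] for i in self.mcmc_orders[d, c])
                seqs.append(EventSequence(events=ev, regions=self.regions,
                                          n_levels=self.n_levels))
            out.append((seqs, self.mcmc_fractions[d]))
        return out


def _prepare(matrix: PathologyMatrix, cfg: FitConfig):
    matrix.require_severity("subtype inference")
    X = matrix.scores.to_numpy()
    if (X > cfg.n_levels).any():
        raise ValueError(
            f"scores above {cfg.n_levels} present; apply cap_scores (or use "
            "a 5-level configuration) before fitting")
    mm = build_measurement_model(cfg.sd, n_scores=cfg.n_levels + 1)
    logp = _case_level_logp(X, mm)
    return X, mm, logp


def _fit_single(logp, w, cfg: FitConfig, rng, regions,
                init: tuple[np.ndarray, np.ndarray] | None = None
                ) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted single-sequence fit: multi-start greedy ascent."""
    n_levels = cfg.n_levels
    cands = []
    if init is not None:
        cands.append(init)
    for _ in range(cfg.n_starts):
        cands.append(random_sequence(regions, n_levels, rng))
    scored = []
    for reg, lev in cands:
        reg, lev, val, _ = _greedy_pass(logp, w, reg, lev, rng)
        scored.append((val, reg, lev))
    scored.sort(key=lambda t: -t[0])
    best = (-np.inf, None, None)
    for val, reg, lev in scored[:max(1, cfg.n_refine)]:
        reg, lev, val = _optimize_sequence(logp, w, reg, lev, rng,
                                           cfg.max_passes)
        if val > best[0]:
            best = (val, reg, lev)
    return best[1], best[2], best[0]


def _mixture_loglik(logp, seqs, fractions):
    """(total mixture loglik, per-case per-cluster log P matrix)."""
    mat = np.column_stack([_log_marginal(logp, reg, lev)
                           for reg, lev in seqs])
    total = float(logsumexp(mat + np.log(fractions), axis=1).sum())
    return total, mat


def _em(logp, seqs, fractions, cfg: FitConfig, rng
        ) -> tuple[list, np.ndarray, float, list[float]]:
    """Generalized EM: soft responsibilities, one greedy pass per M-step."""
    trace = []
    total, mat = _mixture_loglik(logp, seqs, fractions)
    trace.append(total)
    for _ in range(cfg.em_max_iter):
        logr = mat + np.log(fractions)
        resp = np.exp(logr - logsumexp(logr, axis=1, keepdims=True))
        fractions = resp.mean(axis=0)
        fractions = np.clip(fractions, 1e-10, None)
        fractions /= fractions.sum()
        new_seqs = []
        for c, (reg, lev) in enumerate(seqs):
            reg, lev, _, _ = _greedy_pass(logp, resp[:, c], reg, lev, rng)
            new_seqs.append((reg, lev))
        seqs = new_seqs
        total, mat = _mixture_loglik(logp, seqs, fractions)
        if trace and total < trace[-1] - 1e-6:
            raise RuntimeError("EM log-likelihood decreased; internal error")
        converged = total - trace[-1] < cfg.em_tol
        trace.append(total)
        if converged:
            break
    # Polish: run each cluster's sequence to full greedy convergence under
    # the final responsibilities (still an ascent step, so the trace stays
    # monotone), iterating with fraction updates until no further gain.
    for _ in range(cfg.em_max_iter):
        logr = mat + np.log(fractions)
        resp = np.exp(logr - logsumexp(logr, axis=1, keepdims=True))
        fractions = np.clip(resp.mean(axis=0), 1e-10, None)
        fractions /= fractions.sum()
        seqs = [_optimize_sequence(logp, resp[:, c], reg, lev, rng,
                                   cfg.max_passes)[:2]
                for c, (reg, lev) in enumerate(seqs)]
        total, mat = _mixture_loglik(logp, seqs, fractions)
        if total < trace[-1] - 1e-6:
            raise RuntimeError("EM log-likelihood decreased; internal error")
        gain = total - trace[-1]
        trace.append(total)
        if gain < cfg.em_tol:
            break
    return seqs, fractions, total, trace


def _split_init(logp, seqs, fractions, mat, cfg, rng, regions):
    """Candidate initializations for c+1 clusters by splitting one cluster."""
    resp = np.exp(mat + np.log(fractions)
                  - logsumexp(mat + np.log(fractions), axis=1, keepdims=True))
    hard = resp.argmax(axis=1)
    sizes = np.bincount(hard, minlength=len(seqs))
    order = np.argsort(-sizes)
    small = replace(cfg, n_starts=max(3, cfg.n_starts // 5), n_refine=2)
    inits = []
    for c in order[:max(1, cfg.split_tries)]:
        members = np.flatnonzero(hard == c)
        if len(members) < 4:
            continue
        for _ in range(max(1, cfg.n_bipartitions)):
            members = rng.permutation(members)
            halves = (members[: len(members) // 2],
                      members[len(members) // 2:])
            new_pair = []
            for half in halves:
                w = np.zeros(logp.shape[0])
                w[half] = 1.0
                reg, lev, _ = _fit_single(logp, w, small, rng, regions,
                                          init=seqs[c])
                new_pair.append((reg, lev))
            cand_seqs = [s for k, s in enumerate(seqs) if k != c] + new_pair
            cand_frac = np.append(np.delete(fractions, c),
                                  [fractions[c] / 2] * 2)
            inits.append((cand_seqs, cand_frac / cand_frac.sum()))
    return inits


def _kmeans_init(X, logp, c: int, cfg: FitConfig, rng, regions):
    """Pattern-based initialization: k-means on burden-normalized rows.

    Normalizing each row by its total burden separates progression patterns
    rather than stages, which makes a reliable complement to the random
    bipartition splits.
    """
    from sklearn.cluster import KMeans

    Xn = X / np.maximum(X.sum(axis=1, keepdims=True), 1)
    labels = KMeans(c, n_init=5,
                    random_state=int(rng.integers(2**31))).fit(Xn).labels_
    if len(np.unique(labels)) < c:
        return None
    small = replace(cfg, n_starts=max(3, cfg.n_starts // 5), n_refine=2)
    seqs = []
    for k in range(c):
        w = (labels == k).astype(float)
        reg, lev, _ = _fit_single(logp, w, small, rng, regions)
        seqs.append((reg, lev))
    frac = np.bincount(labels, minlength=c).astype(float)
    return seqs, frac / frac.sum()


def _fit_path(matrix: PathologyMatrix, n_subtypes: int, cfg: FitConfig,
              rng: np.random.Generator) -> list[SubtypeModel]:
    """Fit 1..n_subtypes hierarchically; returns one model per count."""
    X, mm, logp = _prepare(matrix, cfg)
    n = X.shape[0]
    if n < n_subtypes * 5:
        raise ValueError(f"need at least {n_subtypes * 5} cases to fit "
                         f"{n_subtypes} subtypes; got {n}")
    regions = tuple(matrix.regions)
    w = np.ones(n)
    reg, lev, ll = _fit_single(logp, w, cfg, rng, regions)
    if np.all(X == X[0]):
        import warnings
        warnings.warn("degenerate input: all score rows identical; "
                      "mixture fractions may collapse")
    models = []
    seqs, fractions = [(reg, lev)], np.array([1.0])
    total, mat = _mixture_loglik(logp, seqs, fractions)
    models.append(_pack(seqs, fractions, total, [ll, total], regions, cfg, mm))
    for c in range(2, n_subtypes + 1):
        inits = _split_init(logp, seqs, fractions, mat, cfg, rng, regions)
        km = _kmeans_init(X, logp, c, cfg, rng, regions)
        if km is not None:
            inits.append(km)
        best = None
        for init_seqs, init_frac in inits:
            out = _em(logp, init_seqs, init_frac, cfg, rng)
            if best is None or out[2] > best[2]:
                best = out
        if best is None:  # clusters too small to split further
            break
        seqs, fractions, total, trace = best
        total, mat = _mixture_loglik(logp, seqs, fractions)
        models.append(_pack(seqs, fractions, total, trace, regions, cfg, mm))
    return models


def _pack(seqs, fractions, total, trace, regions, cfg, mm) -> SubtypeModel:
    sequences = [EventSequence.from_arrays(reg, lev, regions, cfg.n_levels)
                 for reg, lev in seqs]
    return SubtypeModel(sequences=sequences, fractions=np.asarray(fractions),
                        log_likelihood=total, loglik_trace=np.asarray(trace),
                        regions=regions, n_levels=cfg.n_levels, mm=mm)


def fit_subtypes(matrix: PathologyMatrix, n_subtypes: int,
                 cfg: FitConfig | None = None,
                 seed: int | np.random.Generator = 0,
                 run_mcmc: bool = True) -> SubtypeModel:
    """Fit an ``n_subtypes`` mixture of event sequences to a capped matrix.

    Returns the fitted model with MCMC posterior samples attached (unless
    ``run_mcmc=False``). All randomness flows from ``seed``.
    """
    if n_subtypes < 1:
        raise ValueError("n_subtypes must be >= 1")
    cfg = cfg or FitConfig()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    model = _fit_path(matrix, n_subtypes, cfg, rng)[-1]
    if model.n_subtypes != n_subtypes:
        raise RuntimeError(f"could not support {n_subtypes} subtypes on "
                           f"{matrix.n_cases} cases")
    if run_mcmc and cfg.mcmc_iters > 0:
        _run_mcmc(model, matrix, cfg, rng)
    return model


def _run_mcmc(model: SubtypeModel, matrix: PathologyMatrix, cfg: FitConfig,
              rng: np.random.Generator) -> None:
    """Metropolis-Hastings over sequences; fractions fixed at their EM fit.

    Proposal: pick a subtype and an event uniformly, move the event to a
    uniformly chosen admissible position (within-region order preserved).
    The admissible-slot count for an event is invariant under its own move,
    so the proposal is symmetric and a flat prior over valid sequences makes
    the acceptance ratio a likelihood ratio.
    """
    _, _, logp = _prepare(matrix, cfg)
    seqs = [s.to_arrays() for s in model.sequences]
    fractions = model.fractions
    K, nc = model.n_stages, model.n_subtypes
    mat = np.column_stack([_log_marginal(logp, reg, lev)
                           for reg, lev in seqs])
    logf = np.log(fractions)
    cur = float(logsumexp(mat + logf, axis=1).sum())
    iters = cfg.mcmc_iters
    orders = np.empty((iters, nc, K), dtype=np.int16)
    lls = np.empty(iters)
    # event code at position p -> canonical event index (region-major)
    def codes(reg, lev):
        return (reg * model.n_levels + (lev - 1)).astype(np.int16)
    accepted = 0
    for it in range(iters):
        c = int(rng.integers(nc))
        reg, lev = seqs[c]
        e = int(rng.integers(K))
        rem, slots = _admissible_insertions(reg, lev, e)
        j = slots[int(rng.integers(len(slots)))]
        order = np.array(rem[:j] + [e] + rem[j:], dtype=np.int64)
        nreg, nlev = reg[order], lev[order]
        col = _log_marginal(logp, nreg, nlev)
        newmat = mat.copy()
        newmat[:, c] = col
        new = float(logsumexp(newmat + logf, axis=1).sum())
        if np.log(rng.random()) < new - cur:
            seqs[c] = (nreg, nlev)
            mat, cur = newmat, new
            accepted += 1
        for k in range(nc):
            orders[it, k] = codes(*seqs[k])
        lls[it] = cur
    model.mcmc_orders = orders
    model.mcmc_fractions = np.tile(fractions, (iters, 1))
    model.mcmc_loglik = lls
    model.mcmc_acceptance = accepted / max(1, iters)


# ---------------------------------------------------------------------------
# Cross-validated model selection
# ---------------------------------------------------------------------------


def _predictive_loglik(logp: np.ndarray, model: SubtypeModel,
                       max_draws: int = 200) -> float:
    """Total log-likelihood under the posterior predictive (thinned draws)."""
    if model.mcmc_orders is None or model.mcmc_orders.shape[0] == 0:
        seqs = [s.to_arrays() for s in model.sequences]
        return _mixture_loglik(logp, seqs, model.fractions)[0]
    draws = model.mcmc_orders
    step = max(1, draws.shape[0] // max_draws)
    thin = draws[::step]
    logf = np.log(model.fractions)
    L = np.empty((thin.shape[0], logp.shape[0]))
    nl = model.n_levels
    for d in range(thin.shape[0]):
        mat = np.column_stack(
            [_log_marginal(logp, thin[d, k] // nl, thin[d, k] % nl + 1)
             for k in range(model.n_subtypes)])
        L[d] = logsumexp(mat + logf, axis=1)
    return float((logsumexp(L, axis=0) - np.log(L.shape[0])).sum())


def cross_validate(matrix: PathologyMatrix, max_subtypes: int,
                   folds: int = 10, cfg: FitConfig | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Out-of-fold likelihood and CVIC for 1..max_subtypes mixtures.

    Folds are assigned by stratified random dealing on total pathology
    burden (seeded). For each candidate subtype count the model is fitted on
    the training folds (hierarchically, so all counts share one fitting path
    per fold) and the held-out fold is scored under the training posterior:
    a training-side MCMC chain is run and the held-out log-likelihood is
    averaged over thinned sequence draws. Scoring the single maximum-
    likelihood sequence instead systematically favours extra subtypes,
    because a duplicate subtype mimics exactly this posterior averaging;
    the predictive form removes that artifact. CVIC(c) = -2 x the total
    out-of-fold predictive log-likelihood; the row with the lowest CVIC is
    the recommended model (``.attrs["selected"]``).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    cfg = cfg or FitConfig()
    rng = np.random.default_rng(seed)
    n = matrix.n_cases
    if n < 2 * folds:
        raise ValueError(f"{folds} folds need at least {2 * folds} cases")
    burden = matrix.scores.sum(axis=1).to_numpy()
    order = np.lexsort((rng.random(n), burden))
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds
    oof = np.full((folds, max_subtypes), np.nan)
    for f in range(folds):
        train = matrix.scores.index[fold_of != f]
        test = matrix.scores.index[fold_of == f]
        tr = replace(matrix, scores=matrix.scores.loc[train],
                     metadata=matrix.metadata.loc[train])
        te = replace(matrix, scores=matrix.scores.loc[test],
                     metadata=matrix.metadata.loc[test])
        models = _fit_path(tr, max_subtypes, cfg,
                           np.random.default_rng(rng.integers(2**31)))
        _, _, logp_te = _prepare(te, cfg)
        for m in models:
            _run_mcmc(m, tr, cfg, np.random.default_rng(rng.integers(2**31)))
            oof[f, m.n_subtypes - 1] = _predictive_loglik(logp_te, m)
            m.mcmc_orders = m.mcmc_fractions = m.mcmc_loglik = None
    table = pd.DataFrame({
        "n_subtypes": np.arange(1, max_subtypes + 1),
        "oof_loglik": np.nansum(oof, axis=0),
        "cvic": -2 * np.nansum(oof, axis=0),
    })
    table["fold_oof"] = [oof[:, c].tolist() for c in range(max_subtypes)]
    table.attrs["selected"] = int(table.loc[table["cvic"].idxmin(),
                                            "n_subtypes"])
    table.attrs["fold_of"] = fold_of
    return table


# ---------------------------------------------------------------------------
# Subject allocation and positional variance
# ---------------------------------------------------------------------------


@dataclass
class SubjectAssignment:
    """Per-case subtype and stage allocation.

    ``table`` has one row per case (``subtype``, ``stage``); the posterior
    arrays preserve full uncertainty. Stage MAP ties break toward the lower
    stage (conservative staging of ambiguous cases).
    """

    table: pd.DataFrame
    subtype_posterior: np.ndarray    # (n, c)
    stage_posterior: np.ndarray      # (n, K+1), under the assigned subtype


def assign_subjects(model: SubtypeModel,
                    matrix: PathologyMatrix) -> SubjectAssignment:
    """Allocate each case to its maximum-posterior subtype and stage."""
    if tuple(matrix.regions) != model.regions:
        raise ValueError("region mismatch between model and matrix")
    cfg = FitConfig(n_levels=model.n_levels, sd=model.mm.sd)
    _, _, logp = _prepare(matrix, cfg)
    seqs = [s.to_arrays() for s in model.sequences]
    mat = np.column_stack([_log_marginal(logp, reg, lev)
                           for reg, lev in seqs])
    logpost = mat + np.log(model.fractions)
    subtype_post = np.exp(logpost - logsumexp(logpost, axis=1, keepdims=True))
    subtype = subtype_post.argmax(axis=1)
    n, K = logp.shape[0], model.n_stages
    stage_post = np.empty((n, K + 1))
    stage = np.empty(n, dtype=int)
    for c in range(model.n_subtypes):
        members = np.flatnonzero(subtype == c)
        if members.size == 0:
            continue
        M = _stage_logliks(logp[members], *seqs[c])
        stage_post[members] = np.exp(M - logsumexp(M, axis=1, keepdims=True))
        stage[members] = M.argmax(axis=1)  # argmax takes the first (lowest)
    table = pd.DataFrame({
        "subtype": subtype,
        "stage": stage,
        "subtype_prob": subtype_post.max(axis=1),
    }, index=matrix.scores.index)
    return SubjectAssignment(table=table, subtype_posterior=subtype_post,
                             stage_posterior=stage_post)


def positional_variance(model: SubtypeModel) -> list[pd.DataFrame]:
    """Posterior event-by-position frequency matrix per subtype.

    Rows are events (region-major, level-minor order), columns sequence
    positions 0..K-1; each row sums to 1 over positions. Computed from the
    stored MCMC draws.
    """
    if model.mcmc_orders is None or model.mcmc_orders.shape[0] == 0:
        raise ValueError("model has no MCMC samples")
    draws, nc, K = model.mcmc_orders.shape
    events = [f"{r}:{l}" for r in model.regions
              for l in range(1, model.n_levels + 1)]
    out = []
    for c in range(nc):
        counts = np.zeros((K, K))
        pos = np.arange(K)
        for d in range(draws):
            counts[model.mcmc_orders[d, c], pos] += 1
        out.append(pd.DataFrame(counts / draws, index=events,
                                columns=pos))
    return out
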