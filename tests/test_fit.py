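"""Fitting, model selection, allocation and positional variance.

Heavy recovery checks live in the acceptance suite; here the fits run on
tiny panels where exhaustive oracles exist, plus the default cohort shared
via a session fixture.
"""

import numpy as np
import pandas as pd
import pytest

import lewyprog as lp
from lewyprog.io import PathologyMatrix
from lewyprog.sustain import (EventSequence, FitConfig, _mixture_loglik,
                              _prepare, enumerate_sequences)


def toy_matrix(truths: np.ndarray, regions, seed=0, sd=0.5, n_levels=3):
    """Observe planted true levels through the measurement kernel."""
    rng = np.random.default_rng(seed)
    mm = lp.build_measurement_model(sd, n_scores=n_levels + 1)
    cdf = np.cumsum(mm.prob, axis=0)
    u = rng.random(truths.shape)
    observed = (u[:, :, None] > cdf.T[truths]).sum(axis=2)
    scores = pd.DataFrame(observed,
                          index=pd.Index([f"t{i}" for i in range(len(truths))],
                                         name="case_id"),
                          columns=list(regions))
    return PathologyMatrix(scores=scores,
                           metadata=pd.DataFrame(index=scores.index),
                           capped=True, catalog=None)


class TestExhaustiveOracle:
    def test_two_region_single_level_recovers_planted_order(self):
        """With 2 events there are exactly 2 sequences; the fit must pick
        the one the exhaustive scan ranks first."""
        regions = ("A", "B")
        seq_ab = EventSequence(events=(("A", 1), ("B", 1)), regions=regions,
                               n_levels=1)
        # planted: A before B, stages uniform over 0..2
        rng = np.random.default_rng(5)
        stages = rng.integers(0, 3, size=300)
        truths = np.array([[seq_ab.expected_level(t, r) for r in regions]
                           for t in stages])
        matrix = toy_matrix(truths, regions, seed=6, n_levels=1)
        cfg = FitConfig(n_levels=1, mcmc_iters=0, n_starts=4)
        model = lp.fit_subtypes(matrix, 1, cfg=cfg, seed=0, run_mcmc=False)
        # exhaustive oracle over both valid sequences
        _, _, logp = _prepare(matrix, cfg)
        best = max(enumerate_sequences(regions, 1),
                   key=lambda s: _mixture_loglik(
                       logp, [s.to_arrays()], np.array([1.0]))[0])
        assert model.sequences[0].events == best.events == (("A", 1),
                                                            ("B", 1))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_region_two_level_global_optimum(self, seed):
        """fit_subtypes(1) finds the global maximum over all 6 valid orders."""
        regions = ("A", "B")
        rng = np.random.default_rng(seed)
        planted = EventSequence(
            events=(("A", 1), ("B", 1), ("A", 2), ("B", 2)),
            regions=regions, n_levels=2)
        stages = rng.integers(0, 5, size=200)
        truths = np.array([[planted.expected_level(t, r) for r in regions]
                           for t in stages])
        matrix = toy_matrix(truths, regions, seed=seed + 10, n_levels=2)
        cfg = FitConfig(n_levels=2, mcmc_iters=0, n_starts=6)
        model = lp.fit_subtypes(matrix, 1, cfg=cfg, seed=seed,
                                run_mcmc=False)
        _, _, logp = _prepare(matrix, cfg)
        lls = {s.events: _mixture_loglik(logp, [s.to_arrays()],
                                         np.array([1.0]))[0]
               for s in enumerate_sequences(regions, 2)}
        best_events = max(lls, key=lls.get)
        assert model.sequences[0].events == best_events
        assert model.log_likelihood == pytest.approx(lls[best_events])


class TestSingleSequenceRecovery:
    def test_planted_48_event_order_recovered(self):
        """Kendall tau >= 0.8 between fitted and planted full-panel order."""
        from scipy.stats import kendalltau
        planted = lp.default_sequences()[0]
        spec = lp.CohortSpec(n_cases=200, sequences=[planted],
                             fractions=(1.0,), seed=11)
        matrix, _ = lp.make_cohort(spec)
        model = lp.fit_subtypes(matrix, 1, cfg=FitConfig(mcmc_iters=0),
                                seed=1, run_mcmc=False)
        pa, pb = planted.positions(), model.sequences[0].positions()
        ev = list(pa)
        tau = kendalltau([pa[e] for e in ev], [pb[e] for e in ev]).statistic
        assert tau >= 0.8


@pytest.fixture(scope="module")
def fitted_two(cohort300):
    _, matrix, _ = cohort300
    sub = PathologyMatrix(scores=matrix.scores.iloc[:150].copy(),
                          metadata=matrix.metadata.iloc[:150].copy(),
                          capped=True)
    cfg = FitConfig(mcmc_iters=3000, n_starts=8)
    return lp.fit_subtypes(sub, 2, cfg=cfg, seed=4)


@pytest.fixture(scope="module")
def small_model(cohort300):
    _, matrix, _ = cohort300
    sub = PathologyMatrix(scores=matrix.scores.iloc[:150].copy(),
                          metadata=matrix.metadata.iloc[:150].copy(),
                          capped=True)
    model = lp.fit_subtypes(sub, 2, cfg=FitConfig(mcmc_iters=0),
                            seed=4, run_mcmc=False)
    return model, sub


class TestEMAndMCMCInvariants:
    def test_em_trace_monotone(self, fitted_two):
        trace = fitted_two.loglik_trace
        assert (np.diff(trace) >= -1e-6).all()

    def test_fractions_simplex(self, fitted_two):
        f = fitted_two.fractions
        assert (f > 0).all() and f.sum() == pytest.approx(1.0)

    def test_every_mcmc_draw_satisfies_ordering_constraint(self, fitted_two):
        orders = fitted_two.mcmc_orders  # (draws, c, K) event codes
        n_levels = fitted_two.n_levels
        reg = orders // n_levels
        lev = orders % n_levels
        K = orders.shape[-1]
        pos = np.empty_like(orders)
        idx = np.argsort(orders, axis=-1, kind="stable")
        # position of each event code
        for d in range(orders.shape[0]):
            for c in range(orders.shape[1]):
                pos[d, c, orders[d, c]] = np.arange(K, dtype=orders.dtype)
        pos = pos.reshape(orders.shape[0], orders.shape[1], -1, n_levels)
        assert (np.diff(pos, axis=-1) > 0).all()

    def test_mcmc_acceptance_rate_sane(self, fitted_two):
        assert 0.0 < fitted_two.mcmc_acceptance < 1.0

    def test_positional_variance_rows_sum_to_one(self, fitted_two):
        pv = lp.positional_variance(fitted_two)
        assert len(pv) == 2
        for m in pv:
            np.testing.assert_allclose(m.sum(axis=1), 1.0)

    def test_positional_variance_degenerate_chain(self, fitted_two):
        clone = lp.SubtypeModel(
            sequences=fitted_two.sequences, fractions=fitted_two.fractions,
            log_likelihood=fitted_two.log_likelihood,
            loglik_trace=fitted_two.loglik_trace,
            regions=fitted_two.regions, n_levels=fitted_two.n_levels,
            mm=fitted_two.mm,
            mcmc_orders=fitted_two.mcmc_orders[:1],
            mcmc_fractions=fitted_two.mcmc_fractions[:1])
        pv = lp.positional_variance(clone)
        for m in pv:
            vals = m.to_numpy()
            assert set(np.unique(vals)) <= {0.0, 1.0}
            assert (vals.sum(axis=1) == 1).all()


class TestAssignment:
    def test_extreme_subjects(self, small_model):
        model, sub = small_model
        extremes = pd.DataFrame(
            [[0] * 16, [3] * 16],
            index=pd.Index(["none", "full"], name="case_id"),
            columns=list(lp.REGIONS))
        m = PathologyMatrix(scores=extremes,
                            metadata=pd.DataFrame(index=extremes.index),
                            capped=True)
        assign = lp.assign_subjects(model, m)
        assert assign.table.loc["none", "stage"] == 0
        assert assign.table.loc["full", "stage"] == 48
        np.testing.assert_allclose(assign.subtype_posterior.sum(axis=1), 1.0)
        np.testing.assert_allclose(assign.stage_posterior.sum(axis=1), 1.0)

    def test_region_mismatch_rejected(self, small_model):
        model, sub = small_model
        with pytest.raises(ValueError, match="region"):
            lp.assign_subjects(model, sub.select_regions(
                list(lp.CATALOG.cns10)))

    def test_staging_tracks_planted_stage(self, cohort300):
        """A subject planted deep into one sequence is staged nearby."""
        spec, matrix, truth = cohort300
        model = lp.SubtypeModel(
            sequences=spec.sequences,
            fractions=np.asarray(spec.fractions),
            log_likelihood=0.0, loglik_trace=np.zeros(1),
            regions=tuple(matrix.regions), n_levels=3,
            mm=lp.build_measurement_model(0.5))
        assign = lp.assign_subjects(model, matrix)
        deep = truth["stage"] >= 10
        err = (assign.table.loc[deep, "stage"]
               - truth.loc[deep, "stage"]).abs()
        assert err.median() <= 3
        agree = (assign.table.loc[deep, "subtype"]
                 == truth.loc[deep, "subtype"]).mean()
        assert agree >= 0.8


class TestCrossValidation:
    def test_partition_property(self, cohort300):
        _, matrix, _ = cohort300
        sub = PathologyMatrix(scores=matrix.scores.iloc[:173].copy(),
                              metadata=matrix.metadata.iloc[:173].copy(),
                              capped=True)
        cfg = FitConfig(mcmc_iters=200, n_starts=2, n_refine=1,
                        em_max_iter=3)
        cv = lp.cross_validate(sub, 1, folds=10, cfg=cfg, seed=9)
        fold_of = cv.attrs["fold_of"]
        assert len(fold_of) == 173
        counts = np.bincount(fold_of, minlength=10)
        assert counts.sum() == 173 and (counts >= 17).all()

    def test_single_subtype_cohort_prefers_one(self):
        """CVIC(1) <= CVIC(2) within one Monte-Carlo fold s.e."""
        planted = lp.default_sequences()[0]
        spec = lp.CohortSpec(n_cases=200, sequences=[planted],
                             fractions=(1.0,), seed=7)
        matrix, _ = lp.make_cohort(spec)
        cfg = FitConfig(mcmc_iters=2000, n_starts=8)
        cv = lp.cross_validate(matrix, 2, folds=5, cfg=cfg, seed=3)
        d = -2 * (np.array(cv["fold_oof"][0]) - np.array(cv["fold_oof"][1]))
        se = d.std(ddof=1) * np.sqrt(len(d))
        assert d.sum() <= se

    def test_guards(self, cohort300):
        _, matrix, _ = cohort300
        with pytest.raises(ValueError):
            lp.cross_validate(matrix, 2, folds=1)
        small = PathologyMatrix(scores=matrix.scores.iloc[:10].copy(),
                                metadata=matrix.metadata.iloc[:10].copy(),
                                capped=True)
        with pytest.raises(ValueError):
            lp.cross_validate(small, 2, folds=10)


class TestInputGuards:
    def test_uncapped_scores_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="cap"):
            lp.fit_subtypes(small_matrix, 1, cfg=FitConfig(mcmc_iters=0),
                            run_mcmc=False)

    def test_too_few_cases_rejected(self, cohort300):
        _, matrix, _ = cohort300
        tiny = PathologyMatrix(scores=matrix.scores.iloc[:8].copy(),
                               metadata=matrix.metadata.iloc[:8].copy(),
                               capped=True)
        with pytest.raises(ValueError, match="at least"):
            lp.fit_subtypes(tiny, 2, run_mcmc=False)

    def test_invalid_subtype_count(self, cohort300):
        _, matrix, _ = cohort300
        with pytest.raises(ValueError):
            lp.fit_subtypes(matrix, 0)
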