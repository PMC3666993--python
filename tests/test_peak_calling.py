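"""NB background model: tail probabilities, fitting, peak calls, control
subtraction, and the empirical FDR table."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chipdose.genome_io import Genome, GenomicInterval
from chipdose.peak_calling import (
    NBGCModel,
    Peak,
    RankedPeakSet,
    _fit_nb_trimmed,
    _nb_isf,
    _rank_peaks,
    call_peaks,
    fdr_curve,
    fit_background,
    nb_tail,
    nb_tail_pvalue,
    subtract_control,
)
from chipdose.read_processing import CoverageTrack, MappedRead, build_coverage


def brute_force_tail(observed: int, mu: float, r: float, far: int = 20_000) -> float:
    """Direct mass summation oracle for P(X >= observed)."""
    ks = np.arange(0, far)
    if math.isinf(r):
        pmf = stats.poisson.pmf(ks, mu)
    else:
        pmf = stats.nbinom.pmf(ks, r, r / (r + mu))
    return float(pmf[observed:].sum())


class TestNbTail:
    def test_zero_observation_has_unit_mass(self):
        assert nb_tail(0, 5.0, 2.0) == 1.0

    @pytest.mark.parametrize("mu", [0.5, 2.0, 5.0, 20.0])
    @pytest.mark.parametrize("r", [0.5, 2.0, 10.0, math.inf])
    def test_matches_direct_summation(self, mu, r):
        for observed in (1, 3, 10, 25, 60):
            expected = brute_force_tail(observed, mu, r)
            if expected < 1e-280:
                continue
            assert nb_tail(observed, mu, r) == pytest.approx(expected, rel=1e-10)

    def test_example_mean5_variance10(self):
        # variance 10 at mean 5 gives r = 5; spot value against summation
        assert nb_tail(20, 5.0, 5.0) == pytest.approx(
            brute_force_tail(20, 5.0, 5.0), rel=1e-10
        )

    def test_poisson_contract_at_large_r(self):
        poisson_tail = float(stats.poisson.sf(14, 5.0))
        assert nb_tail(15, 5.0, math.inf) == pytest.approx(poisson_tail, rel=1e-12)
        assert nb_tail(15, 5.0, 1e9) == pytest.approx(poisson_tail, rel=1e-6)

    @settings(deadline=None, max_examples=60)
    @given(
        mu=st.floats(0.2, 50),
        r=st.floats(0.3, 50),
        observed=st.integers(0, 200),
    )
    def test_monotone_nonincreasing_in_observed(self, mu, r, observed):
        assert nb_tail(observed + 1, mu, r) <= nb_tail(observed, mu, r)

    def test_isf_is_smallest_significant_count(self):
        for alpha in (1e-2, 1e-4, 1e-8):
            for mu, r in ((3.0, 2.0), (8.0, 5.0), (4.0, math.inf)):
                c = _nb_isf(alpha, mu, r)
                assert nb_tail(c, mu, r) <= alpha
                assert c == 0 or nb_tail(c - 1, mu, r) > alpha


class TestFitting:
    def test_constant_coverage_falls_back_to_poisson(self):
        mu, r = _fit_nb_trimmed(np.full(500, 7.0))
        assert mu == pytest.approx(7.0, abs=1e-9)
        assert math.isinf(r)

    def test_parameter_recovery_on_clean_nb_counts(self, rng):
        for mu_t, r_t in ((6.0, 4.0), (12.0, 8.0)):
            x = rng.negative_binomial(r_t, r_t / (r_t + mu_t), 4_000).astype(float)
            mu, r = _fit_nb_trimmed(x)
            assert mu == pytest.approx(mu_t, rel=0.05)
            assert r == pytest.approx(r_t, rel=0.25)

    def test_gc_independent_background_fits_equal_means(self, background_only):
        # generator means differ by bin; within a bin the fit should track the
        # generator mean closely, and dispersion should match across bins
        cfg, genome, coverage, model = background_only
        big = model.n_windows >= 2_000
        assert big.sum() >= 3
        for b in np.flatnonzero(big):
            mu_true, r_true = cfg.background_params(float(model.gc_bin_edges[b]) + 1e-9)
            assert model.window_mu[b] == pytest.approx(mu_true, rel=0.05)
            assert model.r[b] == pytest.approx(r_true, rel=0.20)

    def test_window_smaller_than_twice_extension_rejected(self, background_only):
        _, genome, coverage, _ = background_only
        with pytest.raises(ValueError):
            fit_background(coverage, genome, window_size=300)

    def test_gc_outside_unit_interval_rejected(self, background_only):
        *_, model = background_only
        with pytest.raises(ValueError):
            nb_tail_pvalue(model, 1.5, 3)
        with pytest.raises(ValueError):
            nb_tail_pvalue(model, -0.1, 3)


def _toy_model(mu=2.0, r=5.0, window=500, ext=200, chrom="c1", nwin=20):
    edges = np.arange(0.0, 1.05, 0.05)
    nb = len(edges) - 1
    return NBGCModel(
        gc_bin_edges=edges,
        mu=np.full(nb, mu),
        r=np.full(nb, r),
        n_windows=np.full(nb, 100),
        window_size=window,
        extension_length=ext,
        window_bins={chrom: np.full(nwin, 8, dtype=np.int32)},
        window_gc={chrom: np.full(nwin, 0.42)},
        total_reads=1000,
    )


def _coverage_from_depth(depth, ext=200):
    return CoverageTrack({"c1": np.asarray(depth, dtype=np.int32)},
                         total_reads_used=1, extension_length=ext)


class TestCallPeaks:
    def test_single_stack_gives_one_peak_with_summit_inside(self):
        depth = np.zeros(10_000, int)
        depth[3_000:3_200] = 30
        model = _toy_model()
        ps = call_peaks(_coverage_from_depth(depth), model, 1e-5)
        assert len(ps) == 1
        (pk,) = ps.peaks
        assert pk.height == 30
        assert 3_000 <= pk.summit < 3_200
        assert pk.p_value == pytest.approx(nb_tail(30, 2.0, 5.0), rel=1e-12)
        assert pk.rank == 1

    def test_merge_rule_at_fragment_scale(self):
        model = _toy_model()
        depth = np.zeros(10_000, int)
        depth[1_000:1_050] = 30
        depth[1_200:1_250] = 30  # 150-base gap: merged
        ps = call_peaks(_coverage_from_depth(depth), model, 1e-5)
        assert len(ps) == 1
        depth2 = np.zeros(10_000, int)
        depth2[1_000:1_050] = 30
        depth2[1_450:1_500] = 30  # 400-base gap: separate peaks
        ps2 = call_peaks(_coverage_from_depth(depth2), model, 1e-5)
        assert len(ps2) == 2

    def test_empty_coverage_gives_empty_set(self):
        ps = call_peaks(_coverage_from_depth(np.zeros(5_000, int)), _toy_model(), 1e-5)
        assert len(ps) == 0

    def test_ranks_are_permutation_with_deterministic_ties(self):
        peaks = [
            Peak(GenomicInterval("c1", i * 500, i * 500 + 100), i * 500 + 50,
                 h, p)
            for i, (h, p) in enumerate([(10, 1e-8), (30, 1e-9), (30, 1e-9),
                                        (5, 1e-3)])
        ]
        ranked = _rank_peaks("s", peaks, 100, 1e-3)
        assert [p.rank for p in ranked.peaks] == [1, 2, 3, 4]
        assert sorted(p.height for p in ranked.peaks[:2]) == [30, 30]
        rerank = _rank_peaks("s", list(reversed(ranked.peaks)), 100, 1e-3)
        assert [
            (p.interval.start, p.rank) for p in rerank.peaks
        ] == [(p.interval.start, p.rank) for p in ranked.peaks]


class TestSubtractControl:
    def _peakset(self, spans, name="s"):
        peaks = [
            Peak(GenomicInterval("c1", s, e), (s + e) // 2, 10, 1e-6)
            for s, e in spans
        ]
        return _rank_peaks(name, peaks, 100, 1e-5)

    def test_peak_inside_control_removed(self):
        ps = self._peakset([(100, 200)])
        ctrl = self._peakset([(50, 300)], "ctrl")
        assert len(subtract_control(ps, ctrl)) == 0

    def test_empty_control_is_identity(self):
        ps = self._peakset([(100, 200), (400, 500)])
        out = subtract_control(ps, self._peakset([], "ctrl"))
        assert [p.interval for p in out.peaks] == [p.interval for p in ps.peaks]

    def test_ranks_recomputed_after_removal(self):
        spans = [(i * 1_000, i * 1_000 + 100) for i in range(10)]
        ps = self._peakset(spans)
        ctrl = self._peakset([spans[1], spans[4], spans[8]], "ctrl")
        out = subtract_control(ps, ctrl)
        assert len(out) == 7
        assert [p.rank for p in out.peaks] == list(range(1, 8))
        survivors = {p.interval.start for p in out.peaks}
        assert survivors == {s for i, (s, _) in enumerate(spans) if i not in (1, 4, 8)}


class TestFdrCurve:
    def test_null_fraction_matches_analytic_summation(self, background_only):
        _, _, coverage, model = background_only
        alpha = 1e-3
        c = model.depth_thresholds(alpha)
        total = model.n_windows.sum()
        expected = sum(
            (model.n_windows[b] / total)
            * nb_tail(int(c[b]), float(model.mu[b]), float(model.r[b]))
            for b in range(len(model.mu))
            if model.n_windows[b]
        )
        assert model.null_genome_fraction(alpha) == pytest.approx(expected, rel=1e-12)

    def test_pure_background_fdr_near_one_where_defined(self, background_only):
        _, _, coverage, model = background_only
        table = fdr_curve(coverage, model, [1e-3, 1e-4])
        assert ((table["fdr"] >= 0.5) & (table["fdr"] <= 1.0)).all()

    def test_planted_signal_drives_fdr_down(self, background_only, std_fixture):
        _, _, bg_cov, bg_model = background_only
        null_tab = fdr_curve(bg_cov, bg_model, [1e-5])
        sig_tab = fdr_curve(
            std_fixture.coverage["overexpressed"],
            std_fixture.models["overexpressed"],
            [1e-5],
        )
        assert sig_tab["fdr"].iloc[0] < null_tab["fdr"].iloc[0]
        assert sig_tab["fdr"].iloc[0] < 0.5

    def test_zero_observed_reported_as_nan(self):
        model = _toy_model()
        table = fdr_curve(_coverage_from_depth(np.zeros(10_000, int)), model, [1e-5])
        assert math.isnan(table["fdr"].iloc[0])
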