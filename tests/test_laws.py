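"""Zipf / Heaps / Menzerath-Altmann fitting against independent oracles."""

import numpy as np
import pytest
from scipy import special

from molvocab import (HeapsCurve, LawFitError, MAData, fit_heaps, fit_ma,
                      fit_zipf, heaps_curve, ma_data_from_proteins,
                      occurrence_spectrum, sample_zipf, segment_regimes)


def grid_search_gamma(ks, weights, xmin, grid=np.arange(1.01, 5.0, 1e-3)):
    """Independent discrete-MLE oracle: exhaustive grid over gamma."""
    ks = np.asarray(ks, dtype=float)
    weights = np.asarray(weights, dtype=float)
    ll = (-weights.sum() * np.log(special.zeta(grid[:, None], xmin))
          - grid[:, None] * (weights * np.log(ks)).sum()).ravel()
    return float(grid[np.argmax(ll)])


class TestOccurrenceSpectrum:
    def test_direct_tally(self):
        spec = occurrence_spectrum([1, 1, 2, 3])
        assert spec.freq == {1: 2, 2: 1, 3: 1}

    def test_trait_conservation(self):
        counts = [3, 3, 7, 1, 0, 2, 2, 2]
        spec = occurrence_spectrum(counts)
        assert spec.n_traits == sum(1 for c in counts if c > 0)

    def test_all_zero_rejected(self):
        with pytest.raises(LawFitError):
            occurrence_spectrum([0, 0, 0])

    def test_matrix_totals_match_manual_tally(self, toy_matrix):
        spec = occurrence_spectrum(toy_matrix)
        manual = {}
        for t in toy_matrix.traits:
            k = int(toy_matrix.counts.loc[t].sum())
            if k > 0:
                manual[k] = manual.get(k, 0) + 1
        assert spec.freq == manual


class TestZipf:
    def test_recovers_gamma_on_seeded_draws(self):
        rng = np.random.default_rng(7)
        draws = sample_zipf(2.0, 1, 10_000, rng)
        fit = fit_zipf(occurrence_spectrum(draws), xmin=1, bootstrap=0)
        assert 1.95 <= fit.gamma <= 2.05
        assert fit.n_tail == 10_000

    def test_mle_agrees_with_grid_search_oracle(self):
        for seed, gamma in [(1, 1.6), (2, 2.0), (3, 3.1)]:
            rng = np.random.default_rng(seed)
            draws = sample_zipf(gamma, 1, 3000, rng)
            k, w = np.unique(draws, return_counts=True)
            fit = fit_zipf(occurrence_spectrum(draws), xmin=1, bootstrap=0)
            assert abs(fit.gamma - grid_search_gamma(k, w, 1)) < 2e-3

    def test_degenerate_spectrum_rejected(self):
        from molvocab import OccurrenceSpectrum
        with pytest.raises(LawFitError):
            fit_zipf(OccurrenceSpectrum({5: 100}), xmin=1, bootstrap=0)

    def test_bootstrap_p_value_seeded_and_deterministic(self):
        rng = np.random.default_rng(4)
        draws = sample_zipf(2.0, 1, 1000, rng)
        spec = occurrence_spectrum(draws)
        f1 = fit_zipf(spec, xmin=1, bootstrap=30, seed=5)
        f2 = fit_zipf(spec, xmin=1, bootstrap=30, seed=5)
        assert f1.p_value == f2.p_value
        assert 0.0 <= f1.p_value <= 1.0

    def test_sampler_gamma_le_one_rejected(self):
        with pytest.raises(LawFitError):
            sample_zipf(1.0, 1, 10, np.random.default_rng(0))

    def test_sampler_empty_draw(self):
        assert len(sample_zipf(2.0, 1, 0, np.random.default_rng(0))) == 0

    def test_auto_xmin_on_shifted_tail(self):
        # body below k=5 distorted; auto-xmin should move past it
        rng = np.random.default_rng(12)
        tail = sample_zipf(2.2, 5, 4000, rng)
        body = rng.integers(1, 5, size=2000)
        fit = fit_zipf(occurrence_spectrum(np.concatenate([tail, body])),
                       xmin="auto", bootstrap=0)
        assert fit.xmin >= 4
        assert abs(fit.gamma - 2.2) < 0.15


class TestHeaps:
    def test_all_distinct_stream(self):
        curve = heaps_curve(stream=list("abcd"))
        assert np.array_equal(curve.N, curve.V)

    def test_constant_stream(self):
        curve = heaps_curve(stream=list("aaa"))
        assert list(zip(curve.N, curve.V)) == [(1, 1), (2, 1), (3, 1)]

    def test_matches_set_based_recount(self):
        rng = np.random.default_rng(5)
        stream = [int(x) for x in rng.integers(0, 40, size=500)]
        curve = heaps_curve(stream=stream)
        seen, expect = set(), []
        for tok in stream:
            seen.add(tok)
            expect.append(len(seen))
        assert np.array_equal(curve.V, np.array(expect, dtype=float))

    def test_proteome_mode_sorts_by_database_size(self):
        curve = heaps_curve(proteomes={"p2": [2, 2, 0], "p1": [1, 0, 0],
                                       "p3": [3, 3, 3]})
        assert list(curve.N) == [1, 4, 9]
        assert list(curve.V) == [1, 2, 3]

    def test_exact_identity_curve(self):
        N = np.arange(1, 200, dtype=float)
        fit = fit_heaps(HeapsCurve(N=N, V=N), n_segments=1)
        assert fit.segments[0].K == pytest.approx(1.0)
        assert fit.segments[0].beta == pytest.approx(1.0)

    def test_noiseless_power_law(self):
        N = np.logspace(1, 4, 60)
        fit = fit_heaps(HeapsCurve(N=N, V=3 * N ** 0.5), n_segments=1)
        assert fit.segments[0].K == pytest.approx(3.0, abs=1e-6)
        assert fit.segments[0].beta == pytest.approx(0.5, abs=1e-6)

    def test_two_regime_recovery(self):
        # beta 0.8 then 0.3 with a break at N = 1e3
        N = np.unique(np.geomspace(10, 1e5, 300).astype(int)).astype(float)
        V = np.where(N <= 1e3, 2.0 * N ** 0.8,
                     2.0 * 1e3 ** 0.8 * (N / 1e3) ** 0.3)
        fit = fit_heaps(HeapsCurve(N=N, V=V), n_segments=2)
        b1, b2 = fit.segments[0].beta, fit.segments[1].beta
        assert abs(b1 - 0.8) <= 0.05 and abs(b2 - 0.3) <= 0.05
        break_n = fit.segments[1].n_range[0]
        assert 1e3 / 1.5 <= break_n <= 1e3 * 1.5

    def test_infeasible_segments_rejected(self):
        N = np.arange(1, 5, dtype=float)
        with pytest.raises(LawFitError):
            fit_heaps(HeapsCurve(N=N, V=N), n_segments=4)


class TestSegmentRegimes:
    def test_linear_points_give_one_segment_under_bic(self):
        x = np.linspace(0, 5, 30)
        pts = list(zip(x, 2 * x + 1))
        assert segment_regimes(pts, 4) == []

    def test_known_breakpoint_recovered_exactly(self):
        x = np.linspace(0, 10, 40)
        y = np.where(x <= 5, x, 5 + 1.5 * (x - 5))  # slope 1 then 1.5
        bps = segment_regimes(list(zip(x, y)), 2, force=True)
        assert len(bps) == 1
        # breakpoint at the first point of the second line
        assert abs(x[bps[0]] - 5.0) <= x[1] - x[0] + 1e-9

    def test_dp_beats_every_manual_two_split(self):
        rng = np.random.default_rng(8)
        x = np.sort(rng.random(30) * 10)
        y = np.where(x < 4, 2 * x, 8 + 0.5 * (x - 4)) + rng.normal(0, 0.1, 30)
        pts = list(zip(x, y))
        bps = segment_regimes(pts, 2, force=True)

        def sse_of(split):
            def line_sse(xx, yy):
                A = np.column_stack([np.ones_like(xx), xx])
                coef, *_ = np.linalg.lstsq(A, yy, rcond=None)
                r = yy - A @ coef
                return float(r @ r)
            return line_sse(x[:split], y[:split]) + line_sse(x[split:], y[split:])

        dp_sse = sse_of(bps[0])
        assert all(dp_sse <= sse_of(s) + 1e-9 for s in range(2, 29))

    def test_zero_segments_rejected(self):
        with pytest.raises(LawFitError):
            segment_regimes([(0, 0), (1, 1), (2, 2), (3, 3)], 0)


class TestMenzerathAltmann:
    def test_flat_law_flags_r2_undefined(self):
        data = MAData(k=np.arange(1, 6), z=np.full(5, 200.0), n=np.ones(5))
        fit = fit_ma(data)
        assert fit.b == pytest.approx(0.0, abs=1e-12)
        assert fit.A == pytest.approx(200.0)
        assert fit.r_squared is None

    def test_noiseless_power_law_exact(self):
        k = np.arange(1, 11, dtype=float)
        data = MAData(k=k, z=200.0 * k ** -0.2, n=np.arange(1, 11, dtype=float))
        fit = fit_ma(data)
        assert fit.A == pytest.approx(200.0, abs=1e-9)
        assert fit.b == pytest.approx(-0.2, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_agrees_with_statsmodels_wls_oracle(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(6)
        k = np.arange(1, 9, dtype=float)
        z = 180.0 * k ** -0.25 * np.exp(rng.normal(0, 0.05, len(k)))
        n = rng.integers(1, 20, len(k)).astype(float)
        fit = fit_ma(MAData(k=k, z=z, n=n))
        X = sm.add_constant(np.log(k))
        res = sm.WLS(np.log(z), X, weights=n).fit()
        assert fit.b == pytest.approx(res.params[1], abs=1e-9)
        assert np.log(fit.A) == pytest.approx(res.params[0], abs=1e-9)

    def test_invariant_under_protein_duplication(self):
        rng = np.random.default_rng(13)
        proteins = [(k, list(rng.uniform(100, 300, k)))
                    for k in range(1, 7) for _ in range(4)]
        fit1 = fit_ma(ma_data_from_proteins(proteins))
        fit2 = fit_ma(ma_data_from_proteins(proteins + proteins))
        assert fit1.A == pytest.approx(fit2.A)
        assert fit1.b == pytest.approx(fit2.b)

    def test_too_few_levels_rejected(self):
        with pytest.raises(LawFitError):
            fit_ma(MAData(k=[1, 2], z=[200, 180], n=[1, 1]))
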