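"""R-square matrices, peak picking and the interval summary measures."""

from __future__ import annotations

import numpy as np
import pytest

from movesync.datatypes import DyadTimeSeries
from movesync.peak_picking import (
    LOSI,
    RSquareMatrix,
    SynchronizationInterval,
    peak_picking,
    sync_frequency,
    sync_mean_r2,
    wclc_rsq_matrix,
    wclr_rsq_matrix,
)

from .oracles import peak_picking_oracle, wclc_rsq_oracle, wclr_rsq_oracle


def _noise_dyad(rng, n):
    return DyadTimeSeries(a=rng.normal(0, 1, n), b=rng.normal(0, 1, n))


def _lagged_copy_dyad(rng, n, lag, start, end, noise=0.0):
    a = rng.uniform(0, 30, n)
    b = rng.uniform(0, 30, n)
    b[start + lag:end + lag] = a[start:end]
    if noise:
        b = b + rng.normal(0, noise, n)
    return DyadTimeSeries(a=a, b=b)


class TestRsqMatrices:
    def test_wclc_matches_bruteforce(self, rng):
        d = _noise_dyad(rng, 500)
        m = wclc_rsq_matrix(d, b=40, tau_max=15, alpha=0.05)
        want = wclc_rsq_oracle(d.a, d.b, 40, 15, 0.05)
        np.testing.assert_allclose(m.values, want, rtol=1e-10, atol=1e-12,
                                   equal_nan=True)

    def test_wclr_matches_bruteforce_two_regressions(self, rng):
        d = _noise_dyad(rng, 400)
        m = wclr_rsq_matrix(d, b=40, tau_max=12, alpha=0.05)
        want = wclr_rsq_oracle(d.a, d.b, 40, 12, 0.05)
        np.testing.assert_allclose(m.values, want, rtol=1e-8, atol=1e-10,
                                   equal_nan=True)

    def test_exact_lagged_copy_saturates_wclc(self, rng):
        d = _lagged_copy_dyad(rng, 800, lag=30, start=0, end=770)
        m = wclc_rsq_matrix(d, b=100, tau_max=40, alpha=None)
        col = np.flatnonzero(m.lags == 30)[0]
        inside = m.values[:800 - 100 - 30, col]
        np.testing.assert_allclose(inside, 1.0, atol=1e-9)

    def test_wclr_discounts_autocorrelation(self, rng):
        """With a strongly autocorrelated A and independent B, Delta R^2
        stays below the raw WCLC R^2 on average."""
        diffs = []
        for _ in range(30):
            a = np.convolve(rng.normal(0, 1, 700), np.ones(25) / 25, mode="same")
            b = rng.normal(0, 1, 700)
            d = DyadTimeSeries(a=a, b=b)
            wclc = wclc_rsq_matrix(d, b=50, tau_max=10, alpha=None)
            wclr = wclr_rsq_matrix(d, b=50, tau_max=10, alpha=None)
            diffs.append(np.nanmean(wclc.values) - np.nanmean(wclr.values))
        assert np.mean(diffs) > 0

    def test_values_in_unit_interval(self, rng):
        d = _noise_dyad(rng, 400)
        for m in (wclc_rsq_matrix(d, 30, 10, None), wclr_rsq_matrix(d, 30, 10, None)):
            v = m.values[np.isfinite(m.values)]
            assert v.min() >= 0.0 and v.max() <= 1.0 + 1e-12

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError):
            wclc_rsq_matrix(_noise_dyad(rng, 200), b=125, tau_max=125)


def _matrix(values, lags, mode="wclc"):
    values = np.asarray(values, float)
    return RSquareMatrix(values=values, lags=np.asarray(lags), mode=mode,
                         window=10, length=values.shape[0] + 9)


class TestPeakPicking:
    def test_all_below_cutoff_gives_empty_losi(self):
        m = _matrix(np.full((6, 5), 0.1), [-2, -1, 0, 1, 2])
        losi = peak_picking(m)
        assert losi.intervals == ()
        assert sync_frequency(losi) == 0.0
        assert np.isnan(sync_mean_r2(losi, m))

    def test_toy_conflict_resolution_keeps_larger_mean(self):
        # a same-lag run over rows 1-3 (0.4, 0.5, 0.45) conflicts with a
        # single row-2 maximum of 0.3 at another lag: one interval survives
        v = np.zeros((6, 5))
        v[1, 3], v[2, 3], v[3, 3] = 0.4, 0.5, 0.45
        v[2, 0] = 0.3
        m = _matrix(v, [-2, -1, 0, 1, 2])
        losi = peak_picking(m, r2_cutoff=0.25)
        assert len(losi.intervals) == 1
        iv = losi.intervals[0]
        assert (iv.row_start, iv.row_end, iv.lag) == (1, 3, 1)
        assert iv.mean_strength == pytest.approx((0.4 + 0.5 + 0.45) / 3)

    def test_matches_enumeration_oracle_on_random_matrices(self, rng):
        lags = np.arange(-6, 7)
        for _ in range(20):
            v = rng.uniform(0, 1, size=(15, 13))
            v[rng.uniform(size=v.shape) < 0.3] = 0.0  # force plateaus
            m = _matrix(v, lags)
            got = sorted((iv.row_start, iv.row_end, iv.lag,
                          pytest.approx(iv.mean_strength))
                         for iv in peak_picking(m, 0.25).intervals)
            want = [(a, b, c, pytest.approx(d))
                    for a, b, c, d in peak_picking_oracle(v, lags, 0.25)]
            assert got == want

    def test_selection_idempotent_under_nonmax_zeroing(self, rng):
        lags = np.arange(-4, 5)
        v = rng.uniform(0.3, 1.0, size=(12, 9))
        m = _matrix(v, lags)
        losi = peak_picking(m, 0.25)
        from movesync.peak_picking import _plateau_local_maxima

        zeroed = np.where(_plateau_local_maxima(v), v, 0.0)
        losi2 = peak_picking(_matrix(zeroed, lags), 0.25)
        assert [(i.row_start, i.row_end, i.lag) for i in losi.intervals] == \
               [(i.row_start, i.row_end, i.lag) for i in losi2.intervals]

    def test_injected_interval_recovered_at_true_lag(self, rng):
        lag, start, end = 25, 600, 1400
        d = _lagged_copy_dyad(rng, 2000, lag, start, end)
        for build in (wclc_rsq_matrix, wclr_rsq_matrix):
            m = build(d, b=125, tau_max=60)
            best = max(peak_picking(m).intervals, key=lambda iv: iv.n_rows)
            assert best.lag == lag
            inter = min(best.row_end, end - 125) - max(best.row_start, start) + 1
            union = max(best.row_end, end - 125) - min(best.row_start, start) + 1
            assert inter / union >= 0.5


class TestSummaries:
    def _losi(self, intervals, n_rows):
        return LOSI(intervals=tuple(SynchronizationInterval(*iv) for iv in intervals),
                    n_rows=n_rows, window=10)

    def test_frequency_counts_covered_rows(self):
        losi = self._losi([(0, 59, 3, 0.5), (200, 259, -1, 0.4)], 400)
        assert sync_frequency(losi) == pytest.approx(120 / 400)
        assert sync_frequency(self._losi([(0, 399, 0, 0.9)], 400)) == 1.0

    def test_mean_r2_pools_member_cells(self, rng):
        v = rng.uniform(0, 1, size=(10, 5))
        m = _matrix(v, [-2, -1, 0, 1, 2])
        losi = self._losi([(2, 4, -1, float(v[2:5, 1].mean()))], 10)
        assert sync_mean_r2(losi, m) == pytest.approx(v[2:5, 1].mean())
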