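"""Cohort assembly and the convergent/predictive validity statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from movesync.battery import BatteryConfig, measure_battery
from movesync.crqa import CrqaParams
from movesync.datatypes import MEASURE_COLUMNS, DyadTimeSeries
from movesync.validity import (
    correlation_matrix,
    efa_ml,
    effect_size_label,
    group_comparison,
    parallel_analysis,
    symptom_correlations,
)

from .oracles import pearson_oracle, spearman_oracle


def _small_battery_config() -> BatteryConfig:
    """Parameters scaled to short fixtures."""
    return BatteryConfig(
        rmea_window_s=8.0, rmea_lag_max_s=1.0, rmea_increment_s=4.0,
        susy_segment_s=8.0, susy_lag_max_s=1.0,
        suco_slope_window_s=1.0, suco_slope_increment_s=0.4,
        pp_window=50, pp_tau_max=25, mi_jackknife_blocks=10,
        crqa=CrqaParams(window_frames=250, window_overlap=125, lag_band=25))


class TestBattery:
    def test_shape_and_determinism(self, rng):
        dyads = [DyadTimeSeries(a=rng.uniform(0, 30, 900),
                                b=rng.uniform(0, 30, 900), dyad_id=f"d{i}")
                 for i in range(2)]
        cfg = _small_battery_config()
        t1 = measure_battery(dyads, config=cfg)
        t2 = measure_battery(dyads, config=cfg)
        assert list(t1.columns) == ["dyad_id", *MEASURE_COLUMNS]
        assert len(t1) == 2
        pd.testing.assert_frame_equal(t1, t2, check_exact=True)

    def test_partial_failure_leaves_other_columns(self, rng):
        short = DyadTimeSeries(a=rng.uniform(0, 30, 400),
                               b=rng.uniform(0, 30, 400), dyad_id="short")
        cfg = _small_battery_config()
        # series shorter than the CRQA window: wincrqa_* missing, rest present
        cfg = BatteryConfig(**{**cfg.__dict__, "crqa": CrqaParams(
            window_frames=500, window_overlap=250, lag_band=25)})
        row = measure_battery([short], config=cfg).iloc[0]
        assert np.isnan(row["wincrqa_rr"])
        assert np.isfinite(row["cc_raw"])
        assert np.isfinite(row["susy_es_abs"])


class TestCorrelationMatrix:
    def _table(self, rng, n=12):
        base = rng.normal(size=n)
        return pd.DataFrame({
            "cc_raw": base + rng.normal(0, 0.5, n),
            "cc_abs": rng.uniform(0, 1, n),
            "mi_raw": base + rng.normal(0, 0.8, n),
        })

    def test_triangles_and_diagonal(self, rng):
        t = self._table(rng)
        res = correlation_matrix(t)
        assert np.allclose(np.diag(res.combined), 1.0)
        assert res.combined.iloc[1, 0] == pytest.approx(res.pearson.iloc[1, 0])
        assert res.combined.iloc[0, 1] == pytest.approx(res.spearman.iloc[0, 1])

    def test_matches_textbook_formulas(self, rng):
        t = self._table(rng, n=5)
        res = correlation_matrix(t)
        x = t["cc_raw"].to_numpy()
        y = t["mi_raw"].to_numpy()
        assert res.pearson.loc["cc_raw", "mi_raw"] == pytest.approx(
            pearson_oracle(x, y), rel=1e-10)
        assert res.spearman.loc["cc_raw", "mi_raw"] == pytest.approx(
            spearman_oracle(x, y), rel=1e-10)

    def test_zero_variance_column_missing(self, rng):
        t = self._table(rng)
        t["cc_abs"] = 0.5
        res = correlation_matrix(t)
        assert np.isnan(res.pearson.loc["cc_abs", "cc_raw"])


def _factor_data(rng, n, loadings):
    """loadings: (p, k) matrix; orthogonal standard-normal factors."""
    loadings = np.asarray(loadings)
    p, k = loadings.shape
    f = rng.normal(size=(n, k))
    unique_sd = np.sqrt(np.clip(1 - (loadings ** 2).sum(axis=1), 0.05, 1))
    return f @ loadings.T + rng.normal(size=(n, p)) * unique_sd


_TWO_FACTOR = np.array([[0.8, 0.0]] * 3 + [[0.0, 0.8]] * 3)


class TestParallelAnalysis:
    def test_recovers_one_factor(self, rng):
        data = _factor_data(rng, 200, np.full((6, 1), 0.8))
        t = pd.DataFrame(data, columns=[f"m{i}" for i in range(6)])
        assert parallel_analysis(t, n_boot=100, seed=1, columns=t.columns) == 1

    def test_recovers_two_factors(self, rng):
        data = _factor_data(rng, 200, _TWO_FACTOR)
        t = pd.DataFrame(data, columns=[f"m{i}" for i in range(6)])
        assert parallel_analysis(t, n_boot=100, seed=2, columns=t.columns) == 2

    def test_pure_noise_rarely_suggests_structure(self, rng):
        hits = 0
        for rep in range(40):
            t = pd.DataFrame(rng.normal(size=(200, 10)),
                             columns=[f"m{i}" for i in range(10)])
            if parallel_analysis(t, n_boot=60, seed=rep, columns=t.columns) <= 1:
                hits += 1
        assert hits >= 38  # 0 or 1 factors in >= 95 percent of replicates


class TestEfaMl:
    def test_recovers_planted_loadings(self, rng):
        data = _factor_data(rng, 200, _TWO_FACTOR)
        t = pd.DataFrame(data, columns=[f"m{i}" for i in range(6)])
        sol = efa_ml(t, 2, columns=t.columns)
        L = np.abs(sol.loadings.to_numpy())
        # up to permutation/sign: each variable loads ~0.8 on one factor, ~0 other
        hi = L.max(axis=1)
        lo = L.min(axis=1)
        np.testing.assert_allclose(hi, 0.8, atol=0.1)
        np.testing.assert_allclose(lo, 0.0, atol=0.1)
        # planted factors are orthogonal
        assert abs(sol.factor_correlation[0, 1]) < 0.15

    def test_saturated_single_factor_fits_perfectly(self, rng):
        data = _factor_data(rng, 500, np.full((3, 1), 0.7))
        t = pd.DataFrame(data, columns=["a", "b", "c"])
        sol = efa_ml(t, 1, columns=t.columns)
        assert sol.rmsea == pytest.approx(0.0, abs=0.05)
        assert sol.rmsr < 0.05


class TestGroupComparison:
    def _table(self, x_ctl, x_pat):
        return pd.DataFrame({
            "group": ["control"] * len(x_ctl) + ["patient"] * len(x_pat),
            "cc_raw": list(x_ctl) + list(x_pat),
        })

    def test_identical_groups_null(self):
        t = self._table([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        res = group_comparison(t)
        assert res.loc["cc_raw", "hedges_g"] == pytest.approx(0.0)
        assert res.loc["cc_raw", "kw_p"] > 0.9

    def test_one_pooled_sd_shift_recovers_unit_g(self, rng):
        x = rng.normal(0, 1, 500)
        y = rng.normal(0, 1, 500)
        y = (y - y.mean()) / y.std(ddof=1)
        x = (x - x.mean()) / x.std(ddof=1) + 1.0
        res = group_comparison(self._table(y, x))
        corr = 1 - 3 / (4 * 1000 - 9)
        assert res.loc["cc_raw", "hedges_g"] == pytest.approx(1.0 * corr, rel=1e-6)

    def test_toy_table_matches_bruteforce(self, rng):
        ctl = rng.normal(0, 1, 4)
        pat = rng.normal(1, 1, 4)
        res = group_comparison(self._table(ctl, pat))
        _, p = stats.kruskal(pat, ctl)
        n1, n2 = 4, 4
        sp = np.sqrt(((n1 - 1) * pat.var(ddof=1) + (n2 - 1) * ctl.var(ddof=1)) / (n1 + n2 - 2))
        g = (pat.mean() - ctl.mean()) / sp * (1 - 3 / (4 * 8 - 9))
        assert res.loc["cc_raw", "kw_p"] == pytest.approx(p, rel=1e-12)
        assert res.loc["cc_raw", "hedges_g"] == pytest.approx(g, rel=1e-12)


class TestSymptomCorrelations:
    def test_constant_symptom_column_missing(self, rng):
        t = pd.DataFrame({"cc_raw": rng.normal(size=10),
                          "phq9": np.full(10, 5.0),
                          "gad7": rng.integers(0, 21, 10).astype(float)})
        res = symptom_correlations(t)
        assert np.isnan(res.loc["cc_raw", "phq9_pearson_r"])
        assert np.isfinite(res.loc["cc_raw", "gad7_pearson_r"])

    def test_null_slope_centered_on_zero(self, rng):
        rs = []
        for _ in range(200):
            t = pd.DataFrame({"cc_raw": rng.normal(size=15),
                              "phq9": rng.integers(0, 27, 15).astype(float),
                              "gad7": rng.integers(0, 21, 15).astype(float)})
            rs.append(symptom_correlations(t).loc["cc_raw", "phq9_pearson_r"])
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < 3 * se


@pytest.fixture(scope="module")
def cohort_stats():
    """Per-cohort Hedges g and symptom correlation of rMEA-WCLC over 15
    replicate cohorts at the generator's standard conditions (shortened
    recordings keep the Monte Carlo fast)."""
    from movesync.synthetic import CohortConfig, DyadConfig, generate_cohort
    from movesync.windowed_correlation import rmea_wclc, wclc_matrix
    from movesync._stats import hedges_g

    gs, sym_rs = [], []
    for rep in range(15):
        cfg = CohortConfig(seed=4000 + rep,
                           dyad=DyadConfig(length_frames=7500))
        dyads, cohort = generate_cohort(cfg)
        vals = np.array([rmea_wclc(wclc_matrix(d)) for d in dyads])
        pat = (cohort["group"] == "patient").to_numpy()
        gs.append(hedges_g(vals[pat], vals[~pat]))
        sym_rs.append(stats.spearmanr(vals, cohort["phq9"]).statistic)
    return np.array(gs), np.array(sym_rs)


class TestEndToEndDirection:
    """The planted clinical contrast points the right way: depressed-group
    dyads are less synchronous, and symptom load correlates negatively with
    synchrony."""

    def test_patients_less_synchronous(self, cohort_stats):
        gs, _ = cohort_stats
        assert gs.mean() < -0.3
        assert (gs < 0).sum() >= 12

    def test_symptom_correlation_sign_recovered(self, cohort_stats):
        _, rs = cohort_stats
        assert rs.mean() < 0
        assert (rs < 0).sum() >= 10


def test_effect_size_labels():
    assert effect_size_label(0.05, "r") == "negligible"
    assert effect_size_label(-0.4, "r") == "moderate"
    assert effect_size_label(0.9, "g") == "large"
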