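"""Generator contracts: determinism, range, calibration, ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from movesync.datatypes import CouplingInterval
from movesync.synthetic import (
    CohortConfig,
    DyadConfig,
    SymptomModel,
    generate_burst_series,
    generate_cohort,
    generate_coupled_dyad,
    generate_frame_stack,
)


class TestBurstSeries:
    def test_no_signal_sources_gives_all_zero(self):
        cfg = DyadConfig(length_frames=500, burst_rate=0.0, noise_sd=0.0, baseline=0.0)
        assert not generate_burst_series(cfg, 1).values.any()

    def test_same_seed_reproduces_bit_identically(self):
        cfg = DyadConfig(length_frames=2000)
        a = generate_burst_series(cfg, 42).values
        b = generate_burst_series(cfg, 42).values
        np.testing.assert_array_equal(a, b)

    def test_values_within_percent_range(self):
        cfg = DyadConfig(length_frames=2000, noise_sd=5.0, burst_amplitude=95.0)
        v = generate_burst_series(cfg, 3).values
        assert v.min() >= 0.0 and v.max() <= 100.0 and v.size == 2000

    def test_elevated_mass_matches_poisson_expectation(self):
        # raised-cosine bursts carry amplitude*duration/2 mass each;
        # expected count = rate * minutes (hard-core thinning is negligible
        # at this occupancy), checked over 200 replicate seeds
        cfg = DyadConfig(length_frames=15_000, burst_rate=2.0,
                         burst_duration_frames=250, burst_amplitude=20.0,
                         noise_sd=0.0, baseline=0.0)
        minutes = 15_000 / 25 / 60
        per_burst = 20.0 * 250 / 2
        expect = cfg.burst_rate * minutes * per_burst
        masses = np.array([generate_burst_series(cfg, s).values.sum()
                           for s in range(200)])
        sd_one = np.sqrt(cfg.burst_rate * minutes) * per_burst
        assert abs(masses.mean() - expect) < 3 * sd_one / np.sqrt(200)

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            DyadConfig(length_frames=0)


class TestCoupledDyad:
    def test_empty_schedule_members_uncorrelated(self):
        cfg = DyadConfig()  # the generator's standard 10-minute recording
        rs = []
        for s in range(100):
            d = generate_coupled_dyad(cfg, [], s)
            rs.append(abs(np.corrcoef(d.a, d.b)[0, 1]))
        assert np.mean(rs) < 0.1

    def test_noiseless_interval_is_exact_lagged_copy(self):
        # dense bursts guarantee driver activity inside the interval
        cfg = DyadConfig(length_frames=2000, noise_sd=0.0, burst_rate=12.0,
                         burst_duration_frames=100)
        iv = CouplingInterval(500, 900, 50, 1.0, 1)
        d = generate_coupled_dyad(cfg, [iv], 7)
        a_seg = d.a[500:900]
        b_seg = d.b[550:950]
        assert np.std(a_seg) > 0
        assert np.corrcoef(a_seg, b_seg)[0, 1] == pytest.approx(1.0)

    def test_schedule_passed_through_as_ground_truth(self):
        cfg = DyadConfig(length_frames=2000)
        sched = [CouplingInterval(100, 400, -10, 0.5, -1)]
        d = generate_coupled_dyad(cfg, sched, 1)
        assert d.schedule == sched

    def test_interval_beyond_bounds_rejected(self):
        cfg = DyadConfig(length_frames=1000)
        with pytest.raises(ValueError):
            generate_coupled_dyad(cfg, [CouplingInterval(800, 1100, 0, 1.0)], 1)
        with pytest.raises(ValueError):
            generate_coupled_dyad(cfg, [CouplingInterval(600, 990, 20, 1.0)], 1)


class TestCohort:
    def test_exact_group_allocation(self):
        cfg = CohortConfig(n_dyads=30, dyad=DyadConfig(length_frames=400,
                                                       burst_rate=0.5),
                           interval_rate_per_min=0.0, seed=5)
        dyads, table = generate_cohort(cfg)
        assert len(dyads) == 30
        assert (table["group"] == "control").sum() == 15
        assert (table["group"] == "patient").sum() == 15

    def test_symptoms_monotone_in_coupling_without_noise(self):
        sm = SymptomModel(intercept=20.0, slope=-10.0, noise_sd=0.0,
                          group_offset=0.0, max_score=27)
        cfg = CohortConfig(n_dyads=20, phq9=sm, coupling_effect=0.0,
                           dyad=DyadConfig(length_frames=400, burst_rate=0.5),
                           interval_rate_per_min=0.0, seed=2)
        _, table = generate_cohort(cfg)
        # slope < 0: score strictly decreasing in coupling up to truncation ties
        order = table.sort_values("coupling_beta")["phq9"].to_numpy()
        assert (np.diff(order) <= 0).all()

    def test_scores_respect_instrument_ranges(self):
        cfg = CohortConfig(n_dyads=12, dyad=DyadConfig(length_frames=400,
                                                       burst_rate=0.5),
                           interval_rate_per_min=0.0, seed=9)
        _, table = generate_cohort(cfg)
        assert table["phq9"].between(0, 27).all()
        assert table["gad7"].between(0, 21).all()

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_dyads=3)


class TestFrameStack:
    def test_static_object_gives_identical_frames(self):
        fs = generate_frame_stack(20, 20, 5, object_size=4, step_px=0, seed=3)
        assert (np.diff(fs.frames.astype(int), axis=0) == 0).all()

    def test_step_changes_symmetric_difference_area(self):
        fs = generate_frame_stack(30, 40, 6, object_size=5, step_px=1, seed=0)
        for t in range(5):
            changed = (fs.frames[t + 1].astype(int) != fs.frames[t].astype(int)).sum()
            assert changed == 2 * 5  # two 5x1 strips enter/leave

    def test_seed_moves_start_but_not_change_counts(self):
        counts = []
        for seed in (1, 2, 3):
            fs = generate_frame_stack(30, 60, 8, object_size=6, step_px=2, seed=seed)
            counts.append([(fs.frames[t + 1].astype(int) != fs.frames[t].astype(int)).sum()
                           for t in range(7)])
        assert counts[0] == counts[1] == counts[2]

    def test_object_leaving_frame_rejected(self):
        with pytest.raises(ValueError):
            generate_frame_stack(10, 12, 10, object_size=5, step_px=1)
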