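"""Simulator contracts: exponential ground truth, determinism, feasibility."""

import numpy as np
import pandas as pd
import pytest

from fpturnover import (
    QuantConfig,
    SimConfig,
    fit_decay,
    quantify_frame,
    simulate_daily_decay,
    simulate_halflife_table,
    simulate_plate_series,
    simulate_video_experiment,
)
from fpturnover.errors import ConfigurationError

LN2 = np.log(2.0)


class TestVideoExperiment:
    def test_noiseless_halving_per_day(self):
        cfg = SimConfig(n_flies=1, peak_day=0, true_half_life=1.0, noise_sd=0.0,
                        n_days=3, n_vials=1, n_frames_per_day=2, seed=3)
        stacks, truth = simulate_video_experiment(cfg)
        day0 = truth.true_total(0, 0)
        day1 = truth.true_total(1, 0)
        assert day1 == pytest.approx(0.5 * day0)
        # and the rendered frames carry exactly those totals
        qc = QuantConfig(threshold=cfg.background_level + 1,
                         roi=(0, cfg.frame_shape[0], 0, cfg.frame_shape[1]))
        measured0 = quantify_frame(stacks[(0, 0, 0)].frames[0], qc).total_fluorescence
        measured1 = quantify_frame(stacks[(1, 0, 0)].frames[0], qc).total_fluorescence
        assert measured0 == pytest.approx(day0)
        assert measured1 == pytest.approx(day1)

    def test_ground_truth_is_exactly_exponential_after_peak(self):
        cfg = SimConfig(noise_sd=0.0, n_vials=1, n_frames_per_day=1, seed=0)
        _, truth = simulate_video_experiment(cfg)
        df = truth.per_day_vial
        post = df[df["day"] >= cfg.peak_day].sort_values("day")
        lnf = np.log(post["true_total"].to_numpy())
        slopes = np.diff(lnf)
        assert slopes == pytest.approx(truth.true_slope, abs=1e-12)
        assert truth.true_slope == pytest.approx(-LN2 / cfg.true_half_life)

    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_days=2, n_vials=1, n_frames_per_day=3, seed=11)
        s1, _ = simulate_video_experiment(cfg)
        s2, _ = simulate_video_experiment(cfg)
        for key in s1:
            for f1, f2 in zip(s1[key].frames, s2[key].frames):
                assert np.array_equal(f1, f2)

    def test_different_seeds_differ(self):
        a, _ = simulate_video_experiment(SimConfig(n_days=1, peak_day=0, n_vials=1,
                                                   n_frames_per_day=1, seed=1))
        b, _ = simulate_video_experiment(SimConfig(n_days=1, peak_day=0, n_vials=1,
                                                   n_frames_per_day=1, seed=2))
        assert not np.array_equal(a[(0, 0, 0)].frames[0], b[(0, 0, 0)].frames[0])

    def test_cameras_are_independent_views(self):
        stacks, truth = simulate_video_experiment(
            SimConfig(n_days=1, peak_day=0, n_vials=1, n_frames_per_day=1,
                      noise_sd=0.0, seed=5)
        )
        t = truth.trajectories
        assert not np.allclose(t[(0, 0, 0)], t[(0, 0, 1)])

    def test_flies_stay_inside_vial_roi(self):
        cfg = SimConfig(n_days=2, n_vials=1, n_frames_per_day=50, seed=9)
        _, truth = simulate_video_experiment(cfg)
        r = cfg.fly_radius_px
        h, w = cfg.frame_shape
        for traj in truth.trajectories.values():
            assert traj[..., 0].min() >= r and traj[..., 0].max() <= h - 1 - r
            assert traj[..., 1].min() >= r and traj[..., 1].max() <= w - 1 - r

    def test_frame_too_small_for_flies_rejected(self):
        with pytest.raises(ConfigurationError, match="non-overlapping"):
            SimConfig(frame_shape=(8, 8), n_flies=10, fly_radius_px=2)

    def test_intensity_ordering_invariants_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(fly_peak_intensity=10.0, background_level=20.0)


class TestPlateSeries:
    def test_noiseless_half_at_one_half_life(self):
        df = simulate_plate_series(78.0, duration_min=156.0, noise_cv=0.0)
        f0 = df["fluorescence"].iloc[0]
        at_78 = df.loc[np.isclose(df["time_min"], 78.0), "fluorescence"].iloc[0]
        assert at_78 == pytest.approx(0.5 * f0)

    def test_noiseless_fit_recovers_slope_to_machine_precision(self):
        df = simulate_plate_series(78.0, duration_min=60.0, noise_cv=0.0)
        fit = fit_decay(df["time_min"], df["fluorescence"],
                        window=(0, len(df) - 1), time_unit="minutes")
        assert fit.slope == pytest.approx(-LN2 / 78.0, abs=1e-12)
        assert fit.half_life == pytest.approx(78.0, abs=1e-9)

    def test_timestamps_every_30_seconds_in_minutes(self):
        df = simulate_plate_series(10.0, duration_min=2.0)
        assert df["time_min"].tolist() == pytest.approx([0.0, 0.5, 1.0, 1.5, 2.0])

    def test_seeded_noise_is_reproducible(self):
        a = simulate_plate_series(78.0, 10.0, noise_cv=0.1, seed=4)
        b = simulate_plate_series(78.0, 10.0, noise_cv=0.1, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_half_life_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_plate_series(0.0, 10.0)


class TestHalflifeTable:
    def test_balanced_design(self):
        tab = simulate_halflife_table(5, seed=0)
        counts = tab.groupby(["age_group", "sex"]).size()
        assert (counts == 5).all() and len(counts) == 4

    def test_zero_effects_zero_noise_constant_response(self):
        tab = simulate_halflife_table(3, residual_sd=0.0, seed=0)
        assert tab["half_life"].nunique() == 1

    def test_effects_shift_cell_means(self):
        tab = simulate_halflife_table(
            4, effects={"age": 2.0, "sex": -1.0, "interaction": 0.5},
            residual_sd=0.0, baseline=4.0, seed=0,
        )
        m = tab.groupby(["age_group", "sex"])["half_life"].mean()
        assert m[("young", "male")] == pytest.approx(4.0)
        assert m[("old", "male")] == pytest.approx(6.0)
        assert m[("young", "female")] == pytest.approx(3.0)
        assert m[("old", "female")] == pytest.approx(5.5)

    def test_unknown_effect_name_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_halflife_table(3, effects={"mating": 1.0})


class TestDailyDecay:
    def test_noiseless_series_is_exact(self):
        t, f = simulate_daily_decay(3.5, n_days=6, noise_cv=0.0)
        assert f == pytest.approx(1000.0 * 2.0 ** (-t / 3.5))

    def test_noise_is_multiplicative_and_seeded(self):
        t1, f1 = simulate_daily_decay(3.5, noise_cv=0.2, seed=8)
        t2, f2 = simulate_daily_decay(3.5, noise_cv=0.2, seed=8)
        assert np.array_equal(f1, f2)
        assert (f1 > 0).all()
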