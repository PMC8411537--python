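"""Track IO, filtering, smoothing, and per-larva statistics."""

import numpy as np
import pandas as pd
import pytest

import larvakin as lk
from larvakin.kinematics import TrackDataError, TrackFormatError


def make_table(n_larvae=2, n_frames=400, speed_px=0.2, angle=0.0, fps=5.0,
               px_scale=0.13):
    rows = []
    for i in range(n_larvae):
        frames = np.arange(n_frames)
        rows.append(
            pd.DataFrame(
                {
                    "larva_id": f"L{i}",
                    "frame": frames,
                    "x_px": 50.0 + speed_px * frames,
                    "y_px": 50.0,
                    "bend_angle_deg": angle,
                }
            )
        )
    return lk.TrackTable(pd.concat(rows, ignore_index=True), fps=fps,
                         px_scale=px_scale)


class TestReadTracks:
    def test_long_round_trip(self, tmp_path):
        table = make_table(n_larvae=2, n_frames=400)
        path = tmp_path / "tracks.csv"
        lk.write_tracks(table, path, "long")
        back = lk.read_tracks(path, "long")
        assert back.larva_ids == ["L0", "L1"]
        assert len(back.data) == 800
        pd.testing.assert_frame_equal(back.data, table.data, check_dtype=False)

    def test_wide_dialect_equivalent_to_long(self, tmp_path):
        table = lk.simulate_larva_track(
            lk.SpeciesBehaviorParams(n_larvae=3, n_frames=200), seed=7
        )
        long_p = tmp_path / "long.csv"
        wide_p = tmp_path / "wide.csv"
        lk.write_tracks(table, long_p, "long")
        lk.write_tracks(table, wide_p, "fimtrack_wide")
        a = lk.read_tracks(long_p, "long")
        b = lk.read_tracks(wide_p, "fimtrack_wide")
        for col in ("x_px", "y_px", "bend_angle_deg"):
            np.testing.assert_allclose(
                a.data[col].to_numpy(), b.data[col].to_numpy(), rtol=0, atol=1e-9
            )

    def test_duplicate_frame_rejected(self, tmp_path):
        df = make_table(1, 10).data
        df = pd.concat([df, df.iloc[[3]]], ignore_index=True)
        path = tmp_path / "dup.csv"
        df.to_csv(path, index=False)
        with pytest.raises(TrackDataError, match="duplicated"):
            lk.read_tracks(path)

    def test_missing_columns_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"larva_id": [1], "frame": [0]}).to_csv(path, index=False)
        with pytest.raises(TrackFormatError, match="x_px"):
            lk.read_tracks(path)


class TestFilterTracks:
    @pytest.mark.parametrize(
        "n_frames,min_frames,kept",
        [(300, 300, False), (301, 300, True), (200, 150, True), (150, 150, False)],
    )
    def test_strictly_more_than(self, n_frames, min_frames, kept):
        table = make_table(1, n_frames)
        out = lk.filter_tracks(table, min_frames=min_frames)
        assert (len(out.data) > 0) == kept

    def test_truncates_to_longest_contiguous_run(self):
        df = make_table(1, 500).data
        df = df[(df["frame"] < 100) | (df["frame"] >= 150)]  # gap at 100-149
        table = lk.TrackTable(df.reset_index(drop=True))
        out = lk.filter_tracks(table, min_frames=300)
        assert len(out.data) == 350
        assert out.data["frame"].min() == 150

    def test_empty_result_is_empty_table(self):
        out = lk.filter_tracks(make_table(1, 100), min_frames=300)
        assert out.data.empty


class TestSmoothSeries:
    def test_constant_unchanged(self):
        np.testing.assert_allclose(lk.smooth_series([3.0] * 10, 5), 3.0)

    def test_impulse_center_value(self):
        out = lk.smooth_series([0, 0, 5, 0, 0], 5)
        assert out[2] == pytest.approx(1.0)
        assert len(out) == 5

    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=20)
        np.testing.assert_array_equal(lk.smooth_series(x, 1), x)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            lk.smooth_series([1, 2, 3], 4)

    def test_oversized_window_returns_global_mean(self):
        with pytest.warns(UserWarning):
            out = lk.smooth_series([1.0, 2.0, 3.0], 5)
        np.testing.assert_allclose(out, 2.0)


class TestCentroidSpeed:
    def test_constant_pixel_step_converts_to_mm_per_s(self):
        # 0.2 px/frame * 0.13 mm/px * 5 frames/s = 0.13 mm/s
        table = make_table(1, 100, speed_px=0.2)
        speeds = lk.centroid_speed(table, smooth=False)
        np.testing.assert_allclose(speeds, 0.13)

    def test_stationary_larva_zero(self):
        table = make_table(1, 100, speed_px=0.0)
        np.testing.assert_allclose(lk.centroid_speed(table, smooth=False), 0.0)

    def test_smoothing_reduces_jitter_variance(self, rng):
        df = make_table(1, 400, speed_px=0.2).data.copy()
        df["x_px"] += rng.normal(0, 0.5, len(df))
        table = lk.TrackTable(df)
        raw = lk.centroid_speed(table, smooth=False)
        smoothed = lk.centroid_speed(table, smooth=True)
        assert smoothed.std() < raw.std()


class TestLabelFrames:
    @pytest.mark.parametrize(
        "angle,label",
        [(25.0, "bending"), (-25.0, "bending"), (20.0, "crawling"),
         (0.0, "crawling"), (-20.0, "crawling")],
    )
    def test_threshold_boundary(self, angle, label):
        table = make_table(1, 10, angle=angle)
        assert (lk.label_frames(table) == label).all()

    def test_lower_threshold_never_decreases_bend_probability(self, rng):
        params = lk.SpeciesBehaviorParams(n_larvae=4, n_frames=400, bend_rate=0.4)
        table = lk.simulate_larva_track(params, seed=3)
        probs = []
        for th in (30.0, 20.0, 10.0, 5.0):
            res = lk.larva_kinematics(table, threshold_deg=th, smooth=False)
            probs.append(np.mean([l.bend_probability for l in res]))
        assert np.all(np.diff(probs) >= 0)


class TestLarvaKinematics:
    def test_bend_probability_is_bending_fraction(self):
        df = make_table(1, 10).data.copy()
        df.loc[df.index[:3], "bend_angle_deg"] = 40.0
        table = lk.TrackTable(df)
        res = lk.larva_kinematics(table, smooth=False)
        assert res[0].bend_probability == pytest.approx(0.3)

    def test_crawling_speed_is_median_over_crawling_frames(self):
        df = make_table(1, 6, speed_px=0.0).data.copy()
        # plant speeds 0.8/1.0/1.2 mm/s on crawling frames, bend the rest
        steps_mm = np.array([0.8, 0.8, 1.0, 1.0, 1.2]) / 5.0
        df["x_px"] = np.concatenate(([0], np.cumsum(steps_mm / 0.13)))
        df.loc[df.index[0], "bend_angle_deg"] = 90.0  # first frame bends
        table = lk.TrackTable(df)
        res = lk.larva_kinematics(table, smooth=False)
        assert res[0].crawling_speed == pytest.approx(1.0, rel=1e-9)

    def test_straight_run_distance_60mm_per_minute(self):
        # 1 mm/s for 300 frames at 5 fps = 60 s -> 60 mm displacement
        table = make_table(1, 300, speed_px=(1.0 / 5.0) / 0.13)
        res = lk.larva_kinematics(table, smooth=False)
        assert res[0].crawling_distance_1min == pytest.approx(60.0, rel=0.01)

    def test_backward_requires_head_tail(self):
        table = make_table(1, 50)
        res = lk.larva_kinematics(table, smooth=False)
        assert res[0].backward is None

    def test_backward_bout_detected_in_simulation(self):
        params = lk.SpeciesBehaviorParams(
            n_larvae=10, n_frames=400, bend_rate=0.0, backward_bout_prob=1.0,
            heading_diffusion=0.0, run_speed_sd=0.0,
        )
        table = lk.simulate_larva_track(params, seed=11)
        res = lk.larva_kinematics(table, smooth=False)
        assert all(l.backward for l in res)

    def test_no_backward_when_prob_zero(self):
        params = lk.SpeciesBehaviorParams(
            n_larvae=6, n_frames=400, bend_rate=0.0, backward_bout_prob=0.0
        )
        table = lk.simulate_larva_track(params, seed=11)
        res = lk.larva_kinematics(table, smooth=False)
        assert not any(l.backward for l in res)


class TestSpeciesSummary:
    def test_single_larva_median_and_zero_sem(self):
        l = lk.LarvaKinematics("a", 0.2, 1.0, 30.0, False, 400)
        s = lk.species_summary([l], species="x")
        assert s.median["bend_probability"] == 0.2
        assert s.sem["bend_probability"] == 0.0

    def test_backward_binomial_se(self):
        larvae = [
            lk.LarvaKinematics(i, 0.1, 1.0, 30.0, flag, 400)
            for i, flag in enumerate([True, False, False, False])
        ]
        s = lk.species_summary(larvae)
        assert s.backward_probability == pytest.approx(0.25)
        assert s.backward_se == pytest.approx(np.sqrt(0.25 * 0.75 / 4), abs=1e-6)
        assert s.backward_se == pytest.approx(0.2165, abs=5e-4)

    def test_median_permutation_invariant(self, rng):
        larvae = [
            lk.LarvaKinematics(i, rng.random(), rng.random(), None, None, 400)
            for i in range(9)
        ]
        s1 = lk.species_summary(larvae)
        perm = [larvae[i] for i in rng.permutation(9)]
        s2 = lk.species_summary(perm)
        assert s1.median == s2.median
        assert s1.sem["bend_probability"] == pytest.approx(s2.sem["bend_probability"])

    def test_median_zero_of_mostly_zeros(self):
        larvae = [
            lk.LarvaKinematics(i, v, 1.0, None, None, 400)
            for i, v in enumerate([0.0, 0.0, 1.0])
        ]
        assert lk.species_summary(larvae).median["bend_probability"] == 0.0

    def test_empty_summary_rejected(self):
        with pytest.raises(ValueError):
            lk.species_summary([])
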