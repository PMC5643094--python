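import numpy as np
import pytest
from scipy import stats as sstats

from ootrack.analytics import (
    AnalyticsError,
    comet_lifespan,
    compare_groups,
    compute_track_stats,
    direction_histogram,
    distance_binned_frequency,
    mobile_fraction,
    net_angle,
    posterior_fraction,
    speed_by_region,
    subpopulation_test,
    track_speed,
)
from ootrack.synthetic import OskarSimParams, generate_oskar_tracks
from ootrack.tracks import TrackSet

from conftest import make_track, random_trackset


def _angle_tracks(angles_deg, geom, start=(0.0, 0.0), length=2.0):
    """One 2-point track per angle, measured about the pole direction."""
    start = np.asarray(start, dtype=float)
    u_pole = geom.posterior_pole - start
    u_pole = u_pole / np.hypot(*u_pole)
    tracks = []
    for i, a in enumerate(angles_deg):
        th = np.radians(a)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        disp = R @ u_pole * length
        tracks.append(make_track([start, start + disp], track_id=f"a{i:05d}", kind="oskar"))
    return TrackSet.from_tracks(tracks)


class TestTrackSpeed:
    def test_constant_velocity(self):
        xy = np.column_stack([np.arange(5) * 0.36, np.zeros(5)])
        assert track_speed(make_track(xy, dt=1.0)) == pytest.approx(0.36)

    def test_arithmetic_mean_of_step_speeds(self):
        tr = make_track([(0, 0), (0.2, 0), (0.6, 0)], dt=1.0)
        assert track_speed(tr) == pytest.approx(0.30)

    def test_matches_step_scan_oracle(self, rng):
        xy = np.cumsum(rng.normal(0, 0.3, (50, 2)), axis=0)
        tr = make_track(xy, dt=1.7)
        expect = np.mean(
            [np.hypot(*(xy[i + 1] - xy[i])) / 1.7 for i in range(len(xy) - 1)]
        )
        assert track_speed(tr) == pytest.approx(expect, abs=1e-12)

    def test_single_point_signalled(self):
        with pytest.raises(AnalyticsError):
            track_speed(make_track([(0, 0)]))

    def test_rigid_motion_invariance(self, rng):
        ts = random_trackset(rng, n_tracks=20)
        moved = ts.transformed(rotation_deg=63.0, shift=(5.0, -3.0))
        for a, b in zip(ts, moved):
            assert track_speed(a) == pytest.approx(track_speed(b), abs=1e-9)


class TestNetAngle:
    def test_toward_pole_is_zero(self, geom):
        tr = make_track([(0, 0), (5, 0)])
        assert net_angle(tr, geom) == pytest.approx(0.0, abs=1e-9)

    def test_away_from_pole_is_180(self, geom):
        tr = make_track([(0, 0), (-5, 0)])
        assert abs(net_angle(tr, geom)) == pytest.approx(180.0, abs=1e-9)

    def test_perpendicular_left_is_plus_90(self, geom):
        # pole direction is +x from the origin; counter-clockwise 90 deg = +y
        tr = make_track([(0, 0), (0, 5)])
        assert net_angle(tr, geom) == pytest.approx(90.0, abs=1e-9)

    def test_zero_net_displacement_signalled(self, geom):
        with pytest.raises(AnalyticsError):
            net_angle(make_track([(0, 0), (1, 0), (0, 0)]), geom)


class TestLifespan:
    @pytest.mark.parametrize("n_frames,expect", [(7, 10.2), (2, 1.7)])
    def test_lifespan_arithmetic(self, n_frames, expect):
        tr = make_track(np.zeros((n_frames, 2)), dt=1.7)
        assert comet_lifespan(tr, 1.7) == pytest.approx(expect)


class TestPosteriorFraction:
    def test_all_toward_pole(self, geom):
        ts = _angle_tracks(np.zeros(20), geom)
        pct, se, n = posterior_fraction(ts, geom, band=(0.0, 50.0))
        assert (pct, n) == (100.0, 20)

    def test_isotropic_null_is_50_percent(self, geom, rng):
        ts = _angle_tracks(rng.uniform(-180, 180, 10_000), geom)
        pct, se, _n = posterior_fraction(ts, geom, band=(0.0, 50.0))
        assert abs(pct - 50.0) < 3 * se

    def test_generator_bias_round_trip(self, geom):
        p = OskarSimParams(
            n_particles=2000, mobile_fraction=1.0, bias_by_band={0: 0.71}, seed=3
        )
        ts = generate_oskar_tracks(p, geom)
        pct, se, n = posterior_fraction(ts, geom, band=(0.0, 10.0))
        assert n >= 30
        assert abs(pct - 71.0) < 3 * max(se, 100 * np.sqrt(0.71 * 0.29 / n))

    def test_mirror_symmetry(self, geom, rng):
        """Reflecting all tracks across the AP axis leaves the posterior
        fraction unchanged."""
        ts = _angle_tracks(rng.uniform(-180, 180, 500), geom)
        mirrored = ts.df.copy()
        mirrored["y_um"] = -mirrored["y_um"]
        tsm = TrackSet(mirrored, validate=False)
        assert posterior_fraction(ts, geom, (0, 50))[0] == pytest.approx(
            posterior_fraction(tsm, geom, (0, 50))[0]
        )

    def test_empty_band_signalled(self, geom):
        ts = _angle_tracks([0.0], geom)
        with pytest.raises(AnalyticsError):
            posterior_fraction(ts, geom, band=(49.0, 49.5))


class TestDirectionHistogram:
    def test_one_track_per_bin(self, geom):
        ts = _angle_tracks(np.arange(5.0, 360.0, 10.0), geom)
        h = direction_histogram(ts, geom, bands=((0.0, 50.0),))
        assert (h["count"] == 1).all()

    def test_single_direction_single_bin(self, geom):
        ts = _angle_tracks(np.zeros(17), geom)
        h = direction_histogram(ts, geom, bands=((0.0, 50.0),))
        assert h["count"].max() == 17 and h["count"].sum() == 17

    def test_counts_match_tally_oracle_and_conserve(self, geom, rng):
        angles = rng.uniform(-180, 180, 400)
        ts = _angle_tracks(angles, geom)
        h = direction_histogram(ts, geom, bands=((0.0, 50.0),))
        tally = np.zeros(36, dtype=int)
        for a in angles:
            tally[int(np.floor((a % 360.0) / 10.0)) % 36] += 1
        assert np.array_equal(h["count"].to_numpy(), tally)
        assert h["count"].sum() == len(angles)


class TestDistanceBinnedFrequency:
    def test_point_mass_in_first_band(self, geom):
        ts = _angle_tracks(np.zeros(9), geom, start=(23.4, 0.0))  # 1.6 um from pole
        t = distance_binned_frequency(ts, geom)
        assert t["freq"].iloc[0] == pytest.approx(1.0)

    def test_frequencies_sum_to_one(self, geom, rng):
        ts = random_trackset(rng, n_tracks=300, geom=geom)
        t = distance_binned_frequency(ts, geom, d_range=(0.0, 60.0))
        assert t["freq"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_starts_flat_within_noise(self, geom, rng):
        d = rng.uniform(0, 50, 10_000)
        tracks = TrackSet.from_tracks(
            [
                make_track([(25.0 - di, 0.0), (25.0 - di + 0.1, 0.0)], track_id=f"u{i}")
                for i, di in enumerate(d)
            ]
        )
        t = distance_binned_frequency(tracks, geom)
        se = np.sqrt(0.1 * 0.9 / 10_000)
        assert np.all(np.abs(t["freq"] - 0.1) < 3 * se + 1e-12)

    def test_matches_floor_division_tally(self, geom, rng):
        ts = random_trackset(rng, n_tracks=200, geom=geom)
        t = distance_binned_frequency(ts, geom, d_range=(0.0, 80.0))
        starts = [np.hypot(*(tr.xy[0] - geom.posterior_pole)) for tr in ts]
        tally = np.zeros(16, dtype=int)
        for d in starts:
            if 0 <= d < 80:
                tally[int(d // 5)] += 1
        assert np.array_equal(t["n"].to_numpy(), tally)


class TestSpeedByRegion:
    def test_constant_speed_both_regions(self, geom):
        tracks = []
        for i, x0 in enumerate([20.0, 5.0]):  # 5 and 20 um from pole at (25, 0)
            xy = np.column_stack([x0 + np.arange(6) * 0.23 * 1.7, np.zeros(6)])
            tracks.append(make_track(xy, track_id=f"c{i}"))
        t = speed_by_region(TrackSet.from_tracks(tracks), geom)
        assert np.allclose(t["mean_speed"], 0.23)

    def test_region_assignment_matches_brute_force(self, geom, rng):
        ts = random_trackset(rng, n_tracks=150, geom=geom)
        t = speed_by_region(ts, geom, regions=((0.0, 15.0), (15.0, 30.0)))
        n_near = n_far = 0
        for tr in ts:
            if len(tr) < 3:
                continue
            d = np.hypot(*(tr.xy[0] - geom.posterior_pole))
            if 0 <= d < 15:
                n_near += 1
            elif 15 <= d < 30:
                n_far += 1
        assert list(t["n"]) == [n_near, n_far]


class TestMobileFraction:
    def test_all_static_is_zero(self):
        ts = TrackSet.from_tracks([make_track(np.zeros((5, 2)), track_id=f"s{i}") for i in range(10)])
        assert mobile_fraction(ts)[0] == 0.0

    def test_threshold_above_any_displacement(self, rng):
        ts = random_trackset(rng, n_tracks=30)
        assert mobile_fraction(ts, min_net_displacement=1e6)[0] == 0.0

    def test_threshold_must_be_positive(self, rng):
        with pytest.raises(AnalyticsError):
            mobile_fraction(random_trackset(rng, 5), min_net_displacement=0.0)


class TestSubpopulationTest:
    def test_no_subpopulation_gives_near_zero_weight(self, rng):
        osk = rng.normal(0.47, 0.1, 500)
        eb1 = rng.normal(0.23, 0.05, 500)
        r = subpopulation_test(osk, eb1, n_boot=99, seed=1)
        assert r["pinned_weight"] < 0.05
        assert r["p_value"] > 0.05

    def test_half_mixture_recovered(self, rng):
        eb1 = rng.normal(0.23, 0.05, 500)
        osk = np.concatenate([rng.normal(0.23, 0.1, 300), rng.normal(0.47, 0.1, 300)])
        r = subpopulation_test(osk, eb1, n_boot=99, seed=1)
        assert abs(r["pinned_weight"] - 0.5) < 0.1
        assert r["p_value"] < 0.05

    def test_null_pvalues_are_uniform(self, rng):
        """When mRNP and comet speeds share one Gaussian distribution the
        parametric-bootstrap LRT p-values are uniform."""
        ps = []
        for i in range(100):
            eb1 = rng.normal(0.23, 0.05, 200)
            osk = rng.normal(0.23, 0.05, 120)
            ps.append(subpopulation_test(osk, eb1, n_boot=49, seed=i)["p_value"])
        assert sstats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_sample_signalled(self):
        with pytest.raises(AnalyticsError):
            subpopulation_test(np.full(100, 0.4), np.random.default_rng(0).normal(0.23, 0.05, 100))


class TestCompareGroups:
    def test_identical_groups_rank_sum_p_is_one(self, rng):
        x = rng.normal(0, 1, 30)
        r = compare_groups(x, x.copy())
        assert r["all_tests"]["rank_sum"][1] == pytest.approx(1.0)

    def test_clear_shift_detected(self, rng):
        r = compare_groups(rng.normal(0, 1, 100), rng.normal(2, 1, 100))
        assert r["p"] < 1e-6

    def test_heavy_tails_select_rank_sum(self, rng):
        a = rng.standard_cauchy(80)
        b = rng.standard_cauchy(80) + 3
        r = compare_groups(a, b)
        assert r["test_used"] == "rank_sum"

    def test_small_samples_signalled(self):
        with pytest.raises(AnalyticsError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])
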