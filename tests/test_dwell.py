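import numpy as np
import pytest
from scipy import stats as sstats

from ootrack.dwell import (
    DwellError,
    DwellEvent,
    compare_regions,
    dwell_time,
    fit_t_location_scale,
    render_kymograph,
    select_cortex_tracks,
)
from ootrack.geometry import build_geometry, distances_to_cortex, nearest_cortex_info
from ootrack.synthetic import EB1SimParams, generate_eb1_tracks
from ootrack.tracks import TrackSet

from conftest import make_track


def _event(dwell, region="posterior", tid="t0"):
    return DwellEvent(tid, 0.0, dwell, dwell, region, 90.0, 1)


class TestSelection:
    def test_track_staying_clear_of_cortex_yields_no_event(self, geom):
        xy = np.column_stack([np.linspace(-5, 5, 10), np.zeros(10)])
        ts = TrackSet.from_tracks([make_track(xy)])
        assert select_cortex_tracks(ts, geom) == []

    def test_perpendicular_hit_has_90_degree_approach(self, geom):
        # straight toward the pole vertex at (25, 0): cortex tangent is ~ +/-y
        xy = np.column_stack([np.linspace(15.0, 24.5, 12), np.zeros(12)])
        ts = TrackSet.from_tracks([make_track(xy)])
        events = select_cortex_tracks(ts, geom)
        assert len(events) == 1
        assert events[0].approach_angle == pytest.approx(90.0, abs=5.0)
        assert events[0].cortex_region == "posterior"

    def test_grazing_track_excluded(self):
        # square cortex with a flat top edge; track creeps toward it at ~7 deg
        pts = [(0, 0), (5, 0), (10, 0), (10, 5), (10, 10), (5, 10), (0, 10), (0, 5)]
        labels = ["lateral"] * 2 + ["posterior"] + ["lateral"] * 5
        g = build_geometry(pts, (10.0, 2.5), (1, 0), labels)
        xy = np.column_stack([2.0 + 0.5 * np.arange(12), 8.5 + 0.06 * np.arange(12)])
        ts = TrackSet.from_tracks([make_track(xy)])
        assert select_cortex_tracks(ts, g) == []

    def test_track_born_in_contact_excluded(self, geom):
        xy = np.column_stack([np.linspace(24.5, 20.0, 6), np.zeros(6)])
        ts = TrackSet.from_tracks([make_track(xy)])
        assert select_cortex_tracks(ts, geom) == []


class TestDwellTime:
    def test_subtraction(self):
        e = DwellEvent("t", 10.2, 25.5, 15.3, "posterior", 45.0, 6)
        assert dwell_time(e) == pytest.approx(15.3)

    def test_contact_at_final_frame_is_zero(self, geom):
        xy = np.column_stack([np.linspace(15.0, 24.3, 8), np.zeros(8)])
        ts = TrackSet.from_tracks([make_track(xy)])
        (event,) = select_cortex_tracks(ts, geom)
        assert event.contact_index == 7
        assert event.dwell == 0.0

    def test_pipeline_matches_brute_force(self, geom):
        """select -> dwell must agree event-for-event with an independent
        per-frame distance scan plus explicit angle computation."""
        params = EB1SimParams(n_comets=300, seed=21)
        ts = generate_eb1_tracks(params, geom)
        events = {e.track_id: e for e in select_cortex_tracks(ts, geom)}

        expected = {}
        for tr in ts:
            if len(tr) < 2:
                continue
            d = np.array([distances_to_cortex(p, geom)[0] for p in tr.xy])
            hit = np.nonzero(d < 1.0)[0]
            if len(hit) == 0 or hit[0] == 0:
                continue
            i = int(hit[0])
            heading = tr.xy[i] - tr.xy[max(0, i - 3)]
            if np.hypot(*heading) == 0:
                continue
            _cp, region, tangent = nearest_cortex_info(tr.xy[i], geom)
            cosang = abs(np.dot(heading, tangent)) / np.hypot(*heading)
            ang = np.degrees(np.arccos(min(cosang, 1.0)))
            if ang < 20.0:
                continue
            expected[tr.track_id] = (i, float(tr.t[-1] - tr.t[i]),
                                     "lateral" if region == "anterior" else region)

        assert set(events) == set(expected)
        for tid, (idx, dw, region) in expected.items():
            assert events[tid].contact_index == idx
            assert events[tid].dwell == pytest.approx(dw, abs=1e-9)
            assert events[tid].cortex_region == region

    def test_rigid_transform_invariance(self, geom):
        params = EB1SimParams(n_comets=120, seed=22)
        ts = generate_eb1_tracks(params, geom)
        th = np.radians(31.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        g2 = build_geometry(geom.cortex @ R.T + [3, 4], R @ geom.posterior_pole + [3, 4],
                            R @ geom.ap_axis, list(geom.region_labels))
        ts2 = ts.transformed(rotation_deg=31.0, shift=(3.0, 4.0))
        d1 = sorted((e.track_id, round(e.dwell, 9)) for e in select_cortex_tracks(ts, geom))
        d2 = sorted((e.track_id, round(e.dwell, 9)) for e in select_cortex_tracks(ts2, g2))
        assert d1 == d2


class TestTFit:
    def test_parameter_recovery(self, rng):
        x = 15.0 + 4.0 * rng.standard_t(5, 10_000)
        fit = fit_t_location_scale(x)
        assert fit.mu == pytest.approx(15.0, rel=0.05)
        assert fit.sigma == pytest.approx(4.0, rel=0.10)
        assert fit.nu == pytest.approx(5.0, rel=0.10)

    def test_agrees_with_scipy_reference_fit(self, rng):
        x = 12.0 + 3.0 * rng.standard_t(8, 3000)
        fit = fit_t_location_scale(x)
        nu_s, mu_s, sig_s = sstats.t.fit(x)
        assert fit.mu == pytest.approx(mu_s, rel=1e-3)
        assert fit.sigma == pytest.approx(sig_s, rel=1e-2)
        assert fit.nu == pytest.approx(nu_s, rel=5e-2)

    def test_gaussian_sample_hits_nu_bound(self, rng):
        x = rng.normal(15, 4, 5000)
        fit = fit_t_location_scale(x)
        assert fit.nu > 50.0 or fit.nu_at_bound

    def test_small_sample_rejected(self):
        with pytest.raises(DwellError):
            fit_t_location_scale(np.arange(9.0))

    def test_summary_mentions_parameters(self, rng):
        fit = fit_t_location_scale(15.0 + 4.0 * rng.standard_t(5, 500))
        s = fit.summary()
        assert "mu" in s and "sigma" in s and "nu" in s


class TestCompareRegions:
    def test_identical_lists_give_no_difference(self, rng):
        events = [_event(d, "posterior", f"t{i}") for i, d in enumerate(rng.exponential(10, 40))]
        r = compare_regions(events, list(events))
        assert r["mean_posterior"] == pytest.approx(r["mean_lateral"])
        assert r["rank_sum_p"] == pytest.approx(1.0, abs=1e-9)

    def test_15s_vs_8s_exponential_generators(self, rng):
        post = [_event(d, "posterior", f"p{i}") for i, d in enumerate(rng.exponential(15, 150))]
        lat = [_event(d, "lateral", f"l{i}") for i, d in enumerate(rng.exponential(8, 150))]
        r = compare_regions(post, lat)
        for key, target in (("mean_posterior", 15.0), ("mean_lateral", 8.0)):
            se = target / np.sqrt(150)  # exponential: sd = mean
            assert abs(r[key] - target) < 3 * se
        assert r["rank_sum_p"] < 1e-6

    def test_empty_region_signalled(self):
        with pytest.raises(DwellError):
            compare_regions([], [_event(5.0)] * 5)


class TestKymograph:
    segment = np.array([[0.0, 0.0], [20.0, 0.0]])

    def test_static_comet_draws_vertical_line(self):
        xy = np.tile([7.3, 0.2], (20, 1))
        ts = TrackSet.from_tracks([make_track(xy)])
        k = render_kymograph(ts, self.segment, duration=19 * 1.7)
        assert k[7, :].sum() == 20
        assert k.sum() == 20

    def test_moving_comet_draws_diagonal(self):
        xy = np.column_stack([np.arange(10) * 1.0, np.zeros(10)])
        ts = TrackSet.from_tracks([make_track(xy)])
        k = render_kymograph(ts, self.segment, duration=9 * 1.7)
        rows = np.nonzero(k)[0]
        assert len(np.unique(rows)) == 10  # one arc bin per frame

    def test_empty_trackset_gives_zero_matrix(self):
        ts = TrackSet.from_tracks([])
        k = render_kymograph(ts, self.segment, duration=17.0)
        assert k.sum() == 0
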