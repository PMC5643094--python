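"""Per-track and population statistics for comet and mRNP trajectories.

Conventions (documented in the methods note):

* A track's *speed* is the mean of its frame-to-frame speeds.
* A track's *direction* is the net first-to-last displacement, expressed as a
  signed angle relative to the direction from the first point toward the
  posterior pole (0 deg = straight at the pole, +90 deg = perpendicular
  counter-clockwise).
* A track is assigned to a distance band by its *first* point's distance to
  the posterior pole.
* "Toward the posterior" means |net angle| < 90 deg (half-plane rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .geometry import OocyteGeometry
from .tracks import Track, TrackSet

#: default net-displacement threshold (um) for calling a track mobile
MOBILE_THRESHOLD = 1.0

#: minimum number of frames for a comet track to enter lifespan statistics
MIN_COMET_POINTS = 3


class AnalyticsError(ValueError):
    pass


def track_speed(track: Track) -> float:
    """Mean of the per-step speeds (um/s).  Needs >= 2 points."""
    if len(track) < 2:
        raise AnalyticsError(f"track {track.track_id}: speed undefined for < 2 points")
    steps = np.hypot(*np.diff(track.xy, axis=0).T)
    dts = np.diff(track.t)
    return float(np.mean(steps / dts))


def net_angle(track: Track, geom: OocyteGeometry) -> float:
    """Signed net direction (deg) relative to the pole direction, in (-180, 180]."""
    if len(track) < 2:
        raise AnalyticsError(f"track {track.track_id}: direction undefined for < 2 points")
    disp = track.xy[-1] - track.xy[0]
    if np.hypot(*disp) == 0.0:
        raise AnalyticsError(f"track {track.track_id}: zero net displacement")
    u_pole = geom.posterior_pole - track.xy[0]
    if np.hypot(*u_pole) == 0.0:
        raise AnalyticsError(f"track {track.track_id}: starts exactly at the pole")
    ang = math.degrees(
        math.atan2(
            u_pole[0] * disp[1] - u_pole[1] * disp[0],
            u_pole[0] * disp[0] + u_pole[1] * disp[1],
        )
    )
    if ang <= -180.0:
        ang += 360.0
    return ang


def comet_lifespan(track: Track, frame_dt: float | None = None) -> float:
    """Observed lifespan (n_frames - 1) * frame_dt in seconds."""
    if len(track) < 2:
        raise AnalyticsError(f"track {track.track_id}: lifespan undefined for < 2 points")
    dt = track.frame_dt if frame_dt is None else frame_dt
    return float((len(track) - 1) * dt)


def compute_track_stats(
    ts: TrackSet,
    geom: OocyteGeometry,
    mobile_threshold: float = MOBILE_THRESHOLD,
) -> pd.DataFrame:
    """Per-track summary: speed, net angle, start distance, lifespan, mobility.

    Tracks whose speed or angle is undefined get NaN in that column rather
    than being dropped, so every downstream statistic can apply its own
    filter.
    """
    rows = []
    for tr in ts:
        d0 = float(np.hypot(*(tr.xy[0] - geom.posterior_pole)))
        try:
            sp = track_speed(tr)
        except AnalyticsError:
            sp = np.nan
        try:
            ang = net_angle(tr, geom)
        except AnalyticsError:
            ang = np.nan
        life = (len(tr) - 1) * tr.frame_dt if len(tr) >= 2 else np.nan
        rows.append(
            {
                "track_id": tr.track_id,
                "kind": tr.kind,
                "n_points": len(tr),
                "speed": sp,
                "net_angle": ang,
                "start_distance": d0,
                "lifespan": life,
                "net_displacement": tr.net_displacement,
                "is_mobile": tr.net_displacement >= mobile_threshold,
            }
        )
    return pd.DataFrame(rows)


def posterior_fraction(ts: TrackSet, geom: OocyteGeometry, band=(0.0, 10.0)):
    """Percent of angle-defined tracks in ``band`` headed toward the pole.

    Returns ``(percent, se_percent, n)`` with a binomial standard error.
    The band filters on start distance and is half-open [lo, hi).
    """
    stats = compute_track_stats(ts, geom)
    lo, hi = band
    sel = stats[
        (stats.start_distance >= lo) & (stats.start_distance < hi) & stats.net_angle.notna()
    ]
    n = len(sel)
    if n == 0:
        raise AnalyticsError(f"no angle-defined tracks with start distance in [{lo}, {hi})")
    p = float(np.mean(np.abs(sel.net_angle) < 90.0))
    se = 100.0 * math.sqrt(p * (1.0 - p) / n)
    return 100.0 * p, se, n


def direction_histogram(
    ts: TrackSet,
    geom: OocyteGeometry,
    interval: float = 10.0,
    bands=((0.0, 10.0), (10.0, 20.0), (20.0, 30.0)),
) -> pd.DataFrame:
    """Counts of net track directions in ``interval``-degree bins per band.

    Angles are folded onto [0, 360) and binned half-open; both raw counts and
    per-band relative frequencies are returned (long form: band_lo, band_hi,
    angle_lo, count, freq).
    """
    if not float(360.0 / interval).is_integer():
        raise AnalyticsError("interval must divide 360")
    nbins = int(360.0 / interval)
    stats = compute_track_stats(ts, geom)
    out = []
    for lo, hi in bands:
        sel = stats[
            (stats.start_distance >= lo) & (stats.start_distance < hi) & stats.net_angle.notna()
        ]
        ang = np.mod(sel.net_angle.to_numpy(dtype=float), 360.0)
        idx = np.floor(ang / interval).astype(int) % nbins
        counts = np.bincount(idx, minlength=nbins)
        total = counts.sum()
        for k in range(nbins):
            out.append(
                {
                    "band_lo": lo,
                    "band_hi": hi,
                    "angle_lo": k * interval,
                    "count": int(counts[k]),
                    "freq": counts[k] / total if total else np.nan,
                }
            )
    return pd.DataFrame(out)


def distance_binned_frequency(
    ts: TrackSet,
    geom: OocyteGeometry,
    bin_width: float = 5.0,
    d_range=(0.0, 50.0),
) -> pd.DataFrame:
    """Relative frequency of track start positions per distance band.

    Tracks starting outside ``d_range`` are excluded; the returned ``freq``
    column sums to 1 over the included bands.
    """
    stats = compute_track_stats(ts, geom)
    lo, hi = d_range
    d = stats.start_distance.to_numpy(dtype=float)
    d = d[(d >= lo) & (d < hi)]
    nbins = int(math.ceil((hi - lo) / bin_width))
    idx = np.floor((d - lo) / bin_width).astype(int)
    counts = np.bincount(idx, minlength=nbins)
    total = counts.sum()
    return pd.DataFrame(
        {
            "band_lo": lo + bin_width * np.arange(nbins),
            "band_hi": lo + bin_width * (np.arange(nbins) + 1),
            "n": counts,
            "freq": counts / total if total else np.full(nbins, np.nan),
        }
    )


def speed_by_region(
    ts: TrackSet,
    geom: OocyteGeometry,
    regions=((0.0, 15.0), (15.0, 30.0)),
    min_points: int = MIN_COMET_POINTS,
) -> pd.DataFrame:
    """Mean comet speed per pole-distance region (n, mean, SEM).

    Region membership is decided by the track's start distance; tracks
    shorter than ``min_points`` frames are excluded (tracker convention).
    """
    stats = compute_track_stats(ts, geom)
    stats = stats[(stats.n_points >= min_points) & stats.speed.notna()]
    rows = []
    for lo, hi in regions:
        sel = stats[(stats.start_distance >= lo) & (stats.start_distance < hi)]
        if len(sel) == 0:
            raise AnalyticsError(f"no tracks in region [{lo}, {hi})")
        sp = sel.speed.to_numpy(dtype=float)
        rows.append(
            {
                "region_lo": lo,
                "region_hi": hi,
                "n": len(sp),
                "mean_speed": float(np.mean(sp)),
                "sem": float(np.std(sp, ddof=1) / math.sqrt(len(sp))) if len(sp) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def mobile_fraction(ts: TrackSet, min_net_displacement: float = MOBILE_THRESHOLD):
    """Percent of tracks whose net displacement reaches the threshold.

    Returns ``(percent, se_percent, n)``.
    """
    if min_net_displacement <= 0:
        raise AnalyticsError("min_net_displacement must be positive")
    disp = np.array([tr.net_displacement for tr in ts])
    n = len(disp)
    if n == 0:
        raise AnalyticsError("empty track set")
    p = float(np.mean(disp >= min_net_displacement))
    return 100.0 * p, 100.0 * math.sqrt(p * (1.0 - p) / n), n


# ---------------------------------------------------------------------------
# mRNP-vs-plus-end subpopulation test


@dataclass(frozen=True)
class MixtureFit:
    weight_pinned: float
    mu_pinned: float
    sigma_pinned: float
    mu_free: float
    sigma_free: float
    loglik: float


def _normal_loglik(x: np.ndarray) -> float:
    mu, sd = float(np.mean(x)), float(np.std(x))
    return float(np.sum(sstats.norm.logpdf(x, mu, sd)))


def _fit_pinned_mixture(
    x: np.ndarray, mu_pinned: float, n_iter: int = 300, tol: float = 1e-9
) -> MixtureFit:
    """EM for a two-component Gaussian mixture with one mean fixed."""
    w = 0.5
    s1 = s2 = float(np.std(x))
    mu2 = float(np.mean(x))
    ll_old = -np.inf
    for _ in range(n_iter):
        l1 = np.log(w + 1e-300) + sstats.norm.logpdf(x, mu_pinned, max(s1, 1e-6))
        l2 = np.log(1.0 - w + 1e-300) + sstats.norm.logpdf(x, mu2, max(s2, 1e-6))
        m = np.maximum(l1, l2)
        den = m + np.log(np.exp(l1 - m) + np.exp(l2 - m))
        r1 = np.exp(l1 - den)
        ll = float(np.sum(den))
        n1 = r1.sum()
        n2 = len(x) - n1
        w = n1 / len(x)
        if n1 > 1e-8:
            s1 = math.sqrt(float(np.sum(r1 * (x - mu_pinned) ** 2)) / n1)
        if n2 > 1e-8:
            mu2 = float(np.sum((1 - r1) * x) / n2)
            s2 = math.sqrt(float(np.sum((1 - r1) * (x - mu2) ** 2)) / n2)
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    return MixtureFit(float(w), mu_pinned, s1, mu2, s2, ll)


def subpopulation_test(
    oskar_speeds,
    eb1_speeds,
    n_boot: int = 200,
    seed: int = 0,
):
    """Test for an mRNP subpopulation moving at the plus-end growth speed.

    Fits the mRNP speed distribution with (a) a single Gaussian and (b) a
    two-component mixture whose first component mean is pinned to the mean
    EB1 comet speed.  Reports the pinned component's weight, the
    likelihood-ratio statistic, and a parametric-bootstrap p-value (samples
    drawn from the one-component fit).  A weight near zero and a
    non-significant p indicate no plus-end-tracking subpopulation.
    """
    x = np.asarray(oskar_speeds, dtype=float)
    e = np.asarray(eb1_speeds, dtype=float)
    if len(x) < 50 or len(e) < 50:
        raise AnalyticsError("need >= 50 speeds per population")
    if np.std(x) < 1e-12 * max(1.0, abs(float(np.mean(x)))) or np.std(e) < 1e-12:
        raise AnalyticsError("degenerate (constant) speed sample")
    mu_pin = float(np.mean(e))
    ll1 = _normal_loglik(x)
    fit2 = _fit_pinned_mixture(x, mu_pin)
    lrt = max(2.0 * (fit2.loglik - ll1), 0.0)
    rng = np.random.default_rng(seed)
    mu0, sd0 = float(np.mean(x)), float(np.std(x))
    exceed = 0
    for _ in range(n_boot):
        xb = rng.normal(mu0, sd0, size=len(x))
        llb1 = _normal_loglik(xb)
        llb2 = _fit_pinned_mixture(xb, mu_pin, n_iter=120).loglik
        if max(2.0 * (llb2 - llb1), 0.0) >= lrt:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_boot)
    return {
        "pinned_mean": mu_pin,
        "pinned_weight": fit2.weight_pinned,
        "mixture_fit": fit2,
        "lrt_statistic": lrt,
        "p_value": p,
        "n_boot": n_boot,
    }


# ---------------------------------------------------------------------------
# two-sample comparison with the test-selection rule


def compare_groups(sample_a, sample_b, alpha: float = 0.05) -> dict:
    """Two-sample comparison following the screen-then-test rule.

    Shapiro-Wilk normality screen on each group (at ``alpha``); if both pass,
    a variance screen (Levene) selects the Student or Welch t test; otherwise
    the Wilcoxon rank-sum test is used.  All three test results are reported
    for transparency along with the selected one.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise AnalyticsError("need >= 3 values per group")
    student = sstats.ttest_ind(a, b, equal_var=True)
    welch = sstats.ttest_ind(a, b, equal_var=False)
    ranksum = sstats.ranksums(a, b)
    normal_a = bool(sstats.shapiro(a).pvalue >= alpha) if np.std(a) > 0 else False
    normal_b = bool(sstats.shapiro(b).pvalue >= alpha) if np.std(b) > 0 else False
    if normal_a and normal_b:
        equal_var = bool(sstats.levene(a, b).pvalue >= alpha)
        chosen, name = (student, "student_t") if equal_var else (welch, "welch_t")
    else:
        chosen, name = ranksum, "rank_sum"
    return {
        "test_used": name,
        "statistic": float(chosen.statistic),
        "p": float(chosen.pvalue),
        "normal": (normal_a, normal_b),
        "all_tests": {
            "student_t": (float(student.statistic), float(student.pvalue)),
            "welch_t": (float(welch.statistic), float(welch.pvalue)),
            "rank_sum": (float(ranksum.statistic), float(ranksum.pvalue)),
        },
    }
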