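"""Cortical dwell-time procedure for EB1 comet tracks.

A growing plus end that reaches the cortex is scored from the first frame at
which it comes within 1 um of the cortex outline to its disappearance; that
interval is its cortical dwell time.  Tracks that graze the cortex at a
shallow angle (< 20 deg to the local tangent) are excluded, since for those
the contact time is ill-defined.  Dwell-time distributions per cortical
region are summarised by a maximum-likelihood location-scale t fit, which is
robust to the long right tail of cortical persistence times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sstats

from .geometry import OocyteGeometry, distances_to_cortex, nearest_cortex_info
from .tracks import TrackSet

CONTACT_DIST = 1.0  # um
MIN_APPROACH_ANGLE = 20.0  # deg
HEADING_STEPS = 3  # pre-contact steps used to estimate the approach heading


class DwellError(ValueError):
    pass


@dataclass(frozen=True)
class DwellEvent:
    track_id: str
    contact_time: float
    end_time: float
    dwell: float
    cortex_region: str
    approach_angle: float
    contact_index: int


def approach_angle(heading: np.ndarray, tangent: np.ndarray) -> float:
    """Acute angle (deg) between the approach heading and the cortex tangent."""
    h = heading / np.hypot(*heading)
    t = tangent / np.hypot(*tangent)
    return math.degrees(math.acos(min(abs(float(h @ t)), 1.0)))


def select_cortex_tracks(
    ts: TrackSet,
    geom: OocyteGeometry,
    contact_dist: float = CONTACT_DIST,
    min_angle: float = MIN_APPROACH_ANGLE,
    heading_steps: int = HEADING_STEPS,
) -> list[DwellEvent]:
    """One dwell event per track that touches the cortex steeply enough.

    A track qualifies if some frame lies within ``contact_dist`` of the
    cortex and the heading over its last ``heading_steps`` pre-contact steps
    meets the local cortex tangent at >= ``min_angle`` degrees.  Only the
    first contact of each track is used.  Tracks already in contact at their
    first frame are excluded (no pre-contact heading exists).  Events at
    anterior-labelled cortex are grouped with lateral (both are ncMTOC-bearing
    cortex); the posterior label is kept distinct.
    """
    events = []
    for tr in ts:
        if len(tr) < 2:
            continue
        d = distances_to_cortex(tr.xy, geom)
        hits = np.nonzero(d < contact_dist)[0]
        if len(hits) == 0:
            continue
        i = int(hits[0])
        if i == 0:
            continue
        j = max(0, i - heading_steps)
        heading = tr.xy[i] - tr.xy[j]
        if np.hypot(*heading) == 0.0:
            continue
        _cp, region, tangent = nearest_cortex_info(tr.xy[i], geom)
        ang = approach_angle(heading, tangent)
        if ang < min_angle:
            continue
        if region == "anterior":
            region = "lateral"
        events.append(
            DwellEvent(
                track_id=tr.track_id,
                contact_time=float(tr.t[i]),
                end_time=float(tr.t[-1]),
                dwell=float(tr.t[-1] - tr.t[i]),
                cortex_region=region,
                approach_angle=ang,
                contact_index=i,
            )
        )
    return events


def dwell_time(event: DwellEvent) -> float:
    """Dwell in seconds: track end time minus first-contact time."""
    return event.end_time - event.contact_time


def events_frame(events) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in events])


# ---------------------------------------------------------------------------
# location-scale t fit


@dataclass(frozen=True)
class TLocScaleFit:
    """Maximum-likelihood location-scale Student-t fit of a dwell sample."""

    mu: float
    sigma: float
    nu: float
    loglik: float
    n: int
    mean: float
    median: float
    converged: bool
    nu_at_bound: bool

    def summary(self) -> str:
        lines = [
            "Location-scale t fit",
            f"  n        {self.n}",
            f"  mu       {self.mu:.4g} s",
            f"  sigma    {self.sigma:.4g} s",
            f"  nu       {self.nu:.4g}" + ("  (at bound)" if self.nu_at_bound else ""),
            f"  loglik   {self.loglik:.4g}",
            f"  mean     {self.mean:.4g} s",
            f"  median   {self.median:.4g} s",
        ]
        return "\n".join(lines)


NU_BOUNDS = (0.5, 100.0)


def fit_t_location_scale(dwells, nu_bounds=NU_BOUNDS) -> TLocScaleFit:
    """MLE of (mu, sigma, nu) for a location-scale t distribution.

    nu is bounded to ``nu_bounds`` during optimisation; a fit ending at the
    upper bound indicates an effectively Gaussian sample and is flagged.
    Requires at least 10 samples.
    """
    x = np.asarray(dwells, dtype=float)
    if len(x) < 10:
        raise DwellError("need >= 10 dwell times for a t fit")
    if np.std(x) == 0:
        raise DwellError("degenerate (constant) dwell sample")

    def nll(theta):
        mu, log_s, log_nu = theta
        return -float(np.sum(sstats.t.logpdf(x, np.exp(log_nu), loc=mu, scale=np.exp(log_s))))

    mad = float(np.median(np.abs(x - np.median(x)))) or float(np.std(x))
    x0 = np.array([float(np.median(x)), math.log(1.4826 * mad), math.log(5.0)])
    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=[(None, None), (math.log(1e-6), None), (math.log(nu_bounds[0]), math.log(nu_bounds[1]))],
    )
    if not res.success and not np.isfinite(res.fun):
        raise DwellError(f"t fit did not converge: {res.message}")
    mu, sigma, nu = float(res.x[0]), float(np.exp(res.x[1])), float(np.exp(res.x[2]))
    at_bound = nu >= nu_bounds[1] * (1 - 1e-6) or nu <= nu_bounds[0] * (1 + 1e-6)
    return TLocScaleFit(
        mu=mu,
        sigma=sigma,
        nu=nu,
        loglik=-float(res.fun),
        n=len(x),
        mean=float(np.mean(x)),
        median=float(np.median(x)),
        converged=bool(res.success),
        nu_at_bound=at_bound,
    )


def compare_regions(posterior_events, lateral_events) -> dict:
    """Posterior-vs-lateral dwell comparison: means, maxima, rank-sum p, fits."""
    if len(posterior_events) < 3 or len(lateral_events) < 3:
        raise DwellError("need >= 3 dwell events per region")
    post = np.array([dwell_time(e) for e in posterior_events])
    lat = np.array([dwell_time(e) for e in lateral_events])
    rs = sstats.ranksums(post, lat)
    fits = {}
    for name, x in (("posterior", post), ("lateral", lat)):
        try:
            fits[name] = fit_t_location_scale(x)
        except DwellError:
            fits[name] = None
    return {
        "mean_posterior": float(np.mean(post)),
        "mean_lateral": float(np.mean(lat)),
        "max_posterior": float(np.max(post)),
        "max_lateral": float(np.max(lat)),
        "n_posterior": len(post),
        "n_lateral": len(lat),
        "rank_sum_statistic": float(rs.statistic),
        "rank_sum_p": float(rs.pvalue),
        "fits": fits,
    }


# ---------------------------------------------------------------------------
# kymograph rendering (visual QC)


def render_kymograph(
    ts: TrackSet,
    cortex_segment: np.ndarray,
    duration: float,
    bin_um: float = 1.0,
    frame_dt: float = 1.7,
    capture_dist: float = 1.0,
) -> np.ndarray:
    """Occupancy matrix (arc-position bins x frames) along a cortex polyline.

    Every track point within ``capture_dist`` of the polyline is projected to
    its arc-length coordinate and accumulated; a comet parked at the cortex
    therefore draws a vertical line, one moving along it a diagonal.
    """
    seg = np.asarray(cortex_segment, dtype=float)
    if seg.ndim != 2 or len(seg) < 2:
        raise DwellError("cortex_segment must be a polyline of >= 2 points")
    edges = np.diff(seg, axis=0)
    edge_len = np.hypot(edges[:, 0], edges[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(edge_len)])
    total = cum[-1]
    n_pos = max(int(math.ceil(total / bin_um)), 1)
    n_frames = int(round(duration / frame_dt)) + 1
    kymo = np.zeros((n_pos, n_frames))
    for tr in ts:
        frames = np.round(tr.t / frame_dt).astype(int)
        for (x, y), f in zip(tr.xy, frames):
            if f < 0 or f >= n_frames:
                continue
            p = np.array([x, y])
            best_d, best_s = np.inf, 0.0
            for k in range(len(edges)):
                e2 = edge_len[k] ** 2
                t = np.clip(((p - seg[k]) @ edges[k]) / e2, 0.0, 1.0) if e2 else 0.0
                proj = seg[k] + t * edges[k]
                dd = float(np.hypot(*(p - proj)))
                if dd < best_d:
                    best_d, best_s = dd, cum[k] + t * edge_len[k]
            if best_d <= capture_dist:
                kymo[min(int(best_s / bin_um), n_pos - 1), f] += 1.0
    return kymo
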