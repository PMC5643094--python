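"""Synthetic EB1-comet and oskar-mRNP track generators.

These generators provide trajectories with the statistical structure that the
analytics assume, so every downstream stage is testable without imaging data:

* EB1 comets nucleate on the anterior/lateral cortex, grow along a nearly
  straight heading with a position-dependent speed (slower near the posterior
  pole), disappear by catastrophe (position-dependent hazard) or by
  age-proportional out-of-plane censoring, and pause on reaching the cortex,
  where they persist under a region-dependent cortical catastrophe hazard.
* oskar mRNPs are mostly immobile; a configurable mobile fraction performs a
  single run whose direction is posterior-biased with a probability that
  depends on the particle's distance band from the posterior pole.

Time is discretised to the frame interval, so observed lifetimes are
geometric rather than exponential; :func:`hazard_for_mean_lifespan` and
:func:`pause_hazard_for_mean_dwell` invert the exact geometric mean so a
generator can be pointed at a target *observed* mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    OocyteGeometry,
    distance_to_posterior_pole,
    distances_to_cortex,
)
from .tracks import Track, TrackSet

DEFAULT_POSTERIOR_BIAS = {0: 0.71, 1: 0.66, 2: 0.63}  # per 10-um band from the pole


class ParamError(ValueError):
    pass


# ---------------------------------------------------------------------------
# discrete-time survival helpers


def expected_observed_lifespan(hazard: float, dt: float, min_points: int = 2) -> float:
    """Mean observed lifespan (n_frames - 1) * dt for a constant hazard.

    A comet alive at frame 0 survives each subsequent frame with probability
    q = exp(-hazard * dt); the observed lifespan is dt times a geometric count
    of survived frames.  Conditioning on at least ``min_points`` recorded
    frames (the analysis discards shorter tracks) shifts the mean by
    memorylessness.
    """
    q = math.exp(-hazard * dt)
    return dt * ((min_points - 1) + q / (1.0 - q))


def hazard_for_mean_lifespan(mean_lifespan: float, dt: float, min_points: int = 2) -> float:
    """Hazard (1/s) whose *observed* mean lifespan equals ``mean_lifespan``.

    Inverts :func:`expected_observed_lifespan` exactly.
    """
    r = mean_lifespan / dt - (min_points - 1)
    if r <= 0:
        raise ParamError("target mean lifespan too short for the frame interval")
    q = r / (1.0 + r)
    return -math.log(q) / dt


def expected_observed_dwell(hazard: float, dt: float) -> float:
    """Mean observed cortical dwell for pause hazard ``hazard``.

    Dwell is measured from the contact frame to the last recorded frame, so it
    is dt times the number of frames survived after contact (possibly zero).
    """
    q = math.exp(-hazard * dt)
    return dt * q / (1.0 - q)


def pause_hazard_for_mean_dwell(mean_dwell: float, dt: float) -> float:
    """Cortical pause hazard whose observed mean dwell equals ``mean_dwell``."""
    r = mean_dwell / dt
    if r <= 0:
        raise ParamError("target mean dwell must be positive")
    q = r / (1.0 + r)
    return -math.log(q) / dt


def observed_lifespan_sd(hazard: float, dt: float) -> float:
    """Standard deviation of the observed (geometric) lifespan."""
    q = math.exp(-hazard * dt)
    return dt * math.sqrt(q) / (1.0 - q)


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class EB1SimParams:
    """Comet generator settings.

    Speeds ramp logistically from ``v_near`` (within ``d_switch`` of the
    posterior pole) to ``v_far`` beyond it; catastrophe hazard ramps the same
    way between ``hazard_near`` and ``hazard_far``.  ``censor_slope`` is the
    age-proportional out-of-plane loss hazard c(t) = censor_slope * t applied
    while the comet grows.  ``cortex_pause`` maps cortex region to the
    catastrophe hazard of a comet paused at that region's cortex.
    """

    n_comets: int = 500
    frame_dt: float = 1.7
    v_far: float = 0.24
    v_near: float = 0.18
    v_sd: float = 0.05
    d_switch: float = 15.0
    ramp_width: float = 0.5
    hazard_far: float = 0.09
    hazard_near: float = 0.09
    censor_slope: float = 0.0
    angular_noise_sd: float = 2.0
    cortex_pause: dict = field(
        default_factory=lambda: {"posterior": 1.0 / 15.0, "lateral": 1.0 / 8.0}
    )
    detection_offset: float = 2.0
    contact_dist: float = 1.0
    max_frames: int = 400
    seed: int = 0

    def validate(self) -> None:
        if self.n_comets < 0 or self.frame_dt <= 0:
            raise ParamError("n_comets must be >= 0 and frame_dt > 0")
        if min(self.v_far, self.v_near) <= 0 or self.v_sd < 0:
            raise ParamError("speeds must be positive, v_sd non-negative")
        if min(self.hazard_far, self.hazard_near) < 0 or self.censor_slope < 0:
            raise ParamError("hazards must be non-negative")


@dataclass(frozen=True)
class OskarSimParams:
    """mRNP generator settings.

    ``bias_by_band`` maps the 10-um distance band of the particle's start
    point (band 0 = 0-10 um from the pole) to its probability of running
    toward the posterior; bands beyond the largest key reuse the last value.
    Run lengths are drawn from ``run_min + Exp(run_length_mean - run_min)``:
    manual tracking only records runs above a detection length, so every
    mobile run exceeds ``run_min``.
    """

    n_particles: int = 500
    frame_dt: float = 0.5
    speed_mean: float = 0.36
    speed_sd: float = 0.1
    bias_by_band: dict = field(default_factory=lambda: dict(DEFAULT_POSTERIOR_BIAS))
    mobile_fraction: float = 0.12
    run_length_mean: float = 3.0
    run_min: float = 1.5
    band_width: float = 10.0
    static_frames: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_particles < 0 or self.frame_dt <= 0:
            raise ParamError("n_particles must be >= 0 and frame_dt > 0")
        if self.speed_mean <= 0 or self.speed_sd < 0:
            raise ParamError("speed_mean must be positive")
        probs = [self.mobile_fraction, *self.bias_by_band.values()]
        if any(p < 0 or p > 1 for p in probs):
            raise ParamError("probabilities must lie in [0, 1]")
        if self.run_length_mean <= self.run_min or self.run_min <= 0:
            raise ParamError("need 0 < run_min < run_length_mean")


# ---------------------------------------------------------------------------
# cortex sampling helpers


def _cortex_arcs(geom: OocyteGeometry, regions=("anterior", "lateral")):
    """Edges (a, b, tangent, inward normal, length) on the given regions."""
    pts = geom.cortex
    nxt = np.roll(pts, -1, axis=0)
    keep = np.array([lab in regions for lab in geom.region_labels])
    a, b = pts[keep], nxt[keep]
    seg = b - a
    lengths = np.hypot(seg[:, 0], seg[:, 1])
    tangent = seg / lengths[:, None]
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
    # orient normals into the polygon
    mid = (a + b) / 2.0
    probe = mid + normal * 1e-3
    inside = geom.contains(probe)
    normal[~inside] *= -1.0
    return a, b, tangent, normal, lengths


def sample_cortex_points(geom: OocyteGeometry, n: int, rng, regions=("anterior", "lateral")):
    """Uniform-by-arc-length cortex points with inward normals."""
    a, b, tangent, normal, lengths = _cortex_arcs(geom, regions)
    if len(a) == 0:
        raise ParamError(f"no cortex edges labelled {regions}")
    probs = lengths / lengths.sum()
    idx = rng.choice(len(a), size=n, p=probs)
    u = rng.random(n)
    pts = a[idx] + (b[idx] - a[idx]) * u[:, None]
    return pts, tangent[idx], normal[idx]


def _rotate(v: np.ndarray, angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _first_shell_crossing(p0, p1, geom, contact_dist, iters: int = 40):
    """Point on segment p0->p1 where the cortex distance first drops to
    ``contact_dist`` (bisection; p0 is outside the shell, p1 inside)."""
    lo, hi = 0.0, 1.0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        q = p0 + (p1 - p0) * mid
        if distances_to_cortex(q, geom)[0] < contact_dist:
            hi = mid
        else:
            lo = mid
    return p0 + (p1 - p0) * hi


# ---------------------------------------------------------------------------
# EB1 comets


def _speed_at(d: float, p: EB1SimParams) -> float:
    ramp = 1.0 / (1.0 + math.exp(-(d - p.d_switch) / p.ramp_width))
    return p.v_near + (p.v_far - p.v_near) * ramp


def _hazard_at(d: float, p: EB1SimParams) -> float:
    ramp = 1.0 / (1.0 + math.exp(-(d - p.d_switch) / p.ramp_width))
    return p.hazard_near + (p.hazard_far - p.hazard_near) * ramp


def generate_eb1_tracks(params: EB1SimParams, geom: OocyteGeometry) -> TrackSet:
    """Simulate EB1 comet tracks on the oocyte geometry.

    Each comet starts ``detection_offset`` um inside the cortex along its
    heading (a growing end is only detected once clear of the nucleation
    zone), advances speed*dt per frame along a persistent heading with small
    angular noise, and terminates by catastrophe, censoring, or cortical
    pause followed by cortical catastrophe.  All points stay inside the
    polygon: a step that would enter the 1-um contact shell stops at the
    shell, where the comet pauses.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    anchors, _tangents, normals = sample_cortex_points(geom, params.n_comets, rng)
    tracks = []
    for i in range(params.n_comets):
        heading = _rotate(normals[i], rng.uniform(-math.pi / 2, math.pi / 2))
        start = anchors[i] + heading * params.detection_offset
        if not geom.contains(start)[0] or distances_to_cortex(start, geom)[0] < params.contact_dist:
            # shallow heading: nudge the detection point along the normal
            start = anchors[i] + normals[i] * params.detection_offset
        pts = [start]
        paused = False
        pause_hazard = 0.0
        pos = start
        for k in range(1, params.max_frames):
            age = (k - 1) * params.frame_dt
            if paused:
                if rng.random() < 1.0 - math.exp(-pause_hazard * params.frame_dt):
                    break
                pts.append(pos)
                continue
            d_pole = distance_to_posterior_pole(pos, geom)
            haz = _hazard_at(d_pole, params)
            p_die = 1.0 - math.exp(-(haz + params.censor_slope * age) * params.frame_dt)
            if rng.random() < p_die:
                break
            if params.angular_noise_sd > 0:
                heading = _rotate(heading, math.radians(rng.normal(0.0, params.angular_noise_sd)))
            speed = max(rng.normal(_speed_at(d_pole, params), params.v_sd), 0.0)
            cand = pos + heading * speed * params.frame_dt
            if (not geom.contains(cand)[0]) or distances_to_cortex(cand, geom)[0] < params.contact_dist:
                pos = _first_shell_crossing(pos, cand, geom, params.contact_dist - 1e-9)
                paused = True
                from .geometry import nearest_cortex_info

                _cp, region, _tan = nearest_cortex_info(pos, geom)
                if region == "anterior":
                    region = "lateral"
                pause_hazard = params.cortex_pause.get(region, 0.0)
            else:
                pos = cand
            pts.append(pos)
        xy = np.asarray(pts)
        nf = len(xy)
        tracks.append(
            Track(
                track_id=f"eb1_{i:05d}",
                kind="eb1",
                frame=np.arange(nf),
                t=np.arange(nf) * params.frame_dt,
                xy=xy,
            )
        )
    return TrackSet.from_tracks(tracks)


# ---------------------------------------------------------------------------
# oskar mRNPs


def _uniform_interior_points(geom: OocyteGeometry, n: int, rng, margin: float = 0.8):
    """Rejection-sample points uniformly inside the cortex polygon."""
    minx, miny, maxx, maxy = geom.polygon.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(2 * (n - got), 64)
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        ok = geom.contains(cand) & (distances_to_cortex(cand, geom) > margin)
        take = cand[ok][: n - got]
        out[got : got + len(take)] = take
        got += len(take)
    return out


def generate_oskar_tracks(params: OskarSimParams, geom: OocyteGeometry) -> TrackSet:
    """Simulate oskar-mRNP tracks.

    A fraction ``mobile_fraction`` of particles performs one run; the run is
    posterior-directed (net angle uniform within +/-90 degrees of the pole
    direction) with the band-dependent probability, otherwise directed into
    the opposite half-plane.  Per-frame speeds are Normal(speed_mean,
    speed_sd) truncated at zero.  Immobile particles sit still for
    ``static_frames`` frames.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    starts = _uniform_interior_points(geom, params.n_particles, rng)
    max_band = max(params.bias_by_band) if params.bias_by_band else 0
    tracks = []
    for i in range(params.n_particles):
        start = starts[i]
        mobile = rng.random() < params.mobile_fraction
        if not mobile:
            nf = params.static_frames
            xy = np.tile(start, (nf, 1))
        else:
            d_pole = distance_to_posterior_pole(start, geom)
            band = min(int(d_pole // params.band_width), max_band)
            p_post = params.bias_by_band.get(band, 0.5)
            to_pole = geom.posterior_pole - start
            to_pole = to_pole / np.hypot(*to_pole)
            if rng.random() < p_post:
                off = rng.uniform(-math.pi / 2 * 0.999, math.pi / 2 * 0.999)
            else:
                off = rng.uniform(math.pi / 2 * 1.001, math.pi * 1.5 * 0.999)
            heading = _rotate(to_pole, off)
            run_len = params.run_min + rng.exponential(params.run_length_mean - params.run_min)
            pts = [start]
            pos = start
            travelled = 0.0
            while travelled < run_len:
                speed = max(rng.normal(params.speed_mean, params.speed_sd), 0.0)
                step = speed * params.frame_dt
                cand = pos + heading * step
                if (not geom.contains(cand)[0]) or distances_to_cortex(cand, geom)[0] < 0.2:
                    break
                pos = cand
                travelled += step
                pts.append(pos)
            xy = np.asarray(pts)
        nf = len(xy)
        tracks.append(
            Track(
                track_id=f"osk_{i:05d}",
                kind="oskar",
                frame=np.arange(nf),
                t=np.arange(nf) * params.frame_dt,
                xy=xy,
            )
        )
    return TrackSet.from_tracks(tracks)
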