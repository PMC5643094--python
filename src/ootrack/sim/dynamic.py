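"""Dynamic microtubule model with dynactin anti-catastrophe feedback.

Microtubules nucleate on the anterior/lateral cortex and grow straight into
the interior at v_g; they undergo catastrophe with hazard
``k_cat0 / (1 + alpha * c(x))`` evaluated at the plus end, where c(x) is a
diffusing, decaying dynactin concentration field fed by kinesin-driven
walkers that ride the microtubules plus-end-ward and deposit where they are.
A plus end reaching the cortex pauses there; its catastrophe hazard becomes
``cortex_pause / (1 + alpha * c(x))``.  Growth speed is likewise slowed to
``v_g / (1 + alpha_v * c(x))``, which reproduces the wild-type slow-down of
plus ends approaching the posterior; setting alpha = alpha_v = 0 gives the
uncoupled ("mutant") control with uniform growth speed and no protection.

The simulator emits plus-end trajectories sampled at the imaging frame
interval ("comet-equivalent" tracks, growth phase only, as an EB1 comet
vanishes when growth stops) so the whole track-analytics pipeline can run on
simulated data, plus per-contact cortical dwell records and a posterior
dynactin time series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ..geometry import OocyteGeometry, exit_distance, nearest_cortex_info
from ..synthetic import sample_cortex_points
from ..tracks import Track, TrackSet
from .common import ConfigError, SimResult, density_from_positions


@dataclass(frozen=True)
class DynamicMTConfig:
    """Parameters of the dynamic feedback model.

    Rates in 1/s, speeds um/s, lengths um.  ``r_nuc`` is the nucleation rate
    per um of anterior/lateral cortex; ``alpha`` couples dynactin to
    catastrophe protection and ``alpha_v`` to growth slow-down; the dynactin
    field lives on a square grid of spacing ``grid_dx`` with explicit-Euler
    diffusion and first-order decay.  Tracks and dwell events recorded before
    ``burn_in`` seconds are discarded so statistics reflect the (quasi-)
    steady state.
    """

    r_nuc: float = 0.015
    v_g: float = 0.23
    v_s: float = 0.5
    k_cat0: float = 0.015
    alpha: float = 1.0
    alpha_v: float = 0.6
    cortex_pause: float = 0.125
    deposition_rate: float = 0.1
    decay: float = 0.02
    D_c: float = 0.5
    grid_dx: float = 1.0
    n_walkers: int = 150
    v_walk: float = 0.47
    walker_capture: float = 3.0
    direction_flip_prob: float = 0.25
    T_total: float = 1500.0
    dt: float = 0.425
    frame_dt: float = 1.7
    burn_in: float = 500.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("r_nuc", "k_cat0", "alpha", "alpha_v", "cortex_pause",
                     "deposition_rate", "decay", "D_c"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.v_g <= 0 or self.v_s <= 0 or self.v_walk <= 0:
            raise ConfigError("v_g, v_s and v_walk must be positive")
        if self.dt <= 0 or self.T_total < self.dt:
            raise ConfigError("need dt > 0 and T_total >= dt")
        if self.v_g * self.dt > self.grid_dx:
            raise ConfigError("unstable dt: growth step exceeds a grid cell")
        if self.D_c * self.dt / self.grid_dx**2 > 0.25:
            raise ConfigError("unstable dt for dynactin diffusion (explicit Euler)")


GROW, PAUSE, SHRINK, DEAD = 0, 1, 2, 3


class _Field:
    """Dynactin concentration on a masked grid with no-flux boundaries."""

    def __init__(self, geom: OocyteGeometry, dx: float):
        minx, miny, maxx, maxy = geom.polygon.bounds
        self.x0, self.y0, self.dx = minx - dx, miny - dx, dx
        nx = int(math.ceil((maxx - self.x0) / dx)) + 2
        ny = int(math.ceil((maxy - self.y0) / dx)) + 2
        cx = self.x0 + (np.arange(nx) + 0.5) * dx
        cy = self.y0 + (np.arange(ny) + 0.5) * dx
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        centers = np.column_stack([gx.ravel(), gy.ravel()])
        self.inside = geom.contains(centers).reshape(nx, ny)
        self.c = np.zeros((nx, ny))
        self._nb = sum(
            np.roll(self.inside, sh, axis=ax).astype(float)
            for ax, sh in ((0, 1), (0, -1), (1, 1), (1, -1))
        )

    def cell(self, pts: np.ndarray):
        pts = np.atleast_2d(pts)
        ix = np.clip(((pts[:, 0] - self.x0) / self.dx).astype(int), 0, self.c.shape[0] - 1)
        iy = np.clip(((pts[:, 1] - self.y0) / self.dx).astype(int), 0, self.c.shape[1] - 1)
        return ix, iy

    def value_at(self, pts: np.ndarray) -> np.ndarray:
        ix, iy = self.cell(pts)
        return self.c[ix, iy]

    def step(self, dt: float, D: float, decay: float) -> None:
        ci = np.where(self.inside, self.c, 0.0)
        lap = (
            np.roll(ci, 1, axis=0)
            + np.roll(ci, -1, axis=0)
            + np.roll(ci, 1, axis=1)
            + np.roll(ci, -1, axis=1)
            - self._nb * ci
        )
        self.c = ci + dt * (D / self.dx**2) * lap - dt * decay * ci
        np.clip(self.c, 0.0, None, out=self.c)
        self.c[~self.inside] = 0.0


def run_dynamic_feedback(config: DynamicMTConfig, geom: OocyteGeometry, seed=None) -> SimResult:
    """Run the feedback model; see the module docstring for the dynamics."""
    config.validate()
    base_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    rng_mt, rng_walk = (np.random.default_rng(s) for s in ss.spawn(2))

    field = _Field(geom, config.grid_dx)
    # anterior/lateral cortex length for the nucleation rate
    pts = geom.cortex
    nxt = np.roll(pts, -1, axis=0)
    keep = np.array([lab in ("anterior", "lateral") for lab in geom.region_labels])
    arc_len = float(np.hypot(*(nxt - pts)[keep].T).sum())
    lam = config.r_nuc * arc_len * config.dt

    # growable struct-of-arrays microtubule store
    cap = 256
    anchor = np.zeros((cap, 2))
    dirn = np.zeros((cap, 2))
    length = np.zeros(cap)
    exit_d = np.zeros(cap)
    state = np.full(cap, DEAD, dtype=np.int8)
    pause_t0 = np.zeros(cap)
    post_contact = np.zeros(cap, dtype=bool)
    n_mt = 0
    track_pts: list[list] = []
    dwell_rows = []
    transit_cat_lengths: list[float] = []  # MT length at in-transit catastrophe

    w_mt = np.full(config.n_walkers, -1, dtype=int)
    w_s = np.zeros(config.n_walkers)
    w_pos = None  # initialised lazily from the walker RNG stream

    rec_every = max(int(round(config.frame_dt / config.dt)), 1)
    n_steps = int(round(config.T_total / config.dt))
    pole = geom.posterior_pole
    post_cells = None
    series = []

    for step in range(n_steps):
        t = step * config.dt

        # --- nucleation
        n_new = rng_mt.poisson(lam)
        if n_new > 0:
            if n_mt + n_new > cap:
                new_cap = max(cap * 2, n_mt + n_new)
                anchor = np.vstack([anchor, np.zeros((new_cap - cap, 2))])
                dirn = np.vstack([dirn, np.zeros((new_cap - cap, 2))])
                length = np.concatenate([length, np.zeros(new_cap - cap)])
                exit_d = np.concatenate([exit_d, np.zeros(new_cap - cap)])
                state = np.concatenate([state, np.full(new_cap - cap, DEAD, dtype=np.int8)])
                pause_t0 = np.concatenate([pause_t0, np.zeros(new_cap - cap)])
                post_contact = np.concatenate([post_contact, np.zeros(new_cap - cap, dtype=bool)])
                cap = new_cap
            anchors, _tg, normals = sample_cortex_points(geom, n_new, rng_mt)
            angles = rng_mt.uniform(-math.pi / 2, math.pi / 2, n_new)
            cc, sss = np.cos(angles), np.sin(angles)
            dirs = np.column_stack(
                [cc * normals[:, 0] - sss * normals[:, 1], sss * normals[:, 0] + cc * normals[:, 1]]
            )
            # weak posterior orientation bias of the growing plus ends:
            # anterograde-pointing candidates are mirrored across the AP
            # normal with a small probability (kept only if still inward)
            if config.direction_flip_prob > 0:
                ap = geom.ap_axis
                retro = dirs @ ap < 0
                flip = retro & (rng_mt.random(n_new) < config.direction_flip_prob)
                if flip.any():
                    mirrored = dirs[flip] - 2.0 * np.outer(dirs[flip] @ ap, ap)
                    ok = np.einsum("ij,ij->i", mirrored, normals[flip]) > 0
                    rows = np.nonzero(flip)[0][ok]
                    dirs[rows] = mirrored[ok]
            for j in range(n_new):
                i = n_mt
                anchor[i] = anchors[j]
                dirn[i] = dirs[j]
                length[i] = 0.0
                exit_d[i] = exit_distance(anchors[j], dirs[j], geom)
                hit = anchors[j] + dirs[j] * exit_d[i]
                _cp, region, _tan = nearest_cortex_info(hit, geom)
                post_contact[i] = region == "posterior"
                state[i] = GROW
                track_pts.append([])
                n_mt += 1

        live = state[:n_mt] < SHRINK  # growing or paused
        tips = anchor[:n_mt] + dirn[:n_mt] * length[:n_mt, None]
        c_tip = field.value_at(tips) if n_mt else np.zeros(0)

        # --- catastrophe draws (growing and paused)
        if n_mt:
            grow_mask = state[:n_mt] == GROW
            pause_mask = state[:n_mt] == PAUSE
            k = np.zeros(n_mt)
            k[grow_mask] = config.k_cat0 / (1.0 + config.alpha * c_tip[grow_mask])
            k[pause_mask] = config.cortex_pause / (1.0 + config.alpha * c_tip[pause_mask])
            u = rng_mt.random(n_mt)
            dies = live & (u < 1.0 - np.exp(-k * config.dt))
            newly_dead = np.nonzero(dies)[0]
            for i in newly_dead:
                if state[i] == PAUSE and t >= config.burn_in:
                    dwell_rows.append(
                        {
                            "region": "posterior" if post_contact[i] else "lateral",
                            "dwell": t - pause_t0[i],
                            "t_contact": pause_t0[i],
                        }
                    )
                elif state[i] == GROW and t >= config.burn_in:
                    transit_cat_lengths.append(float(length[i]))
            state[newly_dead] = SHRINK

            # --- growth / pause transition
            grow_mask = state[:n_mt] == GROW
            if grow_mask.any():
                gi = np.nonzero(grow_mask)[0]
                v_eff = config.v_g / (1.0 + config.alpha_v * c_tip[gi])
                length[gi] += v_eff * config.dt
                reach = length[gi] >= exit_d[gi]
                ri = gi[reach]
                length[ri] = exit_d[ri]
                state[ri] = PAUSE
                pause_t0[ri] = t

            # --- shrinkage
            sh = np.nonzero(state[:n_mt] == SHRINK)[0]
            length[sh] -= config.v_s * config.dt
            dead = sh[length[sh] <= 0.0]
            length[dead] = 0.0
            state[dead] = DEAD

        # --- dynactin walkers: ride plus-end-ward, fall off shrinking MTs,
        # rebind the nearest living MT at the projected position (net motion
        # across the MT network follows the weak posterior orientation bias)
        if config.n_walkers:
            if w_pos is None:
                from ..synthetic import _uniform_interior_points

                w_pos = _uniform_interior_points(geom, config.n_walkers, rng_walk, margin=0.5)
            living = np.nonzero(state[:n_mt] < SHRINK)[0]
            lost = (w_mt >= 0) & (state[np.clip(w_mt, 0, max(cap - 1, 0))] >= SHRINK)
            w_mt[lost] = -1
            unassigned = np.nonzero(w_mt < 0)[0]
            if len(unassigned) and len(living):
                A, U, L = anchor[living], dirn[living], length[living]
                P = w_pos[unassigned]
                tproj = np.clip(
                    np.einsum("ijk,jk->ij", P[:, None, :] - A[None, :, :], U), 0.0, L[None, :]
                )
                proj = A[None, :, :] + tproj[..., None] * U[None, :, :]
                d2 = np.sum((P[:, None, :] - proj) ** 2, axis=2)
                nearest = np.argmin(d2, axis=1)
                rows = np.arange(len(unassigned))
                in_reach = d2[rows, nearest] <= config.walker_capture**2
                w_mt[unassigned[in_reach]] = living[nearest[in_reach]]
                w_s[unassigned[in_reach]] = tproj[rows, nearest][in_reach]
                # out-of-reach walkers wait in place until an MT grows past
            riding = np.nonzero(w_mt >= 0)[0]
            if len(riding):
                w_s[riding] = np.minimum(
                    w_s[riding] + config.v_walk * config.dt, length[w_mt[riding]]
                )
                w_pos[riding] = anchor[w_mt[riding]] + dirn[w_mt[riding]] * w_s[riding][:, None]
            ix, iy = field.cell(w_pos)
            np.add.at(field.c, (ix, iy), config.deposition_rate * config.dt)

        field.step(config.dt, config.D_c, config.decay)

        # --- frame-rate recording
        if step % rec_every == 0 and n_mt:
            frame = step // rec_every
            gi = np.nonzero(state[:n_mt] == GROW)[0]
            tps = anchor[gi] + dirn[gi] * length[gi, None]
            for i, p in zip(gi, tps):
                track_pts[i].append((frame, p[0], p[1]))
            if post_cells is None:
                gx, gy = np.meshgrid(
                    field.x0 + (np.arange(field.c.shape[0]) + 0.5) * field.dx,
                    field.y0 + (np.arange(field.c.shape[1]) + 0.5) * field.dx,
                    indexing="ij",
                )
                dpole = np.hypot(gx - pole[0], gy - pole[1])
                post_cells = field.inside & (dpole <= 10.0)
            wx = float(np.mean(w_pos @ geom.ap_axis)) if w_pos is not None else float("nan")
            series.append(
                {
                    "t": frame * config.frame_dt,
                    "posterior_dynactin": float(field.c[post_cells].mean()),
                    "mean_dynactin": float(field.c[field.inside].mean()),
                    "n_mts": int((state[:n_mt] < SHRINK).sum()),
                    "walker_mean_ap": wx,
                }
            )

    # --- assemble comet-equivalent tracks (growth phase, post burn-in)
    tracks = []
    for i, pts_i in enumerate(track_pts):
        if len(pts_i) < 2:
            continue
        arr = np.asarray(pts_i)
        if arr[0, 0] * config.frame_dt < config.burn_in:
            continue
        # keep the contiguous leading run of frames (growth is contiguous)
        frames = arr[:, 0].astype(int)
        tracks.append(
            Track(
                track_id=f"sim_{i:06d}",
                kind="eb1",
                frame=frames,
                t=frames * config.frame_dt,
                xy=arr[:, 1:3],
            )
        )
    ts = TrackSet.from_tracks(tracks)
    live_tips = anchor[:n_mt][state[:n_mt] < SHRINK] + (
        dirn[:n_mt][state[:n_mt] < SHRINK]
        * length[:n_mt][state[:n_mt] < SHRINK][:, None]
    )
    density = density_from_positions(live_tips if len(live_tips) else np.zeros((0, 2)), geom)
    return SimResult(
        positions=live_tips,
        density=density,
        anchored=np.zeros(0, dtype=bool),
        comet_tracks=ts,
        dwells=pd.DataFrame(dwell_rows, columns=["region", "dwell", "t_contact"]),
        dynactin_series=pd.DataFrame(series),
        meta={
            "model": "dynamic_feedback",
            "alpha": config.alpha,
            "alpha_v": config.alpha_v,
            "n_mts_total": n_mt,
            "n_tracks": len(ts),
            "catastrophe_lengths": np.asarray(transit_cat_lengths),
        },
    )


def mutant_scenario(config: DynamicMTConfig, geom: OocyteGeometry, seed=None) -> dict:
    """Paired wild-type vs uncoupled-mutant runs on shared seeds.

    The mutant lacks dynactin coupling entirely (alpha = 0, uniform growth
    speed via alpha_v = 0), emulating loss of the Arp1-dependent plus-end
    protection; both runs use the same random streams so contrasts are
    paired.
    """
    wt = run_dynamic_feedback(config, geom, seed=seed)
    mut_cfg = replace(config, alpha=0.0, alpha_v=0.0)
    mut = run_dynamic_feedback(mut_cfg, geom, seed=seed)
    return {"wild_type": wt, "mutant": mut}
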