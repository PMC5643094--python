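"""Static-rod transport model.

Microtubules are fixed rods anchored on the anterior/lateral cortex with the
plus end pointing into the interior; lengths are exponential with mean
``epsilon * L_AP`` (the mean target length, a fraction of the
anterior-posterior extent), truncated where the rod would exit the cortex.
Cargo alternates free diffusion (optionally advected by a prescribed
circulation) with plus-end-directed walking on the nearest rod within a
capture radius; cargo that reaches a plus end at the posterior cortex is
anchored there.  Reducing epsilon shortens the rods, and the final cargo
distribution shifts from a tight posterior cortical crescent to a diffuse
posterior cloud.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..geometry import OocyteGeometry, exit_distance
from ..synthetic import _uniform_interior_points, sample_cortex_points
from .common import ConfigError, SimResult, density_from_positions, distances_to_posterior_arc


@dataclass(frozen=True)
class StaticRodConfig:
    """Parameters of the static-rod cargo transport model.

    epsilon is dimensionless (fraction of L_AP); speeds in um/s, D_cyto in
    um^2/s, rates in 1/s, times in s, distances in um.  ``tip_behavior``
    selects what a walking cargo does at an interior plus end: ``run_off``
    (detach immediately) or ``tethered`` (stay at the tip until it unbinds
    stochastically).
    """

    epsilon: float = 0.5
    n_mts: int = 250
    n_cargo: int = 500
    v_walk: float = 0.47
    D_cyto: float = 0.01
    k_unbind: float = 0.01
    flow_u: float = 0.0
    T_total: float = 10800.0
    dt: float = 1.0
    capture_radius: float = 0.5
    anchor_dist: float = 1.5
    tip_behavior: str = "run_off"
    density_cell: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.epsilon <= 1.0):
            raise ConfigError("epsilon must be in (0, 1]")
        if self.dt <= 0 or self.T_total < self.dt:
            raise ConfigError("need dt > 0 and T_total >= dt")
        if self.v_walk * self.dt > self.capture_radius:
            raise ConfigError("dt too large: walker step exceeds the capture radius")
        if self.tip_behavior not in ("run_off", "tethered"):
            raise ConfigError("tip_behavior must be 'run_off' or 'tethered'")
        if min(self.n_mts, self.n_cargo) <= 0:
            raise ConfigError("n_mts and n_cargo must be positive")


@dataclass(frozen=True)
class MTRods:
    """Struct-of-arrays rod set: anchor + unit direction + truncated length."""

    anchor: np.ndarray
    direction: np.ndarray
    length: np.ndarray
    raw_length: np.ndarray

    def __len__(self) -> int:
        return len(self.length)

    @property
    def tip(self) -> np.ndarray:
        return self.anchor + self.direction * self.length[:, None]


def sample_static_rods(config: StaticRodConfig, geom: OocyteGeometry, seed=None) -> MTRods:
    """Sample rods: anchors uniform on the anterior/lateral arc, directions
    uniform over the interior half-plane, lengths Exp(epsilon * L_AP)
    truncated at the cortex."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    anchors, _t, normals = sample_cortex_points(geom, config.n_mts, rng)
    angles = rng.uniform(-math.pi / 2, math.pi / 2, config.n_mts)
    c, s = np.cos(angles), np.sin(angles)
    dirs = np.column_stack(
        [c * normals[:, 0] - s * normals[:, 1], s * normals[:, 0] + c * normals[:, 1]]
    )
    raw = rng.exponential(config.epsilon * geom.L_AP, config.n_mts)
    exit_d = np.array(
        [exit_distance(anchors[i], dirs[i], geom) for i in range(config.n_mts)]
    )
    length = np.minimum(raw, np.maximum(exit_d - 1e-9, 0.0))
    return MTRods(anchor=anchors, direction=dirs, length=length, raw_length=raw)


def _flow_velocity(pos: np.ndarray, geom: OocyteGeometry, u: float) -> np.ndarray:
    """Prescribed two-vortex circulation (stand-in for cytoplasmic streaming)."""
    minx, miny, maxx, maxy = geom.polygon.bounds
    xt = (pos[:, 0] - minx) / (maxx - minx)
    yt = (pos[:, 1] - miny) / (maxy - miny)
    # stream function sin(pi x) sin(2 pi y): two counter-rotating vortices
    vx = np.sin(np.pi * xt) * np.cos(2 * np.pi * yt)
    vy = -0.5 * np.cos(np.pi * xt) * np.sin(2 * np.pi * yt)
    return u * np.column_stack([vx, vy])


def run_cargo_transport(
    rods: MTRods, config: StaticRodConfig, geom: OocyteGeometry, seed=None
) -> SimResult:
    """Run the cargo dynamics on a fixed rod set and return the final state.

    Cargo count is conserved exactly: each particle is always in exactly one
    of {free, bound, anchored}.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = config.n_cargo
    pos = _uniform_interior_points(geom, n, rng, margin=0.2)
    bound = np.full(n, -1, dtype=int)  # rod index, -1 = free
    s_arc = np.zeros(n)
    anchored = np.zeros(n, dtype=bool)

    A, U, L = rods.anchor, rods.direction, rods.length
    tips = rods.tip
    # anchoring happens only at plus ends that actually reach the cortex on
    # the posterior-labelled arc (cortical anchoring machinery)
    at_cortex = rods.raw_length > rods.length + 1e-12  # length was cortex-truncated
    tip_near_posterior = at_cortex & (
        distances_to_posterior_arc(tips, geom) <= config.anchor_dist
    )

    n_steps = int(round(config.T_total / config.dt))
    p_unbind = 1.0 - math.exp(-config.k_unbind * config.dt)
    sigma = math.sqrt(2.0 * config.D_cyto * config.dt)

    for _ in range(n_steps):
        # walking cargo
        on = (bound >= 0) & ~anchored
        if on.any():
            idx = np.nonzero(on)[0]
            rid = bound[idx]
            s_new = s_arc[idx] + config.v_walk * config.dt
            at_tip = s_new >= L[rid]
            s_new = np.minimum(s_new, L[rid])
            s_arc[idx] = s_new
            pos[idx] = A[rid] + U[rid] * s_new[:, None]
            if at_tip.any():
                ti = idx[at_tip]
                tr = rid[at_tip]
                anchor_now = tip_near_posterior[tr]
                anchored[ti[anchor_now]] = True
                bound[ti[anchor_now]] = -1
                if config.tip_behavior == "run_off":
                    bound[ti[~anchor_now]] = -1
            # stochastic unbinding (tethered tips included)
            still = (bound >= 0) & ~anchored
            if still.any():
                si = np.nonzero(still)[0]
                off = rng.random(len(si)) < p_unbind
                bound[si[off]] = -1

        # free cargo: diffusion (+ flow), reflecting boundary by rejection
        free = (bound < 0) & ~anchored
        if free.any():
            fi = np.nonzero(free)[0]
            step = rng.normal(0.0, sigma, (len(fi), 2))
            if config.flow_u != 0.0:
                step = step + _flow_velocity(pos[fi], geom, config.flow_u) * config.dt
            cand = pos[fi] + step
            ok = geom.contains(cand)
            pos[fi[ok]] = cand[ok]

            # capture by the nearest rod within the capture radius
            P = pos[fi]
            diff = P[:, None, :] - A[None, :, :]
            t = np.einsum("ijk,jk->ij", diff, U)
            t = np.clip(t, 0.0, L[None, :])
            proj = A[None, :, :] + t[..., None] * U[None, :, :]
            d2 = np.sum((P[:, None, :] - proj) ** 2, axis=2)
            nearest = np.argmin(d2, axis=1)
            near_ok = d2[np.arange(len(fi)), nearest] <= config.capture_radius**2
            cap = fi[near_ok]
            bound[cap] = nearest[near_ok]
            s_arc[cap] = t[np.arange(len(fi)), nearest][near_ok]
            pos[cap] = proj[np.arange(len(fi)), nearest][near_ok]

        assert int(anchored.sum() + (bound >= 0).sum() + ((bound < 0) & ~anchored).sum()) == n

    density = density_from_positions(pos, geom, cell=config.density_cell)
    return SimResult(
        positions=pos,
        density=density,
        anchored=anchored,
        meta={
            "model": "static_rod",
            "epsilon": config.epsilon,
            "n_steps": n_steps,
            "anchored_fraction": float(anchored.mean()),
        },
    )
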