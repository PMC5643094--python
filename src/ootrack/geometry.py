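"""Oocyte cross-section geometry and distance/region queries.

All analysis is two-dimensional: every measurement the package handles comes
from single-plane time-lapse movies, so the oocyte is represented by its
cortex outline in the imaging plane.  Coordinates are in micrometres.

The cortex is a closed simple polygon whose vertices carry region labels
(``anterior``, ``lateral``, ``posterior``).  The posterior pole is a marked
point on the cortex and the anterior->posterior (AP) axis is a unit vector;
together they define the reference frame for every directional statistic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import LinearRing, Point as ShapelyPoint, Polygon

REGIONS = ("anterior", "lateral", "posterior")

#: tolerance (um) for "the posterior pole lies on the cortex"
POLE_ON_CORTEX_TOL = 1e-6


class GeometryError(ValueError):
    """Raised for invalid cortex outlines or pole/axis specifications."""


@dataclass(frozen=True)
class OocyteGeometry:
    """Validated oocyte cross-section.

    Attributes
    ----------
    cortex : (n, 2) float array
        Ordered cortex vertices in um (closed implicitly; the last vertex
        connects back to the first).
    posterior_pole : (2,) float array
        Point on the cortex marking the posterior pole.
    ap_axis : (2,) float array
        Unit vector pointing anterior -> posterior.
    region_labels : tuple of str
        Per-vertex region label; an edge inherits the label of its first
        vertex.
    L_AP : float
        Extent of the cortex projected onto the AP axis (um).
    """

    cortex: np.ndarray
    posterior_pole: np.ndarray
    ap_axis: np.ndarray
    region_labels: tuple
    L_AP: float
    _polygon: Polygon = field(repr=False, compare=False, default=None)

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    @property
    def centroid(self) -> np.ndarray:
        c = self._polygon.centroid
        return np.array([c.x, c.y])

    def arc_vertices(self, region: str) -> np.ndarray:
        """Indices of cortex vertices carrying ``region``'s label."""
        return np.array([i for i, r in enumerate(self.region_labels) if r == region], dtype=int)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorised point-in-polygon test (boundary counts as inside)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        from shapely import contains_xy

        inside = contains_xy(self._polygon, pts[:, 0], pts[:, 1])
        # boundary points: shapely contains_xy is exclusive; accept on-boundary
        near = np.array(
            [self._polygon.exterior.distance(ShapelyPoint(*p)) < 1e-9 if not i else False
             for p, i in zip(pts, inside)]
        )
        return inside | near


def _as_unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if not np.isfinite(n) or n == 0:
        raise GeometryError("ap_axis must be a nonzero finite vector")
    return v / n


def build_geometry(cortex_points, posterior_pole, ap_axis, region_labels) -> OocyteGeometry:
    """Validate a cortex outline and assemble an :class:`OocyteGeometry`.

    Parameters
    ----------
    cortex_points : sequence of (x, y)
        At least 8 ordered vertices forming a simple closed polygon (um).
    posterior_pole : (x, y)
        Must lie on the cortex (within ``POLE_ON_CORTEX_TOL``).
    ap_axis : (x, y)
        Anterior->posterior direction; normalised internally.
    region_labels : sequence of str
        One of ``anterior``/``lateral``/``posterior`` per vertex.

    Raises
    ------
    GeometryError
        For self-intersecting outlines, a pole off the cortex, bad labels,
        or a degenerate AP extent.
    """
    pts = np.asarray(cortex_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 8:
        raise GeometryError("cortex needs >= 8 (x, y) vertices")
    if not np.all(np.isfinite(pts)):
        raise GeometryError("cortex vertices must be finite")
    labels = tuple(region_labels)
    if len(labels) != len(pts):
        raise GeometryError("region_labels must cover every cortex vertex")
    bad = set(labels) - set(REGIONS)
    if bad:
        raise GeometryError(f"unknown region labels: {sorted(bad)}")

    ring = LinearRing(pts)
    if not ring.is_simple or not ring.is_valid:
        raise GeometryError("cortex polygon is self-intersecting")
    poly = Polygon(ring)
    if poly.area <= 0:
        raise GeometryError("cortex polygon has zero area")

    pole = np.asarray(posterior_pole, dtype=float)
    if pole.shape != (2,) or not np.all(np.isfinite(pole)):
        raise GeometryError("posterior_pole must be a finite (x, y) point")
    if poly.exterior.distance(ShapelyPoint(*pole)) > POLE_ON_CORTEX_TOL:
        raise GeometryError("posterior_pole does not lie on the cortex")

    axis = _as_unit(ap_axis)
    proj = pts @ axis
    L_AP = float(proj.max() - proj.min())
    if L_AP <= 0:
        raise GeometryError("degenerate AP extent")

    # the posterior-labelled arc must contain (the vertex nearest) the pole
    nearest = int(np.argmin(np.hypot(*(pts - pole).T)))
    if labels[nearest] != "posterior":
        raise GeometryError("posterior-labelled arc does not contain the posterior pole")

    return OocyteGeometry(
        cortex=pts,
        posterior_pole=pole,
        ap_axis=axis,
        region_labels=labels,
        L_AP=L_AP,
        _polygon=poly,
    )


def ellipse_geometry(
    a: float = 25.0,
    b: float = 20.0,
    n_vertices: int = 64,
    posterior_half_angle: float = 15.0,
    anterior_half_angle: float = 30.0,
) -> OocyteGeometry:
    """Standard test-bed oocyte: an ellipse with the posterior pole at (+a, 0).

    The AP axis is +x.  Vertices within ``posterior_half_angle`` degrees of the
    pole (seen from the centre) are labelled posterior, those within
    ``anterior_half_angle`` of (-a, 0) anterior, the rest lateral.  The default
    50 x 40 um outline approximates a stage-9 oocyte cross section.
    """
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    pts = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
    ang = np.degrees(np.abs(np.arctan2(pts[:, 1], pts[:, 0])))
    labels = []
    for d in ang:
        if d <= posterior_half_angle:
            labels.append("posterior")
        elif d >= 180.0 - anterior_half_angle:
            labels.append("anterior")
        else:
            labels.append("lateral")
    return build_geometry(pts, (a, 0.0), (1.0, 0.0), labels)


def distance_to_posterior_pole(p, geom: OocyteGeometry) -> float:
    """Euclidean distance (um) from ``p`` to the posterior pole."""
    p = np.asarray(p, dtype=float)
    return float(np.hypot(*(p - geom.posterior_pole)))


def distance_to_cortex(p, geom: OocyteGeometry) -> float:
    """Minimum distance (um) from ``p`` to any cortex edge."""
    p = np.asarray(p, dtype=float)
    return float(geom.polygon.exterior.distance(ShapelyPoint(*p)))


def distances_to_cortex(points: np.ndarray, geom: OocyteGeometry) -> np.ndarray:
    """Vectorised :func:`distance_to_cortex` over an (n, 2) array."""
    from shapely import distance, points as mk_points

    pts = mk_points(np.atleast_2d(np.asarray(points, dtype=float)))
    return distance(geom.polygon.exterior, pts)


def distance_band(d: float, bin_width: float) -> int:
    """Half-open distance band index: band k covers [k*w, (k+1)*w)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if d < 0:
        raise ValueError("distance must be non-negative")
    return int(math.floor(d / bin_width))


def nearest_cortex_info(p, geom: OocyteGeometry):
    """Nearest boundary point, its cortex region, and the local tangent.

    Returns ``(closest_point, region, tangent_unit_vector)``.  The region is
    the label of the first vertex of the nearest edge (edges inherit their
    first vertex's label); the tangent is the direction of that edge.
    """
    p = np.asarray(p, dtype=float)
    pts = geom.cortex
    n = len(pts)
    a = pts
    b = np.roll(pts, -1, axis=0)
    ab = b - a
    ab2 = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.where(ab2 == 0, 1.0, ab2), 0.0, 1.0)
    proj = a + t[:, None] * ab
    d2 = np.einsum("ij,ij->i", p - proj, p - proj)
    k = int(np.argmin(d2))
    tangent = ab[k] / math.hypot(*ab[k])
    return proj[k], geom.region_labels[k], tangent


def exit_distance(origin, direction, geom: OocyteGeometry, max_len: float = 1e6) -> float:
    """Distance along ``direction`` from ``origin`` to where the ray leaves
    the cortex polygon.  Used to truncate microtubule rods at the cortex."""
    from shapely.geometry import LineString

    origin = np.asarray(origin, dtype=float)
    u = _as_unit(direction)
    far = origin + u * max_len
    seg = LineString([origin, far])
    hit = seg.intersection(geom.polygon.exterior)
    if hit.is_empty:
        return 0.0
    best = None
    geoms = getattr(hit, "geoms", [hit])
    for g in geoms:
        for x, y in getattr(g, "coords", []):
            d = (np.array([x, y]) - origin) @ u
            if d > 1e-9 and (best is None or d < best):
                best = d
    return float(best) if best is not None else 0.0


# ---------------------------------------------------------------------------
# JSON geometry files


def write_geometry(geom: OocyteGeometry, path) -> None:
    payload = {
        "cortex": geom.cortex.tolist(),
        "posterior_pole": geom.posterior_pole.tolist(),
        "ap_axis": geom.ap_axis.tolist(),
        "region_labels": list(geom.region_labels),
        "units": "um",
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_geometry(path) -> OocyteGeometry:
    payload = json.loads(Path(path).read_text())
    for key in ("cortex", "posterior_pole", "ap_axis", "region_labels"):
        if key not in payload:
            raise GeometryError(f"geometry file missing key {key!r}")
    return build_geometry(
        payload["cortex"],
        payload["posterior_pole"],
        payload["ap_axis"],
        payload["region_labels"],
    )
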