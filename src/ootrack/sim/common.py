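"""Shared simulator containers and the crescent-vs-cloud score."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..geometry import OocyteGeometry


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DensityGrid:
    """Cargo counts on a regular grid (counts[ix, iy]; cells are square)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray

    @property
    def cell_area(self) -> float:
        return float((self.x_edges[1] - self.x_edges[0]) * (self.y_edges[1] - self.y_edges[0]))

    @property
    def centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell centre coordinates (x-major order)."""
        cx = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        cy = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])

    @property
    def density(self) -> np.ndarray:
        """Counts per um^2."""
        return self.counts / self.cell_area


def density_from_positions(positions: np.ndarray, geom: OocyteGeometry, cell: float = 1.0) -> DensityGrid:
    minx, miny, maxx, maxy = geom.polygon.bounds
    x_edges = np.arange(minx - cell, maxx + 2 * cell, cell)
    y_edges = np.arange(miny - cell, maxy + 2 * cell, cell)
    counts, _, _ = np.histogram2d(positions[:, 0], positions[:, 1], bins=[x_edges, y_edges])
    return DensityGrid(x_edges=x_edges, y_edges=y_edges, counts=counts)


@dataclass
class SimResult:
    """Output bundle of a transport simulation run."""

    positions: np.ndarray
    density: DensityGrid
    anchored: np.ndarray
    comet_tracks: object = None  # TrackSet or None
    dwells: object = None  # DataFrame (region, dwell) or None
    dynactin_series: object = None  # DataFrame or None
    meta: dict = field(default_factory=dict)


def posterior_arc_lines(geom: OocyteGeometry):
    """Shapely line collection of the posterior-labelled cortex edges."""
    from shapely.geometry import MultiLineString

    pts = geom.cortex
    nxt = np.roll(pts, -1, axis=0)
    segs = [
        (tuple(a), tuple(b))
        for a, b, lab in zip(pts, nxt, geom.region_labels)
        if lab == "posterior"
    ]
    if not segs:
        raise ConfigError("geometry has no posterior-labelled cortex")
    return MultiLineString(segs)


def distances_to_posterior_arc(points: np.ndarray, geom: OocyteGeometry) -> np.ndarray:
    from shapely import distance, points as mk_points

    arc = posterior_arc_lines(geom)
    return distance(arc, mk_points(np.atleast_2d(points)))


def crescent_score(density: DensityGrid, geom: OocyteGeometry, shell: float = 2.0) -> float:
    """Cortical-crescent enrichment: mean density in a thin shell along the
    posterior cortex divided by mean density in the rest of the posterior
    third of the cytoplasm.

    Scores > 1 indicate cortical enrichment (a crescent); a uniform
    distribution scores 1.  Returns +inf when all posterior-third cargo sits
    in the shell and NaN when the posterior third is empty altogether.
    """
    centers = density.centers
    inside = geom.contains(centers)
    if not inside.any():
        raise ConfigError("density grid does not overlap the geometry")
    d_arc = distances_to_posterior_arc(centers, geom)
    proj = centers @ geom.ap_axis
    cortex_proj = geom.cortex @ geom.ap_axis
    thr = cortex_proj.min() + (2.0 / 3.0) * (cortex_proj.max() - cortex_proj.min())
    vals = density.density.ravel()
    shell_mask = inside & (d_arc <= shell)
    region_mask = inside & (proj >= thr) & ~shell_mask
    if not shell_mask.any() or not region_mask.any():
        raise ConfigError("empty shell or posterior region at this grid resolution")
    mean_shell = float(vals[shell_mask].mean())
    mean_region = float(vals[region_mask].mean())
    if mean_region == 0.0:
        return float("inf") if mean_shell > 0 else float("nan")
    return mean_shell / mean_region


def fraction_entering_band(ts, geom: OocyteGeometry, band=(0.0, 10.0)) -> float:
    """Fraction of tracks with at least one point whose pole distance is in
    the half-open band [lo, hi)."""
    lo, hi = band
    n_tot = 0
    n_in = 0
    for tr in ts:
        d = np.hypot(*(tr.xy - geom.posterior_pole).T)
        n_tot += 1
        if np.any((d >= lo) & (d < hi)):
            n_in += 1
    return n_in / n_tot if n_tot else float("nan")
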