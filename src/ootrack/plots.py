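"""Figure helpers (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def rose_plot(direction_hist, band=None, ax=None, **kwargs):
    """Circular histogram of net track directions (0 deg = toward the pole)."""
    df = direction_hist
    if band is not None:
        df = df[df.band_lo == band[0]]
    if ax is None:
        _fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    for (lo, hi), g in df.groupby(["band_lo", "band_hi"]):
        theta = np.radians(g.angle_lo.to_numpy(dtype=float) + 5.0)
        ax.bar(theta, g["count"], width=np.radians(10.0), alpha=0.6,
               label=f"{lo:g}-{hi:g} um", **kwargs)
    ax.set_theta_zero_location("E")
    ax.legend(fontsize="x-small", loc="upper left", bbox_to_anchor=(1.0, 1.1))
    return ax


def distance_frequency_plot(table, ax=None):
    if ax is None:
        _fig, ax = plt.subplots()
    ax.bar(table.band_lo, table.freq, width=table.band_hi - table.band_lo, align="edge",
           edgecolor="k", alpha=0.7)
    ax.set_xlabel("distance from posterior pole (um)")
    ax.set_ylabel("relative frequency")
    return ax


def dwell_histogram(dwells, fit=None, ax=None, label=None):
    from scipy import stats as sstats

    if ax is None:
        _fig, ax = plt.subplots()
    dwells = np.asarray(dwells, dtype=float)
    ax.hist(dwells, bins="auto", density=True, alpha=0.6, label=label)
    if fit is not None:
        xs = np.linspace(0, dwells.max() * 1.1, 200)
        ax.plot(xs, sstats.t.pdf(xs, fit.nu, loc=fit.mu, scale=fit.sigma),
                "k-", label="t fit")
    ax.set_xlabel("cortical dwell time (s)")
    ax.set_ylabel("density")
    if label or fit is not None:
        ax.legend()
    return ax


def density_heatmap(grid, geom=None, ax=None):
    if ax is None:
        _fig, ax = plt.subplots()
    ax.imshow(
        grid.counts.T,
        origin="lower",
        extent=(grid.x_edges[0], grid.x_edges[-1], grid.y_edges[0], grid.y_edges[-1]),
        cmap="inferno",
        aspect="equal",
    )
    if geom is not None:
        cortex = np.vstack([geom.cortex, geom.cortex[:1]])
        ax.plot(cortex[:, 0], cortex[:, 1], "w-", lw=0.8)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    return ax


def kymograph_image(kymo, frame_dt=1.7, bin_um=1.0, ax=None):
    if ax is None:
        _fig, ax = plt.subplots()
    ax.imshow(kymo, origin="upper", aspect="auto", cmap="Greys",
              extent=(0, kymo.shape[1] * frame_dt, kymo.shape[0] * bin_um, 0))
    ax.set_xlabel("time (s)")
    ax.set_ylabel("arc position (um)")
    return ax


def save(fig_or_ax, path, dpi=150):
    fig = getattr(fig_or_ax, "figure", fig_or_ax)
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
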